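"""Synthetic two-class expression data with known planted structure.

The generator follows the microarray convention: log-scale expression is
Gaussian per probe around a probe-specific baseline, and an informative
probe's mean is shifted in the case class by a chosen multiple of the noise
SD.  Optional uniform missingness and expression-linked exponential survival
times make every downstream module testable without any external download.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import CanesError, ExpressionDataset, resolve_markers

#: log2-intensity range the per-probe baselines are drawn from
BASELINE_RANGE = (6.0, 12.0)


def generate_dataset(n_case: int, n_control: int, n_probes: int,
                     informative=(), noise_sd: float = 1.0,
                     missing_rate: float = 0.0, seed: int = 0,
                     marker_names: dict | None = None,
                     dataset_id: str = "synthetic") -> ExpressionDataset:
    """Two-class Gaussian log-expression with planted mean-shift markers.

    Parameters
    ----------
    informative
        Iterable of ``(probe_index, effect_size)`` pairs; the probe's case
        mean is shifted by ``effect_size * noise_sd``.
    missing_rate
        Fraction of cells masked uniformly at random; the realized count is
        ``round(rate * cells)``, so the realized rate is within one cell of
        the request.
    marker_names
        Optional ``probe_index -> gene symbol`` overrides; remaining probes
        get generic ``G####`` symbols.
    """
    if n_case < 2 or n_control < 2:
        raise CanesError("need at least 2 samples per class")
    if not 0 <= missing_rate < 0.5:
        raise CanesError("missing_rate must be in [0, 0.5)")
    informative = list(informative)
    for idx, _ in informative:
        if not 0 <= idx < n_probes:
            raise CanesError(f"informative probe index {idx} out of range")

    rng = np.random.default_rng(seed)
    n_samples = n_case + n_control
    baseline = rng.uniform(*BASELINE_RANGE, size=n_probes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_probes, n_samples))
    for idx, effect in informative:
        values[idx, :n_case] += effect * noise_sd

    if missing_rate > 0:
        n_cells = n_probes * n_samples
        n_missing = int(round(missing_rate * n_cells))
        flat = rng.choice(n_cells, size=n_missing, replace=False)
        values.flat[flat] = np.nan

    probe_ids = [f"p_{i:04d}" for i in range(n_probes)]
    marker_names = marker_names or {}
    gene_map = {
        probe_ids[i]: marker_names.get(i, f"G{i:04d}") for i in range(n_probes)
    }
    sample_ids = [f"case_{i:03d}" for i in range(n_case)] + [
        f"ctrl_{i:03d}" for i in range(n_control)
    ]
    labels = np.array(["cancer"] * n_case + ["normal"] * n_control, dtype=object)
    return ExpressionDataset(
        values=values, probe_ids=probe_ids, sample_ids=sample_ids,
        labels=labels, gene_map=gene_map, dataset_id=dataset_id,
    )


def generate_survival(ds: ExpressionDataset, marker, log_hr_per_sd: float,
                      censor_rate: float = 0.0, seed: int = 0,
                      baseline_hazard: float = 0.1) -> ExpressionDataset:
    """Attach exponential survival times whose hazard tracks a marker.

    Event times are exponential with per-sample hazard
    ``baseline_hazard * exp(log_hr_per_sd * z)`` where z is the marker's
    standardized expression.  Independent exponential censoring is tuned so
    the expected censored fraction approximates ``censor_rate``; at rate 0
    every sample has an event.
    """
    if not 0 <= censor_rate < 1:
        raise CanesError("censor_rate must be in [0, 1)")
    ms = resolve_markers([marker] if isinstance(marker, str) else marker, ds)
    expr = ds.values[ms.indices].mean(axis=0)
    if np.isnan(expr).any():
        raise CanesError("marker expression has missing values; impute first")
    s = expr.std()
    z = (expr - expr.mean()) / s if s > 0 else np.zeros_like(expr)

    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.exp(log_hr_per_sd * z)
    event_times = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        # for a (T, C) exponential pair the censored fraction is
        # lam_c / (lam + lam_c); tune lam_c against the mean hazard
        lam_c = censor_rate / (1 - censor_rate) * hazard.mean()
        censor_times = rng.exponential(1.0 / lam_c, size=hazard.size)
        times = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    else:
        times, events = event_times, np.ones(hazard.size, dtype=int)

    out = ds.with_values(ds.values.copy())
    out.survival = pd.DataFrame({"time": times, "event": events},
                                index=list(ds.sample_ids))
    return out


# ----------------------------------------------------------------------
# shipped fixture presets
# ----------------------------------------------------------------------

def preset_cldn_toy(seed: int = 0, missing_rate: float = 0.0) -> ExpressionDataset:
    """Gastric-cancer-like toy: 38 cases vs 31 controls, 200 probes, a
    three-claudin panel of unequal effect (CLDN18 strongest, CLDN4 weakest).
    """
    return generate_dataset(
        n_case=38, n_control=31, n_probes=200,
        informative=[(0, 1.5), (1, 1.0), (2, 2.0)],
        marker_names={0: "CLDN1", 1: "CLDN4", 2: "CLDN18"},
        missing_rate=missing_rate, seed=seed, dataset_id="cldn_toy",
    )


#: the seven-name panel of the panel7 preset
PANEL7_GENES = ("BRCA1", "BRCA2", "BRIP1", "CHEK2", "PALB2", "RB1", "TP53")


def preset_panel7(seed: int = 0) -> ExpressionDataset:
    """Lung-like test set: 46 cases vs 45 controls, 300 probes, a seven-gene
    panel of which only two (BRIP1, RB1) are informative.
    """
    return generate_dataset(
        n_case=46, n_control=45, n_probes=300,
        informative=[(2, 2.0), (5, 1.5)],
        marker_names={i: g for i, g in enumerate(PANEL7_GENES)},
        seed=seed, dataset_id="panel7",
    )


PRESETS = {"cldn_toy": preset_cldn_toy, "panel7": preset_panel7}
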