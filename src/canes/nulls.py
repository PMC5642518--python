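"""Size-matched empirical nulls, standardized measures, empirical p-values,
influence measures, and exhaustive subset search with Westfall-Young
correction.

Raw performance measures drift upward with panel size, so an observed measure
t_o for an m-probe panel is judged against the null distribution of the same
measure for n random m-probe sets drawn from the same dataset and evaluated
by the identical cross-validated procedure.  The standardized measure is

    z = (t_o - t_bar) / s

with t_bar and s the null mean and (n-1)-divisor standard deviation, and the
empirical p-value counts null draws at least as good as the observation,
p = #{t_r >= t_o} / n.  An add-one variant (1 + #)/(n + 1) is the default so
that a panel beating every resample still yields a usable, strictly positive
p for downstream Fisher/Stouffer combination.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    CanesError,
    DEFAULT_POSITIVE_LABEL,
    ExpressionDataset,
    MarkerSet,
    average_panel,
    resolve_markers,
)
from .panel_eval import averaged_measures_loocv, default_classifiers, loocv_panel

P_VALUE_MODES = ("add_one", "as_printed")
SUBSET_SIZE_CAP = 12


@dataclass
class NullDistribution:
    """n resampled measure values for random size-m probe sets."""

    dataset_id: str
    measure: str
    m: int
    n: int
    values: np.ndarray
    seed: int
    classifier_names: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n:
            raise CanesError("null distribution size mismatch")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n > 1 else 0.0


@dataclass
class StandardizedResult:
    t_obs: float
    z: float
    p: float
    mode: str
    null: NullDistribution | None = None


def empirical_p(t_obs: float, null_values, mode: str = "add_one") -> float:
    """Fraction of null draws at least as good as the observation.

    Ties count against the observed set (>=).  ``add_one`` applies the
    (1 + c)/(n + 1) correction; ``as_printed`` is the plain c/n relative
    frequency, which can be exactly 0.
    """
    if mode not in P_VALUE_MODES:
        raise CanesError(f"unknown p-value mode {mode!r}")
    null_values = np.asarray(null_values, dtype=float)
    c = int((null_values >= t_obs).sum())
    n = null_values.size
    return (1 + c) / (n + 1) if mode == "add_one" else c / n


def standardize(t_obs: float, null: NullDistribution,
                mode: str = "add_one") -> StandardizedResult:
    """Standardized measure z = (t_obs - mean)/sd and empirical p-value."""
    sd = null.sd
    z = (t_obs - null.mean) / sd if sd > 0 else float("nan")
    p = empirical_p(t_obs, null.values, mode)
    return StandardizedResult(t_obs=t_obs, z=z, p=p, mode=mode, null=null)


def _null_cache_path(cache_dir, key):
    return Path(cache_dir) / f"null_{key}.json"


def _dataset_fingerprint(ds: ExpressionDataset) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.nan_to_num(ds.values)).tobytes())
    h.update("|".join(map(str, ds.labels)).encode())
    return h.hexdigest()[:16]


def build_null(ds: ExpressionDataset, m: int, n: int = 1000,
               measure: str = "auc", classifiers=None, seed: int = 0,
               positive_label: str = DEFAULT_POSITIVE_LABEL,
               cache_dir=None) -> NullDistribution:
    """Evaluate n random m-probe sets by the same LOOCV procedure.

    Probe sets are drawn uniformly without replacement from *all* probes
    (the observed panel is not excluded; its inclusion bias is O(m/#probes)).
    Deterministic given ``seed``.  With ``cache_dir`` set, the resampled
    values are cached on disk keyed by dataset content, m, n, measure,
    classifier set and seed.
    """
    if m > ds.n_probes:
        raise CanesError(f"cannot draw {m} probes from {ds.n_probes}")
    if n < 19:
        raise CanesError("need at least 19 resamples for a usable null")
    classifiers = classifiers or default_classifiers()
    names = tuple(c.name for c in classifiers)

    cache_path = None
    if cache_dir is not None:
        key = f"{_dataset_fingerprint(ds)}_{m}_{n}_{measure}_{'-'.join(names)}_{seed}"
        cache_path = _null_cache_path(cache_dir, key)
        if cache_path.exists():
            payload = json.loads(cache_path.read_text())
            return NullDistribution(
                dataset_id=ds.dataset_id, measure=measure, m=m, n=n,
                values=np.asarray(payload["values"]), seed=seed,
                classifier_names=names,
            )

    y = ds.binary_labels(positive_label)
    rng = np.random.default_rng(seed)
    values = np.empty(n)
    for r in range(n):
        rows = rng.choice(ds.n_probes, size=m, replace=False)
        X = ds.values[rows].T.copy()
        values[r] = averaged_measures_loocv(X, y, classifiers)[measure]

    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        cache_path.write_text(json.dumps({"values": values.tolist()}))
    return NullDistribution(
        dataset_id=ds.dataset_id, measure=measure, m=m, n=n,
        values=values, seed=seed, classifier_names=names,
    )


def evaluate_with_null(ds: ExpressionDataset, markers, measure: str = "auc",
                       n: int = 1000, classifiers=None, seed: int = 0,
                       mode: str = "add_one",
                       positive_label: str = DEFAULT_POSITIVE_LABEL,
                       cache_dir=None) -> StandardizedResult:
    """Observed consensus measure of a panel plus its z and empirical p."""
    if not isinstance(markers, MarkerSet):
        markers = resolve_markers(markers, ds)
    classifiers = classifiers or default_classifiers()
    X = ds.feature_matrix(markers.indices)
    y = ds.binary_labels(positive_label)
    t_obs = averaged_measures_loocv(X, y, classifiers)[measure]
    null = build_null(ds, m=markers.n_probes, n=n, measure=measure,
                      classifiers=classifiers, seed=seed,
                      positive_label=positive_label, cache_dir=cache_dir)
    return standardize(t_obs, null, mode)


# ----------------------------------------------------------------------
# influence of a single marker
# ----------------------------------------------------------------------

def influence(ds: ExpressionDataset, markers, name, measure: str = "auc",
              classifiers=None,
              positive_label: str = DEFAULT_POSITIVE_LABEL) -> float:
    """t(full panel) - t(panel without ``name``), consensus measure.

    Positive influence means the marker helps the panel.  Both runs use the
    same scheme and the same classifier seeds.
    """
    if not isinstance(markers, MarkerSet):
        markers = resolve_markers(markers, ds)
    resolved = markers.resolved_names()
    if name not in resolved:
        raise CanesError(f"{name!r} is not a resolved member of the panel")
    if len(resolved) < 2:
        raise CanesError("influence needs a panel of at least 2 resolved markers")
    classifiers = classifiers or default_classifiers()
    y = ds.binary_labels(positive_label)

    def t_for(names):
        sub = resolve_markers(names, ds)
        X = ds.feature_matrix(sub.indices)
        return averaged_measures_loocv(X, y, classifiers)[measure]

    return t_for(resolved) - t_for([n for n in resolved if n != name])


# ----------------------------------------------------------------------
# exhaustive subset search with Westfall-Young correction
# ----------------------------------------------------------------------

@dataclass
class SubsetResult:
    subset: tuple                 # marker names
    m: int                        # resolved probe count
    t_obs: dict                   # measure -> observed consensus value
    raw_p: dict = field(default_factory=dict)
    adj_p: dict = field(default_factory=dict)
    z: dict = field(default_factory=dict)


def _westfall_young_adjust(t_obs: np.ndarray, null_cols: np.ndarray,
                           mode: str) -> tuple:
    """Free step-down minP adjustment over one family of subsets.

    ``t_obs``: observed measure per subset (K,).  ``null_cols``: resampled
    measures, shape (n, K) — column j is the size-matched null for subset j,
    with row r sharing one resampling replicate across all subsets.  Returns
    (raw_p, adj_p) arrays under the requested counting mode.
    """
    n, K = null_cols.shape
    # per-subset raw counts (ties count with >=)
    raw_c = (null_cols >= t_obs[None, :]).sum(axis=0)
    # per-resample, per-subset minP scores: rank of each resample within its
    # own null column, as a plain c/n p-value (self included, so >= 1/n)
    p_star = np.empty_like(null_cols)
    for j in range(K):
        col = null_cols[:, j]
        # p_star[r, j] = #{r' : col[r'] >= col[r]} / n   (self included)
        p_star[:, j] = (col[None, :] >= col[:, None]).sum(axis=1) / n
    order = np.argsort(raw_c, kind="mergesort")  # most significant first
    q = np.full(n, np.inf)
    adj_c = np.empty(K, dtype=int)
    # step-down from the least significant end: successive minima of p*
    for pos in range(K - 1, -1, -1):
        j = order[pos]
        q = np.minimum(q, p_star[:, j])
        adj_c[j] = int((q <= raw_c[j] / n).sum())
    # enforce step-down monotonicity (adjusted p nondecreasing in raw rank)
    running = 0
    for pos in range(K):
        j = order[pos]
        running = max(running, adj_c[j])
        adj_c[j] = running
    if mode == "add_one":
        raw_p = (1 + raw_c) / (n + 1)
        adj_p = (1 + adj_c) / (n + 1)
    else:
        raw_p = raw_c / n
        adj_p = adj_c / n
    adj_p = np.maximum(adj_p, raw_p)
    return raw_p, np.minimum(adj_p, 1.0)


def subset_search(ds: ExpressionDataset, markers, measures=("ba", "auc"),
                  n_null: int = 999, classifiers=None, seed: int = 0,
                  mode: str = "add_one",
                  positive_label: str = DEFAULT_POSITIVE_LABEL,
                  wy_unit: str = "marker_resample") -> list:
    """Evaluate every non-empty subset of the panel with adjusted p-values.

    Each subset is scored by LOOCV; its raw empirical p comes from a
    size-matched null of random probe sets (one shared null per distinct
    subset size: resampling replicate r draws one random probe set per size).
    Family-wise adjustment is Westfall-Young free step-down minP over those
    shared resamples.  ``wy_unit='label_permutation'`` instead re-evaluates
    all subsets under label permutations (slower; an alternative null unit).

    Panels above 12 resolved names are refused (2^12 - 1 subsets).
    """
    if not isinstance(markers, MarkerSet):
        markers = resolve_markers(markers, ds)
    names = markers.resolved_names()
    if len(names) > SUBSET_SIZE_CAP:
        raise CanesError(
            f"{len(names)} markers -> {2 ** len(names) - 1} subsets; cap is "
            f"{SUBSET_SIZE_CAP} names — shrink the panel or search greedily outside"
        )
    classifiers = classifiers or default_classifiers()
    y = ds.binary_labels(positive_label)

    subsets = []
    for k in range(1, len(names) + 1):
        subsets.extend(itertools.combinations(names, k))

    results = []
    for sub in subsets:
        idx, seen = [], set()
        for nm in sub:
            for i in markers.by_name[nm]:
                if i not in seen:
                    seen.add(i)
                    idx.append(i)
        X = ds.values[idx].T.copy()
        t = averaged_measures_loocv(X, y, classifiers)
        results.append(SubsetResult(subset=sub, m=len(idx),
                                    t_obs={m: t[m] for m in measures}))

    sizes = sorted({r.m for r in results})
    rng = np.random.default_rng(seed)
    # null[measure][r, size_index]
    null = {m: np.empty((n_null, len(sizes))) for m in measures}
    if wy_unit == "marker_resample":
        for r in range(n_null):
            for si, m_sz in enumerate(sizes):
                rows = rng.choice(ds.n_probes, size=m_sz, replace=False)
                t = averaged_measures_loocv(ds.values[rows].T.copy(), y, classifiers)
                for meas in measures:
                    null[meas][r, si] = t[meas]
    elif wy_unit == "label_permutation":
        for r in range(n_null):
            y_perm = rng.permutation(y)
            per_size = {}
            for res in results:
                if res.m not in per_size:
                    rows = rng.choice(ds.n_probes, size=res.m, replace=False)
                    per_size[res.m] = averaged_measures_loocv(
                        ds.values[rows].T.copy(), y_perm, classifiers)
            for si, m_sz in enumerate(sizes):
                for meas in measures:
                    null[meas][r, si] = per_size[m_sz][meas]
    else:
        raise CanesError(f"unknown Westfall-Young unit {wy_unit!r}")

    size_col = {m_sz: si for si, m_sz in enumerate(sizes)}
    for meas in measures:
        t_obs = np.array([r.t_obs[meas] for r in results])
        cols = np.column_stack([null[meas][:, size_col[r.m]] for r in results])
        raw_p, adj_p = _westfall_young_adjust(t_obs, cols, mode)
        for j, res in enumerate(results):
            res.raw_p[meas] = float(raw_p[j])
            res.adj_p[meas] = float(adj_p[j])
            col = null[meas][:, size_col[res.m]]
            sd = float(np.std(col, ddof=1))
            res.z[meas] = (res.t_obs[meas] - float(np.mean(col))) / sd if sd > 0 else float("nan")
    return results
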