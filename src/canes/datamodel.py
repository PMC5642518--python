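"""Core domain types for biomarker panel evaluation.

The central object is :class:`ExpressionDataset`, a probes x samples matrix of
log-scale expression values with per-sample binary phenotype labels and
optional survival follow-up.  A :class:`MarkerSet` records how a user's query
identifiers (gene symbols, miRNA names, or probe IDs) resolve to probe rows of
one dataset.  Classification output is carried by :class:`ConfusionCounts`,
:class:`MeasurePanel` (the ten evaluation measures) and
:class:`EvaluationResult` (per-classifier panels plus their consensus
average).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical order of the ten evaluation measures
MEASURES = ("auc", "ac", "ba", "sn", "sp", "ppv", "npv", "fpr", "fdr", "f1")

#: default name of the positive (case) class
DEFAULT_POSITIVE_LABEL = "cancer"


class CanesError(Exception):
    """Base class for all domain errors."""


class FormatError(CanesError):
    """Malformed input file (duplicate IDs, bad header, non-numeric cell)."""


class ReconciliationError(CanesError):
    """Sample bookkeeping mismatch between matrix, labels, or survival."""


class ResolutionError(CanesError):
    """No query identifier could be matched to a probe row."""


class DegenerateSplitError(CanesError):
    """A requested grouping produced an empty group."""


@dataclass
class ExpressionDataset:
    """Probes x samples expression matrix with phenotype annotation.

    Parameters
    ----------
    values
        Float matrix of shape ``(n_probes, n_samples)``; missing cells are
        ``NaN`` and mirrored in ``missing_mask``.
    probe_ids, sample_ids
        Unique row / column identifiers.
    labels
        Per-sample class label.  Exactly two distinct values are required
        whenever the dataset is used for classification.
    gene_map
        Optional probe ID -> gene symbol map (many probes may share a symbol).
    survival
        Optional per-sample follow-up: DataFrame indexed by sample ID with
        columns ``time`` (positive) and ``event`` (0 = censored, 1 = event).
    outlier_flags
        Advisory per-sample quality flags (set by preprocessing, never
        enforced).
    """

    values: np.ndarray
    probe_ids: list
    sample_ids: list
    labels: np.ndarray
    gene_map: dict | None = None
    survival: pd.DataFrame | None = None
    outlier_flags: np.ndarray | None = None
    missing_mask: np.ndarray | None = None
    dataset_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n_probes, n_samples = self.values.shape
        if len(self.probe_ids) != n_probes:
            raise FormatError(
                f"{len(self.probe_ids)} probe IDs for {n_probes} matrix rows"
            )
        if len(self.sample_ids) != n_samples:
            raise FormatError(
                f"{len(self.sample_ids)} sample IDs for {n_samples} matrix columns"
            )
        if len(set(self.probe_ids)) != n_probes:
            raise FormatError("duplicate probe IDs")
        if len(set(self.sample_ids)) != n_samples:
            raise FormatError("duplicate sample IDs")
        if self.labels.shape != (n_samples,):
            raise ReconciliationError("one label required per sample")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise FormatError("missing_mask shape mismatch")
            self.values = self.values.copy()
            self.values[self.missing_mask] = np.nan
        if self.outlier_flags is None:
            self.outlier_flags = np.zeros(n_samples, dtype=bool)
        if self.survival is not None:
            self._check_survival()

    def _check_survival(self):
        surv = self.survival
        missing = set(surv.index) - set(self.sample_ids)
        if missing:
            raise ReconciliationError(
                f"survival rows for unknown samples: {sorted(missing)[:5]}"
            )
        if not (surv["time"] > 0).all():
            raise FormatError("survival times must be positive")
        if not surv["event"].isin([0, 1]).all():
            raise FormatError("survival event indicator must be 0 or 1")

    # -- basic geometry -------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def classes(self) -> list:
        return sorted(set(self.labels))

    def class_counts(self) -> dict:
        labs, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))

    # -- classification helpers -----------------------------------------
    def binary_labels(self, positive_label: str = DEFAULT_POSITIVE_LABEL) -> np.ndarray:
        """Return 0/1 labels with 1 marking the positive (case) class.

        If ``positive_label`` is absent from the data, the lexicographically
        first class is treated as positive (useful for tumor-type-vs-type
        comparisons where neither class is 'cancer').
        """
        classes = self.classes()
        if len(classes) != 2:
            raise CanesError(
                f"binary labels require exactly 2 classes, found {classes}"
            )
        pos = positive_label if positive_label in classes else classes[0]
        return (self.labels == pos).astype(int)

    def feature_matrix(self, rows) -> np.ndarray:
        """samples x features view of the given probe rows (copied)."""
        rows = np.asarray(rows, dtype=int)
        return self.values[rows].T.copy()

    def probe_index(self) -> dict:
        return {p: i for i, p in enumerate(self.probe_ids)}

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        """Copy of the dataset with a replaced value matrix."""
        return replace(self, values=values, missing_mask=None)


@dataclass
class MarkerSet:
    """A query panel resolved against one dataset.

    ``names`` preserves the user's order; ``by_name`` maps each resolved name
    to its probe rows (a symbol may hit several probes); ``indices`` is the
    deduplicated union in name order; ``unmatched`` lists names with no probe.
    """

    names: list
    indices: list
    unmatched: list
    by_name: dict
    dataset_id: str = ""

    @property
    def n_probes(self) -> int:
        return len(self.indices)

    def resolved_names(self) -> list:
        return [n for n in self.names if n not in self.unmatched]


def resolve_markers(names, ds: ExpressionDataset) -> MarkerSet:
    """Match query identifiers to probe rows of ``ds``.

    Probe IDs match exactly (case-sensitive); anything else is matched
    case-insensitively against the gene symbols of ``ds.gene_map``.  A name
    hitting several probes resolves to all of them.  Unmatched names are
    recorded but only a fully unresolved query is an error.
    """
    names = list(names)
    if not names:
        raise ResolutionError("empty marker list")
    probe_idx = ds.probe_index()
    symbol_idx: dict = {}
    if ds.gene_map:
        for probe, symbol in ds.gene_map.items():
            if probe in probe_idx and symbol is not None:
                symbol_idx.setdefault(str(symbol).upper(), []).append(probe_idx[probe])
    by_name, unmatched = {}, []
    for name in names:
        if name in probe_idx:
            by_name[name] = [probe_idx[name]]
        elif str(name).upper() in symbol_idx:
            by_name[name] = sorted(symbol_idx[str(name).upper()])
        else:
            unmatched.append(name)
    if not by_name:
        raise ResolutionError(f"none of {names} matched a probe in the dataset")
    indices, seen = [], set()
    for name in names:
        for i in by_name.get(name, ()):
            if i not in seen:
                seen.add(i)
                indices.append(i)
    return MarkerSet(
        names=names,
        indices=indices,
        unmatched=unmatched,
        by_name=by_name,
        dataset_id=ds.dataset_id,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MeasurePanel:
    """The ten evaluation measures of one classifier run.

    Undefined measures (degenerate denominators, e.g. PPV with no predicted
    positives) are ``NaN`` rather than an error.
    """

    auc: float
    ac: float
    ba: float
    sn: float
    sp: float
    ppv: float
    npv: float
    fpr: float
    fdr: float
    f1: float
    counts: ConfusionCounts | None = None
    classifier: str = ""
    pooled_scores: tuple | None = None  # (scores, true 0/1 labels)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in MEASURES}

    def __getitem__(self, measure: str) -> float:
        if measure not in MEASURES:
            raise KeyError(measure)
        return getattr(self, measure)


@dataclass
class EvaluationResult:
    """Per-classifier measure panels and their consensus average."""

    per_classifier: dict  # name -> MeasurePanel
    average: MeasurePanel
    scheme: str
    skipped_folds: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for name, panel in self.per_classifier.items():
            rows.append({"classifier": name, **panel.as_dict()})
        rows.append({"classifier": "average", **self.average.as_dict()})
        return pd.DataFrame(rows)


def average_panel(panels) -> MeasurePanel:
    """Arithmetic mean of each measure over its defined (non-NaN) values."""
    panels = list(panels)
    out = {}
    for m in MEASURES:
        vals = [p[m] for p in panels if not math.isnan(p[m])]
        out[m] = float(np.mean(vals)) if vals else float("nan")
    return MeasurePanel(**out, counts=None, classifier="average")
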