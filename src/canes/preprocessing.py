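"""Matrix-level preprocessing: quantile normalization, missing-data policy,
kNN imputation, and correlation-based sample outlier flagging.

The pipeline mirrors common microarray practice: a dataset whose overall
missing rate exceeds 5% is excluded outright; below that, missing cells are
imputed from the k nearest probes; columns are then quantile-normalized so
every sample shares one empirical distribution.  Outlier flags are advisory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.impute import KNNImputer

from .datamodel import CanesError, ExpressionDataset


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample column onto the mean empirical distribution.

    The reference distribution is the across-sample mean of the order
    statistics of complete probe rows.  For complete data each column's
    sorted values become exactly that reference, in the column's original
    rank order (ties get the average of their reference slots).  Columns with
    missing cells are mapped through interpolated quantiles of the reference,
    leaving missing cells missing.
    """
    if ds.n_samples < 2:
        raise CanesError("quantile normalization needs at least 2 samples")
    X = ds.values
    complete = ~np.isnan(X).any(axis=1)
    if not complete.any():
        raise CanesError("no complete probe rows to build the reference")
    reference = np.sort(X[complete], axis=0).mean(axis=1)

    out = np.full_like(X, np.nan)
    n_ref = reference.size
    for j in range(X.shape[1]):
        col = X[:, j]
        obs = ~np.isnan(col)
        vals = col[obs]
        order = np.argsort(vals, kind="mergesort")
        ranks = np.empty(vals.size)
        ranks[order] = np.arange(vals.size)
        # average ranks over ties so tied inputs stay tied
        uniq, inv = np.unique(vals, return_inverse=True)
        if uniq.size < vals.size:
            sums = np.bincount(inv, weights=ranks)
            cnts = np.bincount(inv)
            ranks = (sums / cnts)[inv]
        if vals.size == n_ref:
            normalized = np.interp(ranks, np.arange(n_ref), reference)
        else:
            q = ranks / (vals.size - 1) if vals.size > 1 else np.zeros_like(ranks)
            normalized = np.quantile(reference, q)
        out[obs, j] = normalized
    return ds.with_values(out)


@dataclass(frozen=True)
class MissingRateDecision:
    keep: bool
    rate: float
    threshold: float


def missing_rate_filter(ds: ExpressionDataset, threshold: float = 0.05) -> MissingRateDecision:
    """Exclude datasets whose fraction of missing cells exceeds ``threshold``.

    The inequality is strict: a rate exactly at the threshold is kept.
    """
    rate = float(ds.missing_mask.mean())
    return MissingRateDecision(keep=not rate > threshold, rate=rate, threshold=threshold)


def impute_knn(ds: ExpressionDataset, k: int = 10) -> ExpressionDataset:
    """Fill missing cells with the unweighted mean of the k nearest probes.

    Probe-to-probe distance is Euclidean over co-observed samples.  Observed
    cells are never altered.  A probe observed in no sample cannot be imputed
    and is an error; ``k`` larger than the number of candidate neighbor
    probes is clamped with a warning.
    """
    X = ds.values
    if not np.isnan(X).any():
        return ds.with_values(X.copy())
    all_missing = np.isnan(X).all(axis=1)
    if all_missing.any():
        bad = [ds.probe_ids[i] for i in np.flatnonzero(all_missing)[:5]]
        raise CanesError(f"probes missing in every sample cannot be imputed: {bad}")
    max_k = ds.n_probes - 1
    if k > max_k:
        warnings.warn(f"k={k} exceeds available neighbor probes; clamped to {max_k}")
        k = max_k
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(X)
    out = X.copy()
    out[np.isnan(X)] = filled[np.isnan(X)]
    return ds.with_values(out)


@dataclass
class OutlierReport:
    flags: np.ndarray            # per-sample advisory flag
    within_mean: np.ndarray      # mean correlation to same-class samples
    between_mean: np.ndarray     # mean correlation to other-class samples
    sd_multiplier: float


def detect_outliers(ds: ExpressionDataset, sd_multiplier: float = 3.0) -> OutlierReport:
    """Flag samples poorly correlated with the rest of their class.

    For each sample we compute the mean Pearson correlation to every other
    sample of the same class (within-group) and to the other class
    (between-group).  A sample is flagged when its within-group mean falls
    more than ``sd_multiplier`` standard deviations below its class mean of
    those within-group correlations.  A constant (zero-variance) sample has
    undefined correlations and is flagged outright.  Flags are advisory.
    """
    X = ds.values
    n = ds.n_samples
    labels = ds.labels
    for cls in set(labels):
        if (labels == cls).sum() < 3:
            raise CanesError("outlier detection needs >=3 samples per class")
    sd = np.nanstd(X, axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isnan(X).any():
            corr = np.ma.corrcoef(np.ma.masked_invalid(X.T)).filled(np.nan)
        else:
            corr = np.corrcoef(X.T)
    np.fill_diagonal(corr, np.nan)

    def _nanmean(row):  # nanmean without the all-NaN RuntimeWarning
        row = row[~np.isnan(row)]
        return row.mean() if row.size else np.nan

    within = np.full(n, np.nan)
    between = np.full(n, np.nan)
    for i in range(n):
        same = labels == labels[i]
        same_others = same.copy()
        same_others[i] = False
        within[i] = _nanmean(corr[i, same_others])
        between[i] = _nanmean(corr[i, ~same])

    flags = np.zeros(n, dtype=bool)
    for cls in set(labels):
        members = np.flatnonzero(labels == cls)
        w = within[members]
        ok = ~np.isnan(w)
        if ok.sum() >= 2 and np.std(w[ok], ddof=1) > 0:
            cutoff = np.mean(w[ok]) - sd_multiplier * np.std(w[ok], ddof=1)
            flags[members[ok]] = w[ok] < cutoff
        flags[members[~ok]] = True
    flags[constant] = True
    return OutlierReport(
        flags=flags, within_mean=within, between_mean=between,
        sd_multiplier=sd_multiplier,
    )


def preprocess(ds: ExpressionDataset, missing_threshold: float = 0.05,
               impute_k: int = 10, flag_outliers: bool = False,
               normalize: bool = True):
    """Full pipeline: missing-rate gate -> kNN imputation -> quantile
    normalization -> optional outlier flagging.

    Returns ``(dataset, report_dict)``; a dataset over the missing-rate
    threshold raises ``CanesError``.
    """
    decision = missing_rate_filter(ds, missing_threshold)
    report = {"missing_rate": decision.rate, "kept": decision.keep}
    if not decision.keep:
        raise CanesError(
            f"dataset excluded: missing rate {decision.rate:.4f} > {missing_threshold}"
        )
    out = impute_knn(ds, k=impute_k)
    if normalize:
        out = quantile_normalize(out)
    if flag_outliers:
        rep = detect_outliers(out)
        out.outlier_flags = rep.flags
        report["outliers"] = [s for s, f in zip(out.sample_ids, rep.flags) if f]
    return out, report
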