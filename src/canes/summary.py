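"""Pan-cancer style summaries: one panel evaluated across many datasets,
with per-dataset standardized measures and combined p-values, plus pairwise
tumor-type discrimination for a single marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combine import CombinedResult, combine
from .datamodel import (
    CanesError,
    DEFAULT_POSITIVE_LABEL,
    ExpressionDataset,
    MEASURES,
    ResolutionError,
    resolve_markers,
)
from .nulls import evaluate_with_null
from .panel_eval import default_classifiers, evaluate_loocv, loocv_panel
from .preprocessing import quantile_normalize


@dataclass
class PanCancerSummary:
    table: pd.DataFrame            # one row per (dataset, classifier)
    combined: dict                 # measure -> CombinedResult
    per_dataset: dict              # dataset_id -> {measure: StandardizedResult}
    unresolved: list               # dataset_ids where no marker matched


def pan_cancer_summary(datasets, names, measures=("auc", "ba"),
                       classifiers=None, n_null: int = 200, seed: int = 0,
                       combine_method: str = "fisher", mode: str = "add_one",
                       positive_label: str = DEFAULT_POSITIVE_LABEL,
                       cache_dir=None) -> PanCancerSummary:
    """Evaluate one marker panel across many datasets.

    Per dataset: LOOCV panels for every classifier (the ten measures), plus
    a size-matched empirical null per requested measure giving z and
    empirical p of the consensus value.  Per measure, the per-dataset
    p-values are combined across datasets by the configured method
    (weighted Stouffer uses each dataset's case/control counts).  Datasets
    where no marker resolves are listed, not fatal.
    """
    datasets = list(datasets)
    if not datasets:
        raise CanesError("need at least one dataset")
    classifiers = classifiers or default_classifiers()

    rows, per_dataset, unresolved, counts = [], {}, [], []
    for ds_i, ds in enumerate(datasets):
        ds_id = ds.dataset_id or f"dataset_{ds_i}"
        if ds_id in per_dataset:  # same dataset supplied twice
            ds_id = f"{ds_id}#{ds_i}"
        try:
            markers = resolve_markers(names, ds)
        except ResolutionError:
            unresolved.append(ds_id)
            continue
        result = evaluate_loocv(ds, markers, classifiers, positive_label)
        std = {}
        for ms_i, measure in enumerate(measures):
            std[measure] = evaluate_with_null(
                ds, markers, measure=measure, n=n_null,
                classifiers=classifiers,
                seed=seed + 1009 * ds_i + ms_i,
                mode=mode, positive_label=positive_label, cache_dir=cache_dir,
            )
        per_dataset[ds_id] = std
        y = ds.binary_labels(positive_label)
        counts.append((int((y == 1).sum()), int((y == 0).sum())))
        for clf_name, panel in list(result.per_classifier.items()) + [
            ("average", result.average)
        ]:
            row = {"dataset": ds_id, "classifier": clf_name, **panel.as_dict()}
            for measure in measures:
                row[f"z_{measure}"] = std[measure].z
                row[f"p_{measure}"] = std[measure].p
            rows.append(row)

    if not per_dataset:
        raise ResolutionError("the marker panel resolved in none of the datasets")
    combined = {}
    for measure in measures:
        p = [per_dataset[d][measure].p for d in per_dataset]
        combined[measure] = combine(
            p, method=combine_method,
            counts=counts if combine_method == "weighted_stouffer" else None,
        )
    return PanCancerSummary(
        table=pd.DataFrame(rows), combined=combined,
        per_dataset=per_dataset, unresolved=unresolved,
    )


def pairwise_discrimination(ds_a: ExpressionDataset, ds_b: ExpressionDataset,
                            marker, classifiers=None, normalize: bool = True):
    """How well one marker separates two tumor types.

    Each dataset is quantile-normalized on its own (no batch correction —
    residual dataset effects remain and inflate apparent separation), the
    marker's per-sample expression is extracted from each, and the merged
    samples are classified type-A vs type-B by pooled LOOCV.  Returns the
    consensus MeasurePanel; its AUC is the natural heatmap cell value.
    """
    classifiers = classifiers or default_classifiers()
    if normalize:
        ds_a, ds_b = quantile_normalize(ds_a), quantile_normalize(ds_b)
    cols = []
    for ds in (ds_a, ds_b):
        ms = resolve_markers([marker] if isinstance(marker, str) else marker, ds)
        if ms.unmatched:
            raise ResolutionError(f"{marker!r} not resolvable in {ds.dataset_id}")
        cols.append(ds.values[ms.indices].mean(axis=0))
    X = np.concatenate(cols)[:, None]
    if np.isnan(X).any():
        raise CanesError("marker expression has missing values; impute first")
    y = np.concatenate([np.ones(len(cols[0]), int), np.zeros(len(cols[1]), int)])
    panels = [loocv_panel(X, y, spec)[0] for spec in classifiers]
    from .datamodel import average_panel

    return average_panel(panels)
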