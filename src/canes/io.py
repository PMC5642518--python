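"""Readers and writers for the plain-text exchange formats.

Expression matrices follow the series-matrix-like layout: probes in rows,
samples in columns, first column probe IDs, header row sample IDs, tab- or
comma-delimited.  Labels are two-column (sample_id, class); survival tables
three-column (sample_id, time, event); annotation two-column
(probe_id, symbol); marker lists one identifier per line.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ConfusionCounts,
    EvaluationResult,
    ExpressionDataset,
    FormatError,
    MeasurePanel,
    ReconciliationError,
)

#: cell tokens treated as missing, case-insensitively
MISSING_TOKENS = {"", "na", "nan", "null"}


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False, **kw)


def read_expression(matrix_path, label_path, annotation_path=None,
                    survival_path=None, dataset_id=None) -> ExpressionDataset:
    """Load a dataset from delimited text files.

    Every sample column of the matrix must have a label; a labelled sample
    missing from the matrix (or vice versa) raises ``ReconciliationError``.
    Empty / NA / NaN cells become missing values.
    """
    raw = _read_table(matrix_path)
    probe_ids = raw.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in raw.columns[1:]]
    if len(set(probe_ids)) != len(probe_ids):
        raise FormatError(f"duplicate probe IDs in {matrix_path}")
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"duplicate sample IDs in {matrix_path}")

    cells = raw.iloc[:, 1:].to_numpy(dtype=object)
    flat = np.char.strip(cells.astype(str))
    missing = np.isin(np.char.lower(flat), sorted(MISSING_TOKENS))
    values = np.full(cells.shape, np.nan)
    try:
        values[~missing] = flat[~missing].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {matrix_path}: {exc}") from exc

    labels_tab = _read_table(label_path, header=None)
    if labels_tab.shape[1] < 2:
        raise FormatError(f"label file {label_path} needs 2 columns")
    # tolerate an optional header line
    if str(labels_tab.iloc[0, 0]).lower() in {"sample", "sample_id", "id"}:
        labels_tab = labels_tab.iloc[1:]
    label_map = dict(zip(labels_tab.iloc[:, 0], labels_tab.iloc[:, 1]))
    unlabeled = [s for s in sample_ids if s not in label_map]
    if unlabeled:
        raise ReconciliationError(f"samples without labels: {unlabeled[:5]}")
    orphans = sorted(set(label_map) - set(sample_ids))
    if orphans:
        raise ReconciliationError(
            f"labelled samples absent from matrix: {orphans[:5]}"
        )
    labels = np.array([label_map[s] for s in sample_ids], dtype=object)

    gene_map = None
    if annotation_path is not None:
        ann = _read_table(annotation_path, header=None)
        if str(ann.iloc[0, 0]).lower() in {"probe", "probe_id", "id"}:
            ann = ann.iloc[1:]
        gene_map = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))

    survival = None
    if survival_path is not None:
        survival = read_survival(survival_path)

    return ExpressionDataset(
        values=values,
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        labels=labels,
        gene_map=gene_map,
        survival=survival,
        dataset_id=dataset_id or Path(matrix_path).stem,
    )


def read_survival(path) -> pd.DataFrame:
    tab = _read_table(path, header=None)
    if str(tab.iloc[0, 0]).lower() in {"sample", "sample_id", "id"}:
        tab = tab.iloc[1:]
    if tab.shape[1] < 3:
        raise FormatError(f"survival file {path} needs 3 columns")
    out = pd.DataFrame(
        {
            "time": tab.iloc[:, 1].astype(float).to_numpy(),
            "event": tab.iloc[:, 2].astype(float).astype(int).to_numpy(),
        },
        index=tab.iloc[:, 0].tolist(),
    )
    return out


def read_marker_list(path) -> list:
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return names


def write_expression(ds: ExpressionDataset, matrix_path, label_path=None,
                     annotation_path=None, survival_path=None):
    """Write a dataset back to the delimited layout (NaN cells as 'NA')."""
    sep = _sep_for(matrix_path)
    frame = pd.DataFrame(ds.values, index=ds.probe_ids, columns=ds.sample_ids)
    frame.to_csv(matrix_path, sep=sep, na_rep="NA", index_label="probe_id")
    if label_path is not None:
        pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.labels}).to_csv(
            label_path, sep=_sep_for(label_path), index=False, header=False
        )
    if annotation_path is not None and ds.gene_map is not None:
        pd.DataFrame(
            {"probe_id": list(ds.gene_map), "symbol": list(ds.gene_map.values())}
        ).to_csv(annotation_path, sep=_sep_for(annotation_path), index=False, header=False)
    if survival_path is not None and ds.survival is not None:
        ds.survival.to_csv(survival_path, sep=_sep_for(survival_path), header=False)


# -- result serialization -----------------------------------------------

def _to_jsonable(obj):
    if isinstance(obj, MeasurePanel):
        d = obj.as_dict()
        d["classifier"] = obj.classifier
        if obj.counts is not None:
            d["counts"] = dataclasses.asdict(obj.counts)
        return _to_jsonable(d)
    if isinstance(obj, EvaluationResult):
        return {
            "scheme": obj.scheme,
            "per_classifier": {k: _to_jsonable(v) for k, v in obj.per_classifier.items()},
            "average": _to_jsonable(obj.average),
            "skipped_folds": obj.skipped_folds,
        }
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def _flatten_rows(obj):
    """Flatten a result record into CSV rows (one row per measure/leaf)."""
    if isinstance(obj, MeasurePanel):
        return [
            {"classifier": obj.classifier, "measure": m, "value": v}
            for m, v in obj.as_dict().items()
        ]
    if isinstance(obj, EvaluationResult):
        rows = []
        for panel in list(obj.per_classifier.values()) + [obj.average]:
            rows.extend(_flatten_rows(panel))
        return rows
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, list):
        rows = []
        for item in obj:
            rows.extend(_flatten_rows(item))
        return rows
    flat = _to_jsonable(obj)
    if isinstance(flat, dict) and all(not isinstance(v, (dict, list)) for v in flat.values()):
        return [flat]
    return [{"key": k, "value": json.dumps(v)} for k, v in flat.items()]


def write_report(results, path, format=None):
    """Serialize a result record to CSV or JSON.

    JSON round-trips every numeric field at full precision
    (``repr``-faithful floats); CSV uses ``repr`` precision as well.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        path.write_text(json.dumps(_to_jsonable(results), indent=2, allow_nan=True) + "\n")
    elif format == "csv":
        pd.DataFrame(_flatten_rows(results)).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report_json(path) -> dict:
    return json.loads(Path(path).read_text())
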