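"""Reading and writing benchmark matrices, truth sidecars and score tables.

Primary dialect is TSV (CSV is accepted on read by delimiter sniffing).
A matrix file is rectangular: first column = variable id, one column per
sample, plus a mandatory ``group`` row right under the header assigning
each sample to ``C`` (control) or ``D`` (disease); group labels may
alternatively come from a two-column sidecar (sample, label).  Floats
are written with 17 significant digits so a write/read round trip is
lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.17g"
VALID_LABELS = frozenset({"C", "D"})


def _sep_for(path: Path, first_line: str | None = None) -> str:
    if first_line is not None:
        return "\t" if "\t" in first_line else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_labels(labels: pd.Series) -> pd.Series:
    labels = labels.astype(str)
    bad = sorted(set(labels) - VALID_LABELS)
    if bad:
        raise ValueError(f"group labels must be 'C' or 'D', found {bad}")
    if set(labels) != VALID_LABELS:
        raise ValueError("both groups C and D must be present")
    return labels


def write_matrix(path, values, group_labels, var_ids=None) -> None:
    """Write a variables-by-samples matrix with an embedded group row."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    labels = _check_labels(pd.Series(list(group_labels)))
    if values.shape[1] != len(labels):
        raise ValueError("one group label per sample column required")
    if var_ids is None:
        var_ids = [f"v{i + 1:04d}" for i in range(values.shape[0])]
    samples = [f"s{i + 1:04d}" for i in range(values.shape[1])]
    sep = _sep_for(path)
    frame = pd.DataFrame(values, index=pd.Index(var_ids, name="variable"), columns=samples)
    with path.open("w") as fh:
        fh.write(sep.join(["variable", *samples]) + "\n")
        fh.write(sep.join(["group", *labels.tolist()]) + "\n")
        frame.to_csv(fh, sep=sep, header=False, float_format=FLOAT_FMT)


def read_matrix(path, labels_path=None) -> tuple[pd.DataFrame, pd.Series]:
    """Read a matrix file; returns (values frame, per-sample label series).

    The embedded ``group`` row takes precedence; otherwise a sidecar
    mapping file is required.
    """
    path = Path(path)
    first = path.open().readline()
    sep = _sep_for(path, first)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if "group" in df.index:
        labels = _check_labels(df.loc["group"])
        df = df.drop(index="group")
    elif labels_path is not None:
        mapping = pd.read_csv(
            Path(labels_path), sep=_sep_for(Path(labels_path)), index_col=0
        ).iloc[:, 0]
        try:
            labels = _check_labels(mapping.loc[df.columns])
        except KeyError as exc:
            raise ValueError(f"label sidecar misses sample(s): {exc}") from exc
    else:
        raise ValueError("matrix has no 'group' row and no label sidecar was given")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in matrix {path.name}: {exc}") from exc
    if not np.all(np.isfinite(values.to_numpy())):
        rows = values.index[~np.isfinite(values).all(axis=1)].tolist()
        raise ValueError(f"non-finite values in variable(s) {rows[:5]}")
    return values, labels


def write_truth(path, var_ids, truth) -> None:
    path = Path(path)
    pd.DataFrame({"variable": list(var_ids), "pattern": list(truth)}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_truth(path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, path.open().readline()), index_col=0)
    return df.iloc[:, 0]


def write_scores(path, table) -> None:
    """Write a ScoreTable: an ``orientation`` metadata row, then one row
    of raw values per variable."""
    path = Path(path)
    sep = _sep_for(path)
    with path.open("w") as fh:
        fh.write(sep.join(["variable", *table.raw.columns]) + "\n")
        fh.write(
            sep.join(["orientation", *[table.orientations[m] for m in table.raw.columns]])
            + "\n"
        )
        table.raw.to_csv(fh, sep=sep, header=False, float_format=FLOAT_FMT)


def write_manifest(path, params: dict) -> None:
    """Record every parameter needed to replay a run."""
    Path(path).write_text(json.dumps(params, indent=2, default=str) + "\n")
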