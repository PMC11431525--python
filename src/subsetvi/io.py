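"""Table and group-specification readers/writers.

Data tables are rectangular CSV/TSV files with a header row; one column is
the outcome, every other column a candidate predictor.  Cells must be
numeric and present — a missing or unparsable cell is reported with its row
and column so the offending record can be located.

Group files are YAML mappings from a group name to a list of predictor
column labels, used to test several columns (for instance the indicator
block of a categorical variable) as one unit.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import TableReadError
from .importance import VariableGroup
from .linear_model import Dataset

__all__ = ["read_table", "write_table", "read_groups", "dataset_to_frame"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(path: str | Path, outcome: str) -> Dataset:
    """Read a header-ed CSV/TSV into a :class:`Dataset`.

    The ``outcome`` column becomes y; the remaining columns, in file order,
    become the predictor matrix.
    """
    path = Path(path)
    if not path.exists():
        raise TableReadError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, sep=_sep_for(path))
    except Exception as err:  # parse failures carry pandas' location info
        raise TableReadError(f"could not parse {path}: {err}") from err
    if frame.columns.duplicated().any():
        dupes = frame.columns[frame.columns.duplicated()].tolist()
        raise TableReadError(f"duplicate column labels in {path}: {dupes}")
    if outcome not in frame.columns:
        raise TableReadError(
            f"outcome column {outcome!r} not found; columns are {list(frame.columns)}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        bad_cols = bad.any()
        col = bad_cols[bad_cols].index[0]
        row = int(bad[col].idxmax())
        raise TableReadError(
            f"missing or non-numeric cell at row {row + 2} (1-based, incl. header), "
            f"column {col!r} in {path}"
        )
    y = numeric[outcome].to_numpy(dtype=float)
    predictors = [c for c in frame.columns if c != outcome]
    X = numeric[predictors].to_numpy(dtype=float)
    return Dataset(y=y, X=X, names=tuple(predictors))


def dataset_to_frame(dataset: Dataset, outcome: str = "y") -> pd.DataFrame:
    data = {outcome: dataset.y}
    for j, name in enumerate(dataset.names):
        data[name] = dataset.X[:, j]
    return pd.DataFrame(data)


def write_table(dataset: Dataset, path: str | Path, outcome: str = "y") -> None:
    path = Path(path)
    dataset_to_frame(dataset, outcome).to_csv(path, sep=_sep_for(path), index=False)


def read_groups(path: str | Path, dataset: Dataset) -> list[VariableGroup]:
    """Read a YAML mapping of group name -> list of column labels."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise TableReadError(f"group file {path} must be a mapping of name -> labels")
    groups = []
    for name, labels in raw.items():
        if isinstance(labels, str):
            labels = [labels]
        members = tuple(dataset.column_index(str(lbl)) for lbl in labels)
        groups.append(VariableGroup(str(name), members))
    return groups
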