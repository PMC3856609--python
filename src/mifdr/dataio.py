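"""Reading and writing expression matrices, group labels and result tables.

File dialects are deliberately minimal:

* **matrix** — tab-separated text, first row sample IDs, first column feature
  IDs, every cell numeric, no missing values;
* **labels** — two tab-separated columns ``sample_id<TAB>group`` with no
  header; exactly two distinct group names must occur.  The first group name
  encountered in the file becomes group X, which fixes the sign of the
  difference score r = mean(X) - mean(Y);
* **results** — ``#``-prefixed ``key<TAB>value`` metadata lines followed by a
  header row and one row per called feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValidationError

__all__ = ["ExpressionDataset", "ResultTable", "read_dataset", "write_results", "read_results"]


@dataclass
class ExpressionDataset:
    """A feature-by-sample numeric matrix with a two-group sample labeling.

    Attributes
    ----------
    values : (M, W) ndarray
        Feature measurements, features in rows.
    feature_ids : list of str
        Unique feature identifiers, length M.
    sample_ids : list of str
        Unique sample identifiers, length W.
    labels : (W,) ndarray of str
        Group name per sample; exactly two distinct names.
    group_x : str
        Which group plays the role of X in r = mean(X) - mean(Y).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    group_x: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise DataValidationError("values must be a 2-D feature-by-sample matrix")
        m, w = self.values.shape
        if m < 1 or w < 2:
            raise DataValidationError("need at least 1 feature and 2 samples")
        if len(self.feature_ids) != m or len(self.sample_ids) != w or len(self.labels) != w:
            raise DataValidationError("ids/labels do not match matrix shape")
        if len(set(self.feature_ids)) != m:
            raise DataValidationError("duplicated feature ID")
        if len(set(self.sample_ids)) != w:
            raise DataValidationError("duplicated sample ID")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("missing value or non-finite cell in matrix")
        groups = list(dict.fromkeys(self.labels))  # preserves first-seen order
        if len(groups) != 2:
            raise DataValidationError(
                f"labels must contain exactly two groups, found {len(groups)}"
            )
        if not self.group_x:
            self.group_x = groups[0]
        elif self.group_x not in groups:
            raise DataValidationError(f"group_x {self.group_x!r} not among labels")
        for g in groups:
            if int(np.sum(self.labels == g)) < 2:
                raise DataValidationError(f"group {g!r} has fewer than 2 samples")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def group_y(self) -> str:
        return next(g for g in dict.fromkeys(self.labels) if g != self.group_x)

    @property
    def mask_x(self) -> np.ndarray:
        """Boolean sample mask for group X."""
        return np.asarray(self.labels == self.group_x)

    def group_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the (M, N_X) and (M, N_Y) sub-matrices for groups X and Y."""
        mx = self.mask_x
        return self.values[:, mx], self.values[:, ~mx]


@dataclass
class ResultTable:
    """Called-feature table plus run metadata.

    ``table`` has columns ``feature_id, d_value, sign, called``; metadata must
    include ``n_pos``/``n_neg`` consistent with the called rows.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    _COLUMNS = ("feature_id", "d_value", "sign", "called")

    def validate(self) -> None:
        if list(self.table.columns) != list(self._COLUMNS):
            raise DataValidationError(f"result table must have columns {self._COLUMNS}")
        called = self.table[self.table["called"]]
        n_pos = int(self.meta.get("n_pos", 0))
        n_neg = int(self.meta.get("n_neg", 0))
        if int((called["sign"] == "+").sum()) != n_pos:
            raise DataValidationError("called '+' rows do not match header n_pos")
        if int((called["sign"] == "-").sum()) != n_neg:
            raise DataValidationError("called '-' rows do not match header n_neg")
        # Called + rows must carry the N+ largest d-values (ties with the
        # boundary value are resolved by the stable tie policy, so equality
        # with an uncalled row is legal but strict exceedance is not); the
        # mirror statement holds for called - rows.
        d = self.table["d_value"].to_numpy(float)
        is_pos = ((self.table["sign"] == "+") & self.table["called"]).to_numpy(bool)
        is_neg = ((self.table["sign"] == "-") & self.table["called"]).to_numpy(bool)
        if is_pos.any() and (~is_pos).any() and d[~is_pos].max() > d[is_pos].min():
            raise DataValidationError("called '+' rows are not the largest d-values")
        if is_neg.any() and (~is_neg).any() and d[~is_neg].min() < d[is_neg].max():
            raise DataValidationError("called '-' rows are not the smallest d-values")


def read_dataset(matrix_path: str | Path, labels_path: str | Path) -> ExpressionDataset:
    """Read a TSV expression matrix and its two-column labels file.

    Group X is the first group name encountered in the labels file, making the
    orientation of r = mean(X) - mean(Y) deterministic.

    Raises
    ------
    DataValidationError
        Duplicated IDs, samples missing from the labels file, more or fewer
        than two groups, non-numeric or missing cells, or a group with fewer
        than two samples.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    try:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataValidationError(f"cannot parse matrix file {matrix_path}: {exc}") from exc
    if df.index.has_duplicates:
        raise DataValidationError("duplicated feature ID in matrix")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataValidationError(f"non-numeric cell in matrix: {exc}") from exc
    if np.any(pd.isna(df.to_numpy())) or not np.all(np.isfinite(values)):
        raise DataValidationError("missing value in matrix")

    label_map: dict[str, str] = {}
    group_order: list[str] = []
    for line in labels_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise DataValidationError(f"labels file line is not two columns: {line!r}")
        sid, grp = parts[0].strip(), parts[1].strip()
        if sid in label_map:
            raise DataValidationError(f"duplicated sample {sid!r} in labels file")
        label_map[sid] = grp
        if grp not in group_order:
            group_order.append(grp)
    if len(group_order) > 2:
        raise DataValidationError(f"more than two groups in labels file: {group_order}")
    missing = [s for s in df.columns if s not in label_map]
    if missing:
        raise DataValidationError(f"samples missing from labels file: {missing}")
    labels = np.array([label_map[s] for s in df.columns], dtype=object)
    return ExpressionDataset(
        values=values,
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        labels=labels,
        group_x=group_order[0],
    )


def write_results(result: ResultTable, path: str | Path) -> None:
    """Write a :class:`ResultTable` as commented-header TSV.

    The table invariants are checked before anything is written; re-reading
    with :func:`read_results` reproduces text fields bit-exactly and reals to
    the printed precision (17 significant digits, i.e. round-trip exact for
    doubles).
    """
    result.validate()
    path = Path(path)
    lines = [f"# {k}\t{v}" for k, v in result.meta.items()]
    body = result.table.to_csv(sep="\t", index=False, float_format="%.17g")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)


def read_results(path: str | Path) -> ResultTable:
    """Inverse of :func:`write_results`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("# "):
            k, _, v = line[2:].partition("\t")
            meta[k] = v
        else:
            rows.append(line)
    from io import StringIO

    table = pd.read_csv(StringIO("\n".join(rows)), sep="\t")
    if table.empty and list(table.columns) != list(ResultTable._COLUMNS):
        table = pd.DataFrame(columns=list(ResultTable._COLUMNS))
    table["feature_id"] = table["feature_id"].astype(str)
    table["sign"] = table["sign"].astype(str)
    table["called"] = table["called"].astype(bool)
    return ResultTable(table=table, meta=meta)
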