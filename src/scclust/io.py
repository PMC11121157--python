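"""Reading, validation and preprocessing of paired omics inputs.

An *omics view* is represented throughout the package as a
:class:`pandas.DataFrame` with unique sample IDs on the index and unique
feature IDs on the columns (samples x features).  Survival data are a
DataFrame indexed by sample ID with ``time`` and ``event`` columns, and
gene-set collections are :class:`GeneSetDB` objects read from GMT files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetDB",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_survival",
    "filter_missing_features",
    "align_samples",
    "standardize_columns",
    "read_gmt",
]

#: tokens interpreted as missing values in matrix files
MISSING_TOKENS = ("", "NA", "NaN", "nan", "na", "NAN")


class OmicsIOError(ValueError):
    """Raised for malformed matrix / survival / GMT inputs."""


@dataclass
class GeneSetDB:
    """A named gene-set collection with a background universe.

    Parameters
    ----------
    sets
        Mapping from set name to member gene IDs (unique within a set).
    universe
        Background gene universe.  Defaults to the union of all members.
    planted
        Optional name of a synthetically planted set (simulation use only).
    """

    sets: dict[str, list[str]]
    universe: list[str] = field(default_factory=list)
    planted: str | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise OmicsIOError(f"gene set {name!r} is empty")
        if not self.universe:
            seen: dict[str, None] = {}
            for genes in self.sets.values():
                for g in genes:
                    seen.setdefault(g)
            self.universe = list(seen)

    def restrict(self, universe: list[str]) -> "GeneSetDB":
        """Intersect the database with a new universe, dropping emptied sets."""
        uni = [g for g in self.universe if g in set(universe)]
        uset = set(uni)
        sets = {}
        for name, genes in self.sets.items():
            kept = [g for g in genes if g in uset]
            if kept:
                sets[name] = kept
        if not sets:
            raise OmicsIOError("no gene sets survive universe restriction")
        return GeneSetDB(sets=sets, universe=uni, planted=self.planted)


def _delimiter(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise OmicsIOError(f"duplicate {what} IDs: {dups}")


def read_omics_matrix(path, orientation: str = "samples_in_rows") -> pd.DataFrame:
    """Read a delimited numeric matrix into a samples x features DataFrame.

    The file must have one header row and one leading ID column; the
    delimiter is taken from the extension (``.csv`` -> comma, else tab).
    ``orientation="features_in_rows"`` transposes after reading so that the
    returned frame is always samples x features.  Missing tokens
    (empty, ``NA``, ``NaN``) become NaN.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _delimiter(path)
    # read the header line manually: pandas silently mangles duplicate columns
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "column")
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
    )
    _check_unique(df.index, "row")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[np.flatnonzero(bad.to_numpy())[0]]
                raise OmicsIOError(
                    f"non-numeric cell at row {row!r}, column {col!r}: "
                    f"{df.loc[row, col]!r}"
                )
            df[col] = coerced
    df = df.astype(float)
    if orientation == "features_in_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return df


def write_omics_matrix(view: pd.DataFrame, path) -> None:
    """Write a samples x features frame as delimited text (inverse of read)."""
    view.to_csv(path, sep=_delimiter(path), na_rep="NA")


def read_survival(path) -> pd.DataFrame:
    """Read a survival table with columns ``sample_id``, ``time``, ``event``.

    Returns a DataFrame indexed by sample ID with ``time`` (positive float)
    and ``event`` (0/1 int) columns.
    """
    df = pd.read_csv(path, sep=_delimiter(path))
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise OmicsIOError(
            f"survival table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    _check_unique(df.index, "sample")
    df = df[["time", "event"]].astype(float)
    if (df["time"] <= 0).any():
        raise OmicsIOError("survival times must be positive")
    if not df["event"].isin([0.0, 1.0]).all():
        raise OmicsIOError("event indicator must be 0 or 1")
    df["event"] = df["event"].astype(int)
    return df


def filter_missing_features(
    view: pd.DataFrame,
    max_missing_rate: float = 0.05,
    impute: str = "mean",
) -> tuple[pd.DataFrame, list[str]]:
    """Drop features with missing rate strictly above the threshold.

    Features whose fraction of missing entries exceeds ``max_missing_rate``
    (default 5%) are removed; remaining missing cells are imputed per
    feature (``mean`` | ``median`` | ``fail``).

    Returns
    -------
    (filtered_view, dropped_feature_ids)
    """
    rates = view.isna().mean(axis=0)
    dropped = list(view.columns[rates > max_missing_rate])
    out = view.drop(columns=dropped).copy()
    if out.shape[1] == 0:
        raise OmicsIOError("no features survive missing filter")
    if out.isna().any().any():
        if impute == "fail":
            raise OmicsIOError("missing values remain and impute='fail'")
        if impute == "mean":
            fill = out.mean(axis=0)
        elif impute == "median":
            fill = out.median(axis=0)
        else:
            raise ValueError(f"unknown impute mode {impute!r}")
        out = out.fillna(fill)
    return out, dropped


def align_samples(
    x: pd.DataFrame, y: pd.DataFrame, surv: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Restrict all three inputs to their common samples, in one shared order.

    Only subjects present in both omics views and the survival table are
    retained; the common order follows the first view's index.
    """
    common = [s for s in x.index if s in set(y.index) and s in set(surv.index)]
    if len(common) < 3:
        raise OmicsIOError(
            "fewer than 3 shared samples "
            f"(x: {len(x)}, y: {len(y)}, survival: {len(surv)}, shared: {len(common)})"
        )
    return x.loc[common], y.loc[common], surv.loc[common]


def standardize_columns(view: pd.DataFrame) -> pd.DataFrame:
    """Center and scale every column to mean 0, unit sd (n-1 denominator).

    Constant columns cannot be scaled; they are dropped with a warning.
    """
    if view.isna().any().any():
        raise OmicsIOError("standardize_columns requires a complete matrix")
    if len(view) < 2:
        raise OmicsIOError("standardization needs at least 2 samples")
    sd = view.std(axis=0, ddof=1)
    constant = list(view.columns[(sd == 0) | sd.isna()])
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s): {constant[:10]}")
        view = view.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (view - view.mean(axis=0)) / sd


def read_gmt(path, universe: list[str] | None = None) -> GeneSetDB:
    """Read a GMT gene-set file (set name, description, tab-separated genes)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise OmicsIOError(
                    f"GMT line {lineno} has {len(fields)} field(s); "
                    "expected name, description, >=1 gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                warnings.warn(f"GMT set {name!r}: duplicate genes removed")
            if name in sets:
                raise OmicsIOError(f"duplicate gene-set name {name!r}")
            sets[name] = uniq
    if not sets:
        raise OmicsIOError("no gene sets in GMT file")
    return GeneSetDB(sets=sets, universe=list(universe or []))


def write_gmt(db: GeneSetDB, path) -> None:
    with open(path, "w") as fh:
        for name, genes in db.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
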