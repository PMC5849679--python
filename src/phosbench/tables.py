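"""Intensity/ratio data model, readers, normalization and filtering.

The canonical in-memory container is :class:`IntensityTable`: a feature x
sample matrix of non-negative intensities (NaN = not quantified) plus two
metadata frames.  On disk the canonical format is a long, tab-separated
table (``feature_id``, ``sample_id``, ``intensity`` plus optional metadata
columns); the MaxQuant "Phospho (STY)Sites.txt"-style wide dialect is
supported as a mapped import, never as the internal model.

All statistics downstream operate on log2 ratios between conditions,
computed within replicates.  Zero intensities are treated as missing when
forming ratios (log2 undefined; zero means "not quantified" in search
engine output).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityTable",
    "RatioTable",
    "TableFormatError",
    "TableParseError",
    "read_intensity_table",
    "write_intensity_table",
    "quantile_normalize",
    "filter_localization",
    "effective_localization_prob",
    "compute_log_ratios",
    "filter_min_quantified",
    "silac_channel_intensities",
    "knn_impute",
]

#: Canonical per-sample metadata columns.
SAMPLE_META_COLUMNS = ("method", "channel", "condition", "replicate")
#: Canonical per-feature metadata columns (all optional).
FEATURE_META_COLUMNS = ("species", "localization_prob", "localization_mbr_zero")

#: Strings readers accept as a missing value (writers emit empty fields).
NA_STRINGS = ("", "NA", "NaN", "nan")


class TableFormatError(ValueError):
    """A table is missing a mandatory column or violates the dialect."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message carries row/column coordinates."""


@dataclass
class IntensityTable:
    """Feature x sample matrix of non-negative intensities with metadata.

    Parameters
    ----------
    values
        DataFrame of intensities, one row per feature (index = unique
        feature ids), one column per sample.  NaN marks a missing value.
    feature_meta
        DataFrame indexed like ``values`` rows; recognised columns are
        ``species``, ``localization_prob`` (in [0, 1] or NaN) and
        ``localization_mbr_zero`` (bool flag marking a localization score
        of 0 that stems from match-between-runs transfer and therefore
        carries no evidence).
    sample_meta
        DataFrame indexed like ``values`` columns with columns ``method``,
        ``channel``, ``condition`` and ``replicate``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame = None
    sample_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.values.index)
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.columns)
        for col, default in (("condition", "all"), ("replicate", 1)):
            if col not in self.sample_meta.columns:
                self.sample_meta[col] = default
        self._validate()

    def _validate(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate feature ids: {dup[:5]}")
        if not self.feature_meta.index.equals(self.values.index):
            raise TableFormatError("feature_meta index does not match values rows")
        if not self.sample_meta.index.equals(self.values.columns):
            raise TableFormatError("sample_meta index does not match values columns")
        arr = self.values.to_numpy()
        if np.nanmin(arr, initial=0.0) < 0:
            raise TableFormatError("negative intensities are not allowed")
        if self.sample_meta["condition"].isna().any():
            raise TableFormatError("every sample needs a condition label")
        if self.sample_meta["replicate"].isna().any():
            raise TableFormatError("every sample needs a replicate index")

    # -- convenience ------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, keep: Sequence) -> "IntensityTable":
        keep = pd.Index(keep)
        return IntensityTable(
            self.values.loc[keep].copy(),
            self.feature_meta.loc[keep].copy(),
            self.sample_meta.copy(),
        )

    def copy(self) -> "IntensityTable":
        return IntensityTable(
            self.values.copy(), self.feature_meta.copy(), self.sample_meta.copy()
        )


@dataclass
class RatioTable:
    """Feature x (contrast, replicate) matrix of log2 ratios.

    ``log2_ratios`` columns are labelled ``{contrast}:r{replicate}`` (or
    just the contrast for unpaired ratios); NaN marks a ratio that could
    not be formed because either side was missing or zero.
    """

    log2_ratios: pd.DataFrame
    contrast: str = ""
    replicates: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.log2_ratios = self.log2_ratios.astype(float)
        if self.log2_ratios.index.has_duplicates:
            raise TableFormatError("duplicate feature ids in ratio table")
        arr = self.log2_ratios.to_numpy()
        if np.isinf(arr).any():
            raise TableFormatError("log2 ratios must be finite where present")

    @property
    def feature_ids(self) -> pd.Index:
        return self.log2_ratios.index

    def copy(self) -> "RatioTable":
        return RatioTable(self.log2_ratios.copy(), self.contrast, self.replicates)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

#: Default column mapping for the MaxQuant sites dialect.  ``intensity_pattern``
#: must contain one capture group naming the sample.
DEFAULT_MAXQUANT_MAPPING: dict = {
    "id_column": "id",
    "intensity_pattern": r"^Intensity (.+)$",
    "localization_column": "Localization prob",
    "reverse_column": "Reverse",
    "contaminant_column": "Potential contaminant",
    "species_column": None,
}


def read_intensity_table(
    path,
    dialect: str = "canonical-long",
    mapping: Mapping | None = None,
) -> IntensityTable:
    """Read a tab-separated intensity table.

    ``canonical-long`` expects columns ``feature_id``, ``sample_id``,
    ``intensity`` plus optional per-feature (``species``,
    ``localization_prob``, ``localization_mbr_zero``) and per-sample
    (``method``, ``channel``, ``condition``, ``replicate``) metadata
    columns that must be constant within a feature/sample respectively.

    ``maxquant-sites`` imports a MaxQuant "Phospho (STY)Sites.txt"-style
    wide table: intensity columns are matched against
    ``mapping["intensity_pattern"]``, the localization probability column
    is parsed, and rows marked "+" in the reverse/contaminant columns are
    dropped.
    """
    if dialect == "canonical-long":
        return _read_canonical_long(path)
    if dialect == "maxquant-sites":
        return _read_maxquant_sites(path, mapping)
    raise TableFormatError(f"unknown dialect {dialect!r}")


def _numeric(series: pd.Series, column: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & ~series.astype(str).str.strip().isin(NA_STRINGS)
    if bad.any():
        row = bad.idxmax()
        raise TableParseError(
            f"non-numeric value {series[row]!r} in column {column!r}, row {row}"
        )
    return out


def _read_canonical_long(path) -> IntensityTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=list(NA_STRINGS))
    for col in ("feature_id", "sample_id", "intensity"):
        if col not in df.columns:
            raise TableFormatError(f"canonical-long table lacks mandatory column {col!r}")
    df["intensity"] = _numeric(df["intensity"], "intensity")
    if df.duplicated(["feature_id", "sample_id"]).any():
        raise TableFormatError("duplicate (feature_id, sample_id) pairs")
    values = df.pivot(index="feature_id", columns="sample_id", values="intensity")
    # preserve file order of first appearance
    values = values.reindex(
        index=pd.unique(df["feature_id"]), columns=pd.unique(df["sample_id"])
    )
    values.index.name = None
    values.columns.name = None

    fmeta = pd.DataFrame(index=values.index)
    for col in FEATURE_META_COLUMNS:
        if col in df.columns:
            per = df.drop_duplicates("feature_id").set_index("feature_id")[col]
            if col == "localization_prob":
                per = _numeric(per, col)
            elif col == "localization_mbr_zero":
                per = per.isin(("True", "true", "1", "yes"))
            fmeta[col] = per.reindex(values.index)
    smeta = pd.DataFrame(index=values.columns)
    for col in SAMPLE_META_COLUMNS:
        if col in df.columns:
            per = df.drop_duplicates("sample_id").set_index("sample_id")[col]
            if col == "replicate":
                per = _numeric(per, col).astype("Int64")
            smeta[col] = per.reindex(values.columns)
    return IntensityTable(values, fmeta, smeta)


def _read_maxquant_sites(path, mapping: Mapping | None) -> IntensityTable:
    mp = dict(DEFAULT_MAXQUANT_MAPPING)
    if mapping:
        mp.update(mapping)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=list(NA_STRINGS))
    idcol = mp["id_column"]
    if idcol not in df.columns:
        raise TableFormatError(f"maxquant-sites table lacks mandatory column {idcol!r}")
    pattern = re.compile(mp["intensity_pattern"])
    intensity_cols = {c: pattern.match(c).group(1) for c in df.columns if pattern.match(c)}
    if not intensity_cols:
        raise TableFormatError(
            f"no intensity columns match pattern {mp['intensity_pattern']!r}"
        )
    # drop decoy / contaminant rows
    for key in ("reverse_column", "contaminant_column"):
        col = mp[key]
        if col and col in df.columns:
            df = df[df[col].fillna("") != "+"]
    df = df.set_index(idcol)
    if df.index.has_duplicates:
        raise TableFormatError("duplicate ids in maxquant-sites table")

    values = pd.DataFrame(index=df.index)
    for col, sample in intensity_cols.items():
        values[sample] = _numeric(df[col], col)
    values.index.name = None

    fmeta = pd.DataFrame(index=values.index)
    loc_col = mp["localization_column"]
    if loc_col and loc_col in df.columns:
        fmeta["localization_prob"] = _numeric(df[loc_col], loc_col)
    if mp.get("species_column") and mp["species_column"] in df.columns:
        fmeta["species"] = df[mp["species_column"]]
    return IntensityTable(values, fmeta, None)


def write_intensity_table(table: IntensityTable, path) -> None:
    """Write an IntensityTable as a canonical long TSV (empty field = missing)."""
    long = table.values.stack(future_stack=True).rename("intensity").reset_index()
    long.columns = ["feature_id", "sample_id", "intensity"]
    for col in FEATURE_META_COLUMNS:
        if col in table.feature_meta.columns:
            long[col] = table.feature_meta[col].reindex(long["feature_id"]).to_numpy()
    for col in SAMPLE_META_COLUMNS:
        if col in table.sample_meta.columns:
            long[col] = table.sample_meta[col].reindex(long["sample_id"]).to_numpy()
    long.to_csv(path, sep="\t", index=False, na_rep="")


def write_ratio_table(ratios: RatioTable, path) -> None:
    out = ratios.log2_ratios.copy()
    out.insert(0, "feature_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_ratio_table(path, contrast: str = "") -> RatioTable:
    df = pd.read_csv(path, sep="\t", na_values=list(NA_STRINGS))
    if "feature_id" not in df.columns:
        raise TableFormatError("ratio table lacks mandatory column 'feature_id'")
    df = df.set_index("feature_id")
    df.index.name = None
    return RatioTable(df, contrast=contrast)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def quantile_normalize(table: IntensityTable) -> IntensityTable:
    """Quantile-normalize sample columns to a common reference distribution.

    Every output column acquires the same multiset of non-missing values:
    the per-rank means of the input columns' order statistics.  Ties within
    a column receive the mean of the target values of their tied ranks;
    missing entries stay missing (normalization runs over present values
    only, per column).  Columns with unequal numbers of present values are
    mapped through linear interpolation of the reference quantile curve.
    """
    X = table.values.to_numpy(dtype=float)
    n_feat, n_samp = X.shape
    if n_samp < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    present = ~np.isnan(X)
    counts = present.sum(axis=0)
    if (counts == 0).any():
        bad = table.sample_ids[np.flatnonzero(counts == 0)[0]]
        raise ValueError(f"sample {bad!r} has no non-missing values")

    m = int(counts.max())
    grid = np.linspace(0.0, 1.0, m)
    curves = np.empty((n_samp, m))
    for j in range(n_samp):
        vals = np.sort(X[present[:, j], j])
        if vals.size == m:
            curves[j] = vals
        else:
            curves[j] = np.interp(grid, np.linspace(0.0, 1.0, vals.size), vals)
    reference = curves.mean(axis=0)

    out = X.copy()
    for j in range(n_samp):
        idx = np.flatnonzero(present[:, j])
        vals = X[idx, j]
        n = vals.size
        if n == m:
            targets = reference
        else:
            targets = np.interp(np.linspace(0.0, 1.0, n), grid, reference)
        order = np.argsort(vals, kind="mergesort")
        assigned = np.empty(n)
        sorted_vals = vals[order]
        # tie groups get the mean target of their rank slots
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        start = 0
        for stop in list(boundaries) + [n]:
            assigned[start:stop] = targets[start:stop].mean()
            start = stop
        col = np.empty(n)
        col[order] = assigned
        out[idx, j] = col
    return IntensityTable(
        pd.DataFrame(out, index=table.feature_ids, columns=table.sample_ids),
        table.feature_meta.copy(),
        table.sample_meta.copy(),
    )


# ---------------------------------------------------------------------------
# Filters and derivations
# ---------------------------------------------------------------------------

def effective_localization_prob(
    probs: Sequence[float], mbr_zero: Sequence[bool] | None = None
) -> float:
    """Reduce per-replicate localization scores to one per-feature value.

    The effective score is the minimum over replicates — the conservative
    convention for multi-run site tables — after discarding scores of
    exactly 0 that are flagged as originating from match-between-runs
    transfer (those carry no localization evidence).  Returns NaN when no
    informative score remains.
    """
    probs = np.asarray(probs, dtype=float)
    if mbr_zero is None:
        mbr_zero = np.zeros(probs.shape, dtype=bool)
    mbr_zero = np.asarray(mbr_zero, dtype=bool)
    keep = ~np.isnan(probs) & ~(mbr_zero & (probs == 0.0))
    if not keep.any():
        return float("nan")
    return float(probs[keep].min())


def filter_localization(table: IntensityTable, threshold: float) -> IntensityTable:
    """Keep features whose localization probability is >= ``threshold``.

    A probability of exactly 0 flagged ``localization_mbr_zero`` is treated
    as missing evidence rather than a failing score.  Features with no
    localization evidence at all are dropped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if "localization_prob" not in table.feature_meta.columns:
        raise TableFormatError("feature_meta lacks 'localization_prob'")
    probs = table.feature_meta["localization_prob"].astype(float).copy()
    if "localization_mbr_zero" in table.feature_meta.columns:
        flag = table.feature_meta["localization_mbr_zero"].fillna(False).astype(bool)
        probs[flag & (probs == 0.0)] = np.nan
    keep = table.feature_ids[(probs >= threshold).to_numpy(dtype=bool)]
    return table.subset_features(keep)


def compute_log_ratios(
    table: IntensityTable,
    numerator_condition: str,
    denominator_condition: str,
    pair_by_replicate: bool = True,
) -> RatioTable:
    """log2(numerator / denominator) per feature, within replicates.

    Ratios are formed between samples of the two conditions sharing a
    replicate index (the within-replicate convention of paired designs).
    A ratio is missing when either side is missing or zero.  With
    ``pair_by_replicate=False`` a single column of condition-mean ratios
    is returned instead.
    """
    cond = table.sample_meta["condition"]
    for label in (numerator_condition, denominator_condition):
        if label not in set(cond):
            raise ValueError(f"unknown condition label {label!r}")
    num_cols = table.sample_ids[(cond == numerator_condition).to_numpy(dtype=bool)]
    den_cols = table.sample_ids[(cond == denominator_condition).to_numpy(dtype=bool)]
    contrast = f"{numerator_condition}/{denominator_condition}"

    vals = table.values.replace(0.0, np.nan)
    if not pair_by_replicate:
        ratio = np.log2(vals[num_cols].mean(axis=1) / vals[den_cols].mean(axis=1))
        return RatioTable(ratio.to_frame(contrast), contrast=contrast)

    rep = table.sample_meta["replicate"]
    num_by_rep = {rep[c]: c for c in num_cols}
    den_by_rep = {rep[c]: c for c in den_cols}
    common = sorted(set(num_by_rep) & set(den_by_rep), key=lambda r: (str(r), r is None))
    if not common:
        raise ValueError(
            f"no shared replicate indices between {numerator_condition!r} "
            f"and {denominator_condition!r}"
        )
    cols = {}
    for r in common:
        cols[f"{contrast}:r{r}"] = np.log2(
            vals[num_by_rep[r]] / vals[den_by_rep[r]]
        )
    return RatioTable(pd.DataFrame(cols), contrast=contrast, replicates=tuple(common))


def filter_min_quantified(ratios: RatioTable, min_replicates: int) -> RatioTable:
    """Keep features quantified (non-missing ratio) in >= ``min_replicates`` columns."""
    n_cols = ratios.log2_ratios.shape[1]
    if not 1 <= min_replicates <= n_cols:
        raise ValueError(
            f"min_replicates must be in [1, {n_cols}], got {min_replicates}"
        )
    counts = ratios.log2_ratios.notna().sum(axis=1)
    keep = counts >= min_replicates
    return RatioTable(
        ratios.log2_ratios.loc[keep].copy(), ratios.contrast, ratios.replicates
    )


def silac_channel_intensities(total, ratio_m_over_l, ratio_h_over_l):
    """Split a total SILAC triplet intensity into (light, medium, heavy).

    Solves light * (1 + rML + rHL) = total, so the three channel
    intensities sum exactly to the total and reproduce the measured
    medium/light and heavy/light ratios.  Accepts scalars or arrays.
    """
    total = np.asarray(total, dtype=float)
    rml = np.asarray(ratio_m_over_l, dtype=float)
    rhl = np.asarray(ratio_h_over_l, dtype=float)
    if np.any(total < 0):
        raise ValueError("total intensity must be non-negative")
    if np.any(rml <= 0) or np.any(rhl <= 0):
        raise ValueError("SILAC ratios must be positive")
    light = total / (1.0 + rml + rhl)
    medium = light * rml
    heavy = light * rhl
    if total.ndim == 0:
        return float(light), float(medium), float(heavy)
    return light, medium, heavy


def knn_impute(ratios: RatioTable, k: int = 10) -> RatioTable:
    """Nearest-neighbour imputation of missing log2 ratios.

    For each hole, the k nearest features (Euclidean distance over the
    columns jointly observed with the target feature, requiring a present
    value in the hole's column) donate the mean of their values in that
    column.  Observed entries are never altered.  Holes with no eligible
    neighbour are left missing and reported via a warning; a ``k`` larger
    than the eligible neighbour count is clamped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = ratios.log2_ratios.to_numpy(dtype=float)
    n, p = X.shape
    present = ~np.isnan(X)
    out = X.copy()
    unimputed: list[tuple] = []
    clamped = False
    holes = np.argwhere(~present)
    for i, j in holes:
        joint = present[i] & present  # (n, p) columns shared with row i
        eligible = np.flatnonzero(present[:, j] & (np.arange(n) != i) & joint.any(axis=1))
        if eligible.size == 0:
            unimputed.append((ratios.feature_ids[i], ratios.log2_ratios.columns[j]))
            continue
        diffs = X[eligible] - X[i]
        diffs[~joint[eligible]] = 0.0
        dists = np.sqrt(np.nansum(diffs**2, axis=1))
        kk = min(k, eligible.size)
        if kk < k:
            clamped = True
        nearest = eligible[np.argsort(dists, kind="mergesort")[:kk]]
        out[i, j] = X[nearest, j].mean()
    if clamped:
        warnings.warn("k exceeded available neighbours; clamped", stacklevel=2)
    if unimputed:
        warnings.warn(
            f"{len(unimputed)} entries had no computable neighbour and stay missing: "
            f"{unimputed[:5]}",
            stacklevel=2,
        )
    return RatioTable(
        pd.DataFrame(out, index=ratios.feature_ids, columns=ratios.log2_ratios.columns),
        ratios.contrast,
        ratios.replicates,
    )
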