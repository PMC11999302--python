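"""Raw indicator rates → comparable, direction-aligned z-scores.

Each indicator column x is standardized to Z = (x − μ)/σ so that columns
measured on different scales (percentages, counts per family, land-cover
shares) become comparable, with mean 0 and standard deviation 1.  σ is the
sample standard deviation (denominator N−1); μ and σ are recorded per column
so the transform is reproducible.  After standardization, columns whose raw
direction is "more is safer" (tree cover, volunteering) are negated so that
larger z always means more vulnerable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateColumnError, MissingDataError, SviError, TableError
from .hierarchy import VULNERABILITY_REDUCING, HierarchyConfig

__all__ = [
    "IndicatorTable",
    "ZScoreMatrix",
    "MissingReport",
    "compute_rate",
    "zscore_normalize",
    "align_direction",
    "handle_missing",
]

MISSING_POLICIES = ("error", "median_impute", "renormalize_weights")


@dataclass(frozen=True)
class IndicatorTable:
    """Area × indicator matrix of raw rates.

    Wraps a float DataFrame whose index is the (unique, string) area ids and
    whose columns are indicator ids; missing cells are NaN.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.df.index
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique().tolist())
            raise TableError(f"duplicate area ids: {dupes}")
        object.__setattr__(self, "df", self.df.astype(float))

    @property
    def area_ids(self) -> tuple[str, ...]:
        return tuple(str(a) for a in self.df.index)

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(self.df.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.df.isna()

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_csv(
        cls,
        path_or_buf,
        *,
        sep: str | None = None,
        cfg: HierarchyConfig | None = None,
    ) -> "IndicatorTable":
        """Read a delimited table: first column area_id, header = indicator ids.

        Comma is the default delimiter, tab is accepted (``sep=None`` sniffs).
        Empty fields and "NA" are missing.  When ``cfg`` is given, columns not
        declared in the hierarchy are rejected.
        """
        df = pd.read_csv(
            path_or_buf,
            sep=sep,
            engine="python" if sep is None else "c",
            index_col=0,
            na_values=["NA"],
            keep_default_na=True,
            dtype={0: str},
        )
        df.index = df.index.astype(str).str.strip()
        if cfg is not None:
            unknown = sorted(set(df.columns) - set(cfg.indicator_ids))
            if unknown:
                raise TableError(
                    f"table columns not declared in hierarchy {cfg.name!r}: {unknown}"
                )
        table = cls(df)
        table.validate_ranges()
        return table

    def to_csv(self, path_or_buf) -> None:
        out = self.df.copy()
        out.index.name = "area_id"
        out.to_csv(path_or_buf, na_rep="NA")

    def validate_ranges(self) -> None:
        """Warn (never error) on percent-like values outside [0, 100]; shares
        expressed as proportions in [0, 1] are fine."""
        for col in self.df.columns:
            vals = self.df[col].dropna()
            if len(vals) and ((vals < -1e-9).any() or (vals > 100 + 1e-9).any()):
                warnings.warn(
                    f"indicator {col!r} has values outside [0, 100]; "
                    "check its scale",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class ZScoreMatrix:
    """Standardized (and possibly direction-aligned) indicator matrix.

    ``normalization_params`` has one row per indicator with the μ, σ used and
    whether the column was flipped during alignment.
    """

    df: pd.DataFrame
    normalization_params: pd.DataFrame
    aligned: bool = False

    @property
    def area_ids(self) -> tuple[str, ...]:
        return tuple(str(a) for a in self.df.index)

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(self.df.columns)


@dataclass(frozen=True)
class MissingReport:
    policy: str
    imputed_cells: tuple[tuple[str, str], ...] = ()  # (area_id, indicator_id)
    missing_cells: tuple[tuple[str, str], ...] = ()
    renormalize: bool = False


# ---------------------------------------------------------------------------

def compute_rate(numerators, denominators, scale: str = "percent") -> np.ndarray:
    """Per-area rate = numerator/denominator, on the percent or proportion scale.

    Zero denominators yield a missing rate with a warning; negative counts are
    a domain error.
    """
    if scale not in ("percent", "proportion"):
        raise ValueError(f"scale must be 'percent' or 'proportion', got {scale!r}")
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    if num.shape != den.shape:
        raise ValueError("numerators and denominators must have the same shape")
    if (num[~np.isnan(num)] < 0).any() or (den[~np.isnan(den)] < 0).any():
        raise SviError("counts must be non-negative")
    out = np.full(num.shape, np.nan)
    zero = den == 0
    if (zero & ~np.isnan(num)).any():
        warnings.warn(
            f"{int((zero & ~np.isnan(num)).sum())} rate(s) undefined "
            "(zero denominator); set to missing",
            stacklevel=2,
        )
    ok = ~zero & ~np.isnan(num) & ~np.isnan(den)
    out[ok] = num[ok] / den[ok] * (100.0 if scale == "percent" else 1.0)
    return out


def _column_params(col: pd.Series, name: str, policy: str) -> tuple[float, float] | None:
    vals = col.dropna()
    if len(vals) < 2 or float(vals.std(ddof=1)) == 0.0:
        if policy == "drop":
            warnings.warn(
                f"dropping degenerate indicator column {name!r} "
                "(constant or <2 observed values)",
                stacklevel=3,
            )
            return None
        raise DegenerateColumnError(
            f"indicator {name!r} is degenerate: constant or fewer than two "
            "observed values; z-scores are undefined"
        )
    return float(vals.mean()), float(vals.std(ddof=1))


def zscore_normalize(table: IndicatorTable, *, on_degenerate: str = "error") -> ZScoreMatrix:
    """Standardize every column to mean 0, sample sd 1 (missing cells stay NaN).

    ``on_degenerate`` is ``"error"`` (default) or ``"drop"`` for constant /
    under-observed columns.
    """
    if on_degenerate not in ("error", "drop"):
        raise ValueError("on_degenerate must be 'error' or 'drop'")
    cols: dict[str, pd.Series] = {}
    params: dict[str, dict] = {}
    for name in table.df.columns:
        p = _column_params(table.df[name], name, on_degenerate)
        if p is None:
            continue
        mu, sigma = p
        cols[name] = (table.df[name] - mu) / sigma
        params[name] = {"mu": mu, "sigma": sigma, "ddof": 1, "flipped": False}
    if not cols:
        raise TableError("no standardizable columns in table")
    zdf = pd.DataFrame(cols, index=table.df.index)
    pdf = pd.DataFrame.from_dict(params, orient="index")
    pdf.index.name = "indicator_id"
    return ZScoreMatrix(df=zdf, normalization_params=pdf, aligned=False)


def align_direction(z: ZScoreMatrix, cfg: HierarchyConfig) -> ZScoreMatrix:
    """Flip vulnerability-reducing columns so larger z = more vulnerable.

    Because z is odd in (x − μ), negating the z column is equivalent to
    having negated the raw values before standardizing.
    """
    directions = cfg.directions()
    missing = sorted(set(z.df.columns) - set(directions))
    if missing:
        raise SviError(
            f"no configured direction for columns: {missing} "
            f"(hierarchy {cfg.name!r})"
        )
    out = z.df.copy()
    params = z.normalization_params.copy()
    for col in out.columns:
        if directions[col] == VULNERABILITY_REDUCING:
            out[col] = -out[col]
            params.loc[col, "flipped"] = ~params.loc[col, "flipped"]
    return ZScoreMatrix(df=out, normalization_params=params, aligned=True)


def handle_missing(
    table: IndicatorTable, policy: str = "renormalize_weights"
) -> tuple[IndicatorTable, MissingReport]:
    """Apply the declared missing-data policy to a raw table.

    error
        abort on the first missing cell, naming area and indicator.
    median_impute
        fill each missing cell with its column median and list the cells.
    renormalize_weights (default)
        leave values untouched; the weighting stage redistributes each
        domain's weight over the indicators observed for that area.
    """
    if policy not in MISSING_POLICIES:
        raise ValueError(
            f"unknown missing-data policy {policy!r}; choose from {MISSING_POLICIES}"
        )
    mask = table.missing_mask
    cells = tuple(
        (str(area), str(col))
        for col in mask.columns
        for area in mask.index[mask[col]]
    )
    if not cells:
        return table, MissingReport(policy=policy)
    if policy == "error":
        area, col = cells[0]
        raise MissingDataError(
            f"missing value for area {area!r}, indicator {col!r} "
            f"({len(cells)} missing cell(s) total) under policy 'error'"
        )
    if policy == "median_impute":
        df = table.df.copy()
        for col in df.columns:
            if df[col].isna().any():
                df[col] = df[col].fillna(df[col].median())
        return IndicatorTable(df), MissingReport(
            policy=policy, imputed_cells=cells, missing_cells=cells
        )
    return table, MissingReport(policy=policy, missing_cells=cells, renormalize=True)
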