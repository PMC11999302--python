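"""Dimension roll-up, ordinal vulnerability classes and index comparison.

Domain scores sum into the three dimension scores (sensitivity, adaptive
capacity, enhanced exposure), which in turn sum to the overall SVI — so the
per-dimension maps partition the index.  Areas are then binned into ordinal
classes, by default seven standard-deviation bands on the standardized SVI
labelled "extremely low" through "extremely high"; septile (quantile) breaks
are the alternative.  A reference index (e.g. an area deprivation index) can
be compared by Spearman rank agreement, class cross-tabulation and per-area
rank discordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ClassificationError, ComparisonError, TierRoutingError
from .hierarchy import HierarchyConfig
from .normalize import ZScoreMatrix
from .weighting import ScoreTable, TierAssignment

__all__ = [
    "DEFAULT_LABELS",
    "ClassificationScheme",
    "SVIResult",
    "ComparisonReport",
    "dimension_scores",
    "classify_svi",
    "compare_indices",
    "assemble_result",
]

DEFAULT_LABELS = (
    "extremely low",
    "very low",
    "relatively low",
    "average",
    "relatively high",
    "very high",
    "extremely high",
)
_DEFAULT_SD_BOUNDARIES = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordinal class scheme: ``sd_bands`` bins the internally standardized SVI
    at fixed boundaries; ``quantiles`` uses equal-count breaks."""

    mode: str = "sd_bands"
    boundaries: tuple[float, ...] = _DEFAULT_SD_BOUNDARIES
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if self.mode not in ("sd_bands", "quantiles"):
            raise ClassificationError(
                f"mode must be 'sd_bands' or 'quantiles', got {self.mode!r}"
            )
        if self.mode == "sd_bands":
            if len(self.labels) != len(self.boundaries) + 1:
                raise ClassificationError(
                    "labels count must be boundaries count + 1 "
                    f"({len(self.labels)} vs {len(self.boundaries)})"
                )
            if any(
                b >= c for b, c in zip(self.boundaries, self.boundaries[1:])
            ):
                raise ClassificationError("boundaries must be strictly increasing")


@dataclass(frozen=True)
class SVIResult:
    """Full per-area output: stand-alone indicator views (the aligned
    z-columns, untouched), domain and dimension scores, overall SVI, ordinal
    class, tier and caveats."""

    indicator_views: pd.DataFrame
    domain_scores: pd.DataFrame
    dimension_scores: pd.DataFrame
    svi: pd.Series
    class_labels: pd.Series
    tier: TierAssignment
    caveats: tuple[str, ...] = ()

    @property
    def area_ids(self) -> tuple[str, ...]:
        return tuple(str(a) for a in self.svi.index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat(
            [
                self.indicator_views.add_prefix("z__"),
                self.domain_scores.add_prefix("domain__"),
                self.dimension_scores.add_prefix("dimension__"),
            ],
            axis=1,
        )
        out["svi"] = self.svi
        out["svi_class"] = self.class_labels
        out["tier"] = self.tier.tier
        out["caveats"] = "; ".join(self.caveats)
        out.index.name = "area_id"
        return out


def dimension_scores(st: ScoreTable, cfg: HierarchyConfig) -> pd.DataFrame:
    """Per-area dimension scores = sum of each dimension's domain scores.

    Tier 4 has no domains, hence no dimension scores."""
    if st.contributing_weights is None or st.domain_scores.shape[1] == 0:
        raise TierRoutingError(
            "dimension scores are undefined for the tier-4 principal-component "
            "index (it ignores domains and dimensions)"
        )
    out = pd.DataFrame(index=st.domain_scores.index, dtype=float)
    for dim in cfg.dimensions:
        doms = [
            d.domain_id
            for d in cfg.dimension_domains(dim.dimension_id)
            if d.domain_id in st.domain_scores.columns
        ]
        out[dim.dimension_id] = (
            st.domain_scores[doms].sum(axis=1) if doms else 0.0
        )
    return out


def classify_svi(svi: pd.Series, scheme: ClassificationScheme | None = None) -> pd.Series:
    """Assign ordinal labels: left-closed right-open intervals, deterministic
    at boundaries; equal scores always share a class."""
    scheme = scheme or ClassificationScheme()
    values = svi.astype(float)
    if scheme.mode == "sd_bands":
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        standardized = (
            (values - values.mean()) / sd if sd > 0 else values * 0.0
        )
        boundaries = np.asarray(scheme.boundaries, dtype=float)
        idx = np.searchsorted(boundaries, standardized.to_numpy(), side="right")
    else:
        k = len(scheme.labels)
        if len(values) < k:
            raise ClassificationError(
                f"quantile mode needs at least {k} areas, got {len(values)}"
            )
        qs = np.quantile(values.to_numpy(), [i / k for i in range(1, k)])
        if np.unique(qs).size < qs.size or values.nunique() == 1:
            raise ClassificationError(
                "degenerate score distribution: quantile boundaries are not "
                "strictly increasing; use sd_bands"
            )
        idx = np.searchsorted(qs, values.to_numpy(), side="right")
    labels = pd.Series(
        pd.Categorical.from_codes(
            idx, categories=list(scheme.labels), ordered=True
        ),
        index=values.index,
        name="svi_class",
    )
    return labels


@dataclass(frozen=True)
class ComparisonReport:
    spearman: float
    p_value: float
    n_shared: int
    crosstab: pd.DataFrame | None
    discordance: pd.DataFrame = field(repr=False, default=None)

    def most_discordant(self, n: int = 5) -> pd.DataFrame:
        return self.discordance.head(n)


def compare_indices(a: pd.Series, b: pd.Series) -> ComparisonReport:
    """Rank agreement between two per-area indices joined on area id.

    Numeric inputs give the Spearman correlation and a per-area rank
    discordance table (sorted by |rank difference|) pointing at the areas
    where the two indices disagree most.  When both inputs are categorical /
    non-numeric labels, a class cross-tabulation is added and Spearman is
    computed on the label codes.
    """
    a = pd.Series(a).copy()
    b = pd.Series(b).copy()
    a.index = a.index.astype(str).str.strip()
    b.index = b.index.astype(str).str.strip()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ComparisonError(
            f"need at least 3 shared areas to compare, got {len(shared)}"
        )
    av, bv = a.loc[shared], b.loc[shared]

    def _codes(s: pd.Series) -> tuple[pd.Series, bool]:
        if pd.api.types.is_numeric_dtype(s):
            return s.astype(float), False
        if isinstance(s.dtype, pd.CategoricalDtype) and s.cat.ordered:
            return pd.Series(s.cat.codes, index=s.index, dtype=float), True
        return pd.Series(pd.factorize(s, sort=True)[0], index=s.index, dtype=float), True

    ac, a_lab = _codes(av)
    bc, b_lab = _codes(bv)
    rho, pval = stats.spearmanr(ac, bc)
    crosstab = pd.crosstab(av, bv) if (a_lab and b_lab) else None
    ranks = pd.DataFrame(
        {
            "rank_a": ac.rank(method="average"),
            "rank_b": bc.rank(method="average"),
        },
        index=shared,
    )
    ranks["rank_diff"] = ranks["rank_a"] - ranks["rank_b"]
    ranks["abs_rank_diff"] = ranks["rank_diff"].abs()
    ranks = ranks.sort_values(
        ["abs_rank_diff"], ascending=False, kind="stable"
    )
    return ComparisonReport(
        spearman=float(rho),
        p_value=float(pval),
        n_shared=int(len(shared)),
        crosstab=crosstab,
        discordance=ranks,
    )


def assemble_result(
    z: ZScoreMatrix,
    st: ScoreTable,
    cfg: HierarchyConfig | None,
    tier: TierAssignment,
    scheme: ClassificationScheme | None = None,
) -> SVIResult:
    """Bundle the stage outputs into one SVIResult (tier 4 gets empty domain
    and dimension tables)."""
    if tier.tier == 4 or cfg is None:
        dims = pd.DataFrame(index=st.svi.index)
    else:
        dims = dimension_scores(st, cfg)
    return SVIResult(
        indicator_views=z.df,
        domain_scores=st.domain_scores,
        dimension_scores=dims,
        svi=st.svi,
        class_labels=classify_svi(st.svi, scheme),
        tier=tier,
        caveats=tuple(tier.robustness_caveats) + tuple(st.flags),
    )
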