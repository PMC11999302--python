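"""Tier classification and tiered weighting.

The data situation of a study area falls into one of four tiers:

* **Tier 1** — the ideal scenario: every dimension holds at least two
  domains and no domain is depleted.  Each domain's weight sums to 1,
  split equally over its m indicators: W = 1/m.
* **Tier 2** — some domains are depleted (missing required indicators, or
  reduced to a lone indicator out of a larger design).  Depleted domains get
  half weight: W = 1/(2m) there, 1/m elsewhere.
* **Tier 3** — some dimension is carried by a single available domain.
  Weights are built exactly as in tier 2, but the index is flagged as less
  robust.
* **Tier 4** — a whole dimension is missing; the hierarchy cannot support a
  vulnerability index and the principal-component fallback
  (:mod:`svikit.pca`) takes over.

The overall SVI of an area is the sum over domains of the weighted sums of
its aligned z-scores: SVI = Σ_n Σ_m W_mn · z_m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, TierRoutingError
from .hierarchy import AvailabilityProfile
from .normalize import MissingReport, ZScoreMatrix

__all__ = [
    "TierAssignment",
    "WeightScheme",
    "ScoreTable",
    "classify_tier",
    "build_weights",
    "apply_weights",
]


@dataclass(frozen=True)
class TierAssignment:
    tier: int
    reasons: tuple[str, ...]
    robustness_caveats: tuple[str, ...] = ()


@dataclass(frozen=True)
class WeightScheme:
    """Per-indicator weights W, keyed (domain_id, indicator_id).

    Unavailable declared indicators carry weight 0; every available one a
    strictly positive weight.  ``domain_weight_sums`` is 1 per domain (tier 1)
    or 0.5 for depleted domains (tiers 2–3).
    """

    weights: dict[tuple[str, str], float]
    tier: TierAssignment
    domain_weight_sums: dict[str, float]

    def domain_indicator_weights(self, domain_id: str) -> dict[str, float]:
        return {
            ind: w
            for (dom, ind), w in self.weights.items()
            if dom == domain_id and w > 0
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"domain_id": dom, "indicator_id": ind, "weight": w, "tier": self.tier.tier}
            for (dom, ind), w in self.weights.items()
        ]
        return pd.DataFrame(rows, columns=["domain_id", "indicator_id", "weight", "tier"])


@dataclass(frozen=True)
class ScoreTable:
    domain_scores: pd.DataFrame  # area × domain
    svi: pd.Series  # per area
    contributing_weights: WeightScheme | None
    flags: tuple[str, ...] = ()

    @property
    def area_ids(self) -> tuple[str, ...]:
        return tuple(str(a) for a in self.svi.index)


def classify_tier(profile: AvailabilityProfile) -> TierAssignment:
    """Assign the tier for an availability profile, precedence 4 > 3 > 2 > 1."""
    empty_dims = sorted(
        d for d, c in profile.available_domain_count.items() if c == 0
    )
    single_dims = sorted(
        d for d, c in profile.available_domain_count.items() if c == 1
    )
    depleted = sorted(profile.depleted_domains)
    if empty_dims:
        return TierAssignment(
            tier=4,
            reasons=tuple(f"dimension {d!r} has no available domain" for d in empty_dims),
            robustness_caveats=(
                "not a Social Vulnerability Index: one or more vulnerability "
                "dimensions are unrepresented; principal-component index only",
            ),
        )
    if single_dims:
        reasons = tuple(
            f"dimension {d!r} is carried by a single available domain"
            for d in single_dims
        )
        if depleted:
            reasons = reasons + tuple(f"domain {d!r} is depleted" for d in depleted)
        return TierAssignment(
            tier=3,
            reasons=reasons,
            robustness_caveats=(
                "index rests on single-domain dimension(s); interpret with care",
            ),
        )
    if depleted:
        return TierAssignment(
            tier=2,
            reasons=tuple(f"domain {d!r} is depleted" for d in depleted),
        )
    return TierAssignment(tier=1, reasons=("all domains complete per design",))


def build_weights(profile: AvailabilityProfile, tier: TierAssignment) -> WeightScheme:
    """Construct W for tiers 1–3: W = 1/m per available indicator, halved to
    1/(2m) inside depleted domains (tiers 2–3).  Tier 4 routes to the PCA path."""
    if tier.tier == 4:
        raise TierRoutingError(
            "tier 4 has no domain-based weights; use svikit.pca "
            "(pca_decompose + pca_index) instead"
        )
    weights: dict[tuple[str, str], float] = {}
    sums: dict[str, float] = {}
    for dom, inds in profile.available_indicators.items():
        m = len(inds)
        if m == 0:
            sums[dom] = 0.0
            continue
        halved = tier.tier in (2, 3) and dom in profile.depleted_domains
        w = 1.0 / (2 * m) if halved else 1.0 / m
        for ind in inds:
            weights[(dom, ind)] = w
        for ind in profile.declared_indicators.get(dom, ()):
            if ind not in inds:
                weights[(dom, ind)] = 0.0
        sums[dom] = w * m
    return WeightScheme(weights=weights, tier=tier, domain_weight_sums=sums)


def apply_weights(
    z: ZScoreMatrix,
    scheme: WeightScheme,
    missing_report: MissingReport | None = None,
) -> ScoreTable:
    """Aggregate aligned z-scores into domain scores and the overall SVI.

    Under the renormalize_weights policy, an area with missing cells inside a
    domain has that domain's weights rescaled over its observed indicators so
    the domain weight sum is preserved; an area with no observed indicator in
    a domain contributes 0 for that domain and is flagged.
    """
    if not z.aligned:
        raise ConsistencyError("apply_weights requires a direction-aligned ZScoreMatrix")
    renorm = bool(missing_report and missing_report.renormalize)
    domains = sorted({dom for (dom, _ind) in scheme.weights})
    missing_cols = sorted(
        {ind for (_dom, ind), w in scheme.weights.items() if w > 0}
        - set(z.df.columns)
    )
    if missing_cols:
        raise ConsistencyError(
            f"weighted indicators absent from z-score matrix: {missing_cols}"
        )
    flags: list[str] = []
    scores = pd.DataFrame(index=z.df.index, dtype=float)
    for dom in domains:
        wmap = scheme.domain_indicator_weights(dom)
        if not wmap:
            scores[dom] = 0.0
            continue
        cols = list(wmap)
        wvec = np.array([wmap[c] for c in cols])
        block = z.df[cols].to_numpy()
        obs = ~np.isnan(block)
        if renorm:
            wmat = np.where(obs, wvec, 0.0)
            denom = wmat.sum(axis=1)
            target = scheme.domain_weight_sums[dom]
            empty = denom == 0
            if empty.any():
                flags.append(
                    f"domain {dom!r}: {int(empty.sum())} area(s) with no observed "
                    "indicator scored 0 for this domain"
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                wmat = np.where(
                    empty[:, None], 0.0, wmat * (target / np.where(denom == 0, 1.0, denom))[:, None]
                )
            scores[dom] = np.nansum(np.where(obs, block, 0.0) * wmat, axis=1)
        else:
            if not obs.all():
                bad = z.df.index[(~obs).any(axis=1)][0]
                raise ConsistencyError(
                    f"unhandled missing z-score in domain {dom!r} (e.g. area "
                    f"{bad!r}); run handle_missing first or use the "
                    "renormalize_weights policy"
                )
            scores[dom] = block @ wvec
    svi = scores.sum(axis=1)
    svi.name = "svi"
    return ScoreTable(
        domain_scores=scores,
        svi=svi,
        contributing_weights=scheme,
        flags=tuple(flags),
    )
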