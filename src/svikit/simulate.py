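"""Census-like synthetic indicator tables with a known latent vulnerability.

Each area draws a latent vulnerability L ~ N(0, 1).  Indicator j is generated
as  raw_j = s_j · loading_j · L + ε,  ε ~ N(0, noise_sd²),  where s_j = −1
for vulnerability-reducing indicators — so the raw table genuinely needs
direction alignment, exercising that code path.  An optional logistic
transform 100 / (1 + e^(−x)) maps values onto a census-style percent scale
(a monotone, hence rank-preserving, change of units).  A square grid of unit
cells provides matching geometries, and the latent truth is returned so
recovery tests can measure how well the computed index ranks areas.

Availability degradation mirrors the four data-availability tiers: deleting
required indicators from a domain (tier 2), stripping a dimension down to a
single domain (tier 3), or dropping a dimension's columns entirely (tier 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import SviError
from .geo import SpatialUnits
from .hierarchy import VULNERABILITY_REDUCING, HierarchyConfig
from .normalize import IndicatorTable

__all__ = ["SimulationSpec", "generate", "degrade", "DEGRADATION_SCENARIOS"]

DEGRADATION_SCENARIOS = (
    "tier1_full",
    "tier2_deplete",
    "tier3_single_domain_dimension",
    "tier4_drop_dimension",
)


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic table.

    Defaults (500 areas, loading 0.8, noise sd 0.6) give indicators that
    correlate 0.8 with the latent factor — a strong but noisy signal typical
    of census vulnerability proxies.
    """

    hierarchy: HierarchyConfig
    n_areas: int = 500
    loading: float | dict[str, float] = 0.8
    noise_sd: float = 0.6
    rate_transform: str = "none"  # "none" | "logistic_percent"
    seed: int = 0
    degradation: str = "tier1_full"
    degradation_targets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_areas < 10:
            raise SviError("n_areas must be ≥ 10 (hand-write smaller fixtures)")
        loadings = (
            self.loading.values()
            if isinstance(self.loading, dict)
            else [self.loading]
        )
        if any(not (0 < l <= 1) for l in loadings):
            raise SviError("loadings must lie in (0, 1]")
        if self.noise_sd < 0:
            raise SviError("noise_sd must be non-negative")
        if self.rate_transform not in ("none", "logistic_percent"):
            raise SviError(f"unknown rate_transform {self.rate_transform!r}")
        if self.degradation not in DEGRADATION_SCENARIOS:
            raise SviError(f"unknown degradation scenario {self.degradation!r}")

    def loading_for(self, indicator_id: str) -> float:
        if isinstance(self.loading, dict):
            return float(self.loading[indicator_id])
        return float(self.loading)


def _grid(n: int) -> tuple[tuple[str, ...], tuple]:
    side = math.ceil(math.sqrt(n))
    ids, geoms = [], []
    for i in range(n):
        r, c = divmod(i, side)
        ids.append(f"A{i + 1:04d}")
        geoms.append(box(c, -r - 1, c + 1, -r))
    return tuple(ids), tuple(geoms)


def generate(
    spec: SimulationSpec,
) -> tuple[IndicatorTable, pd.Series, SpatialUnits]:
    """Generate (table, latent truth, grid geometry) for a simulation spec.

    Only indicators the hierarchy marks as available in the case study are
    generated; the declared degradation scenario is then applied on top.
    """
    rng = np.random.default_rng(spec.seed)
    ids, geoms = _grid(spec.n_areas)
    latent = pd.Series(
        rng.standard_normal(spec.n_areas), index=pd.Index(ids, name="area_id"),
        name="latent_vulnerability",
    )
    cfg = spec.hierarchy
    cols: dict[str, np.ndarray] = {}
    for ind_id in cfg.available_indicator_ids():
        ind = cfg.indicator(ind_id)
        sign = -1.0 if ind.direction == VULNERABILITY_REDUCING else 1.0
        raw = (
            sign * spec.loading_for(ind_id) * latent.to_numpy()
            + spec.noise_sd * rng.standard_normal(spec.n_areas)
        )
        if spec.rate_transform == "logistic_percent":
            raw = 100.0 / (1.0 + np.exp(-raw))
        cols[ind_id] = raw
    table = IndicatorTable(pd.DataFrame(cols, index=latent.index))
    if spec.degradation != "tier1_full":
        table = degrade(table, spec.degradation, spec.degradation_targets, cfg)
    units = SpatialUnits(area_ids=ids, geometries=geoms, crs=None)
    return table, latent, units


def _default_targets(scenario: str, cfg: HierarchyConfig) -> tuple[str, ...]:
    if scenario == "tier2_deplete":
        # deplete the first multi-indicator domain: drop all but its first
        for dom in cfg.domains:
            inds = cfg.domain_indicators(dom.domain_id)
            if len(inds) > 1:
                return tuple(i.indicator_id for i in inds[1:])
        raise SviError("no multi-indicator domain to deplete")
    if scenario == "tier3_single_domain_dimension":
        return ("sensitivity",)
    if scenario == "tier4_drop_dimension":
        return ("enhanced_exposure",)
    return ()


def degrade(
    table: IndicatorTable,
    scenario: str,
    targets: tuple[str, ...] = (),
    cfg: HierarchyConfig | None = None,
) -> IndicatorTable:
    """Remove columns to emulate a data-availability regime.

    tier2_deplete
        targets are indicator ids to delete (named required indicators).
    tier3_single_domain_dimension
        target is a dimension id (optionally followed by the domain id to
        keep); all that dimension's domains but one lose their columns.
    tier4_drop_dimension
        target is a dimension id; every column of its domains is deleted.

    Removal is column deletion; remaining columns are untouched.
    """
    if scenario not in DEGRADATION_SCENARIOS:
        raise SviError(f"unknown degradation scenario {scenario!r}")
    if scenario == "tier1_full":
        return table
    if cfg is None:
        raise SviError("degrade needs the hierarchy to resolve targets")
    targets = tuple(targets) or _default_targets(scenario, cfg)
    drop: set[str] = set()
    if scenario == "tier2_deplete":
        unknown = sorted(set(targets) - set(cfg.indicator_ids))
        if unknown:
            raise SviError(f"unknown indicator target(s): {unknown}")
        drop.update(targets)
    else:
        dim = targets[0]
        if dim not in cfg.dimension_ids:
            raise SviError(f"unknown dimension target {dim!r}")
        doms = cfg.dimension_domains(dim)
        if scenario == "tier3_single_domain_dimension":
            keep = targets[1] if len(targets) > 1 else doms[0].domain_id
            if keep not in {d.domain_id for d in doms}:
                raise SviError(
                    f"domain {keep!r} is not in dimension {dim!r}"
                )
            doms = [d for d in doms if d.domain_id != keep]
        for d in doms:
            drop.update(i.indicator_id for i in cfg.domain_indicators(d.domain_id))
    kept = [c for c in table.df.columns if c not in drop]
    if not kept:
        raise SviError("degradation would remove every column")
    return IndicatorTable(table.df[kept])
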