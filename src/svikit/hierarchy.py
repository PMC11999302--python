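"""Indicator hierarchy: indicators nested in domains nested in dimensions.

A Social Vulnerability Index (SVI) configuration declares, for one hazard,
which indicator columns exist, which thematic domain each belongs to (Age,
Health, Income, ...), which of the three vulnerability dimensions each domain
feeds (sensitivity, adaptive capacity, enhanced exposure), and whether larger
raw values mean more or less vulnerability.  The hierarchy is declarative:
it describes the *designed* index, while the availability profile measures
how much of that design a concrete indicator table actually covers — the
quantity that drives tier selection downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError, LinkageError, TableError

__all__ = [
    "DIMENSION_IDS",
    "SUB_ABILITIES",
    "IndicatorDefinition",
    "DomainDefinition",
    "DimensionDefinition",
    "HierarchyConfig",
    "AvailabilityProfile",
    "Violation",
    "ValidationReport",
    "load_hierarchy",
    "save_hierarchy",
    "validate_hierarchy",
    "availability_profile",
]

#: The three top-level vulnerability dimensions a full SVI requires.
DIMENSION_IDS = ("sensitivity", "adaptive_capacity", "enhanced_exposure")

#: Adaptive-capacity sub-abilities; reporting metadata only, never an
#: aggregation level.
SUB_ABILITIES = ("prepare", "respond", "recover")

VULNERABILITY_INCREASING = "vulnerability_increasing"
VULNERABILITY_REDUCING = "vulnerability_reducing"
_DIRECTIONS = (VULNERABILITY_INCREASING, VULNERABILITY_REDUCING)


@dataclass(frozen=True)
class IndicatorDefinition:
    indicator_id: str
    label: str
    domain_id: str
    direction: str = VULNERABILITY_INCREASING
    required: bool = True
    sub_abilities: frozenset[str] = frozenset()
    hazard_tags: frozenset[str] = frozenset()
    #: whether the case-study census actually publishes this indicator;
    #: presets use ``False`` for designed-but-unavailable columns.
    case_study_available: bool = True

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ConfigurationError(
                f"indicator {self.indicator_id!r}: direction must be one of "
                f"{_DIRECTIONS}, got {self.direction!r}"
            )
        bad = set(self.sub_abilities) - set(SUB_ABILITIES)
        if bad:
            raise ConfigurationError(
                f"indicator {self.indicator_id!r}: unknown sub-abilities {sorted(bad)}"
            )


@dataclass(frozen=True)
class DomainDefinition:
    # designed_size is derived, not stored: HierarchyConfig.designed_size()
    domain_id: str
    label: str
    dimension_id: str


@dataclass(frozen=True)
class DimensionDefinition:
    dimension_id: str
    label: str


@dataclass(frozen=True)
class HierarchyConfig:
    """Fully linked hierarchy for one hazard/city configuration."""

    hazard: str
    name: str
    dimensions: tuple[DimensionDefinition, ...]
    domains: tuple[DomainDefinition, ...]
    indicators: tuple[IndicatorDefinition, ...]

    def __post_init__(self) -> None:
        ind_ids = [i.indicator_id for i in self.indicators]
        if len(set(ind_ids)) != len(ind_ids):
            dupes = sorted({i for i in ind_ids if ind_ids.count(i) > 1})
            raise ConfigurationError(f"duplicate indicator ids: {dupes}")
        dom_ids = [d.domain_id for d in self.domains]
        if len(set(dom_ids)) != len(dom_ids):
            dupes = sorted({d for d in dom_ids if dom_ids.count(d) > 1})
            raise ConfigurationError(f"duplicate domain ids: {dupes}")
        dim_ids = {d.dimension_id for d in self.dimensions}
        dangling = sorted(
            d.domain_id for d in self.domains if d.dimension_id not in dim_ids
        )
        if dangling:
            raise LinkageError(
                f"domains reference unknown dimensions: {dangling} "
                f"(known: {sorted(dim_ids)})"
            )
        dangling_pairs = sorted(
            (i.indicator_id, i.domain_id)
            for i in self.indicators
            if i.domain_id not in set(dom_ids)
        )
        if dangling_pairs:
            detail = ", ".join(f"{ind!r} -> {dom!r}" for ind, dom in dangling_pairs)
            raise LinkageError(
                f"indicators reference unknown domains: {detail} "
                f"(known: {sorted(dom_ids)})"
            )
        empty = sorted(
            d.domain_id
            for d in self.domains
            if not any(i.domain_id == d.domain_id for i in self.indicators)
        )
        if empty:
            raise ConfigurationError(f"domains declared without indicators: {empty}")

    # -- lookups -----------------------------------------------------------
    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(i.indicator_id for i in self.indicators)

    @property
    def domain_ids(self) -> tuple[str, ...]:
        return tuple(d.domain_id for d in self.domains)

    @property
    def dimension_ids(self) -> tuple[str, ...]:
        return tuple(d.dimension_id for d in self.dimensions)

    def indicator(self, indicator_id: str) -> IndicatorDefinition:
        for i in self.indicators:
            if i.indicator_id == indicator_id:
                return i
        raise KeyError(indicator_id)

    def domain(self, domain_id: str) -> DomainDefinition:
        for d in self.domains:
            if d.domain_id == domain_id:
                return d
        raise KeyError(domain_id)

    def domain_indicators(self, domain_id: str) -> tuple[IndicatorDefinition, ...]:
        return tuple(i for i in self.indicators if i.domain_id == domain_id)

    def designed_size(self, domain_id: str) -> int:
        return len(self.domain_indicators(domain_id))

    def dimension_domains(self, dimension_id: str) -> tuple[DomainDefinition, ...]:
        return tuple(d for d in self.domains if d.dimension_id == dimension_id)

    def directions(self) -> dict[str, str]:
        return {i.indicator_id: i.direction for i in self.indicators}

    def available_indicator_ids(self) -> tuple[str, ...]:
        """Indicator ids the case-study census publishes (presets only mark
        a handful as unavailable; user configs default to all available)."""
        return tuple(
            i.indicator_id for i in self.indicators if i.case_study_available
        )


# ---------------------------------------------------------------------------
# serialization

def _indicator_to_doc(i: IndicatorDefinition) -> dict:
    doc: dict = {
        "id": i.indicator_id,
        "label": i.label,
        "domain": i.domain_id,
        "direction": i.direction,
        "required": i.required,
    }
    if i.sub_abilities:
        doc["sub_abilities"] = sorted(i.sub_abilities)
    if i.hazard_tags:
        doc["hazard_tags"] = sorted(i.hazard_tags)
    if not i.case_study_available:
        doc["case_study_available"] = False
    return doc


def save_hierarchy(cfg: HierarchyConfig, path_or_buf) -> None:
    """Write a hierarchy back to its YAML document form."""
    doc = {
        "name": cfg.name,
        "hazard": cfg.hazard,
        "dimensions": [
            {"id": d.dimension_id, "label": d.label} for d in cfg.dimensions
        ],
        "domains": [
            {"id": d.domain_id, "label": d.label, "dimension": d.dimension_id}
            for d in cfg.domains
        ],
        "indicators": [_indicator_to_doc(i) for i in cfg.indicators],
    }
    text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w", encoding="utf-8") as fh:
            fh.write(text)


def _require(doc: dict, key: str) -> object:
    if key not in doc:
        raise ConfigurationError(f"configuration document missing key {key!r}")
    return doc[key]


def load_hierarchy(source) -> HierarchyConfig:
    """Load a hierarchy configuration from YAML.

    ``source`` may be a path, an open text file, or a YAML string containing
    the top-level keys ``dimensions``, ``domains`` and ``indicators``.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.lstrip().startswith(("{", "dimensions:", "name:")):
            text = s
        else:
            with open(s, encoding="utf-8") as fh:
                text = fh.read()
    try:
        doc = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough message
        raise ConfigurationError(f"configuration does not parse as YAML: {exc}")
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration document must be a mapping")

    dims = tuple(
        DimensionDefinition(
            dimension_id=str(_require(d, "id")), label=str(d.get("label", d["id"]))
        )
        for d in _require(doc, "dimensions")
    )
    doms = tuple(
        DomainDefinition(
            domain_id=str(_require(d, "id")),
            label=str(d.get("label", d["id"])),
            dimension_id=str(_require(d, "dimension")),
        )
        for d in _require(doc, "domains")
    )
    inds = tuple(
        IndicatorDefinition(
            indicator_id=str(_require(i, "id")),
            label=str(i.get("label", i["id"])),
            domain_id=str(_require(i, "domain")),
            direction=str(i.get("direction", VULNERABILITY_INCREASING)),
            required=bool(i.get("required", True)),
            sub_abilities=frozenset(i.get("sub_abilities", ())),
            hazard_tags=frozenset(i.get("hazard_tags", ())),
            case_study_available=bool(i.get("case_study_available", True)),
        )
        for i in _require(doc, "indicators")
    )
    return HierarchyConfig(
        hazard=str(doc.get("hazard", "unspecified")),
        name=str(doc.get("name", "custom")),
        dimensions=dims,
        domains=doms,
        indicators=inds,
    )


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Violation:
    severity: str  # "error" | "warning"
    code: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...] = ()

    @property
    def errors(self) -> tuple[Violation, ...]:
        return tuple(v for v in self.violations if v.severity == "error")

    @property
    def warnings(self) -> tuple[Violation, ...]:
        return tuple(v for v in self.violations if v.severity == "warning")

    def is_valid(self) -> bool:
        return not self.errors


def validate_hierarchy(cfg: HierarchyConfig) -> ValidationReport:
    """Check a loaded hierarchy against the structural rules of a full SVI.

    A valid configuration carries exactly the three dimensions (sensitivity,
    adaptive capacity, enhanced exposure); a dimension fed by a single domain
    is legal but flagged, since the index then leans on one theme for a whole
    dimension (the Milan situation).
    """
    out: list[Violation] = []
    declared = set(cfg.dimension_ids)
    for dim in DIMENSION_IDS:
        if dim not in declared:
            out.append(
                Violation("error", "dimension-absent", f"dimension absent: {dim}")
            )
    for extra in sorted(declared - set(DIMENSION_IDS)):
        out.append(
            Violation(
                "error",
                "dimension-unknown",
                f"dimension {extra!r} is not one of {DIMENSION_IDS}",
            )
        )
    for dim in cfg.dimensions:
        doms = cfg.dimension_domains(dim.dimension_id)
        if len(doms) == 0:
            out.append(
                Violation(
                    "error",
                    "dimension-empty",
                    f"dimension {dim.dimension_id!r} has no domains",
                )
            )
        elif len(doms) == 1:
            out.append(
                Violation(
                    "warning",
                    "single-domain-dimension",
                    f"dimension {dim.dimension_id!r} is represented by the "
                    f"single domain {doms[0].domain_id!r}",
                )
            )
    return ValidationReport(tuple(out))


# ---------------------------------------------------------------------------
# availability profiling

@dataclass(frozen=True)
class AvailabilityProfile:
    """How much of the designed hierarchy a concrete table covers.

    ``available_count[d]`` is m — the number of the domain's indicators that
    are present in the table and carry rankable information (not all-missing,
    not constant).  A domain is *depleted* when it is missing required
    indicators relative to its design, or is reduced to a lone indicator out
    of a multi-indicator design; domains designed with a single indicator are
    not depleted.  Depleted domains get half weight under tiered weighting.
    """

    available_count: dict[str, int]
    designed_size: dict[str, int]
    missing_required: dict[str, bool]
    available_indicators: dict[str, tuple[str, ...]]
    declared_indicators: dict[str, tuple[str, ...]]
    available_domain_count: dict[str, int]
    depleted_domains: frozenset[str]
    dimension_of_domain: dict[str, str] = field(default_factory=dict)

    @property
    def available_total(self) -> int:
        return sum(self.available_count.values())


def _rankable_columns(cfg: HierarchyConfig, table) -> set[str]:
    """Columns present in the table that are neither all-missing nor constant."""
    df = table.df if hasattr(table, "df") else table
    good: set[str] = set()
    for ind in cfg.indicator_ids:
        if ind not in df.columns:
            continue
        col = df[ind].dropna()
        if len(col) >= 2 and col.nunique() >= 2:
            good.add(ind)
    return good


def availability_profile(cfg: HierarchyConfig, table) -> AvailabilityProfile:
    """Profile a table against its hierarchy: per-domain m, depleted domains,
    per-dimension available-domain counts.

    Raises :class:`TableError` when the table has no recognized indicator
    column at all.
    """
    good = _rankable_columns(cfg, table)
    if not good:
        raise TableError(
            "table contains no usable indicator column declared in the hierarchy"
        )
    avail_count: dict[str, int] = {}
    designed: dict[str, int] = {}
    miss_req: dict[str, bool] = {}
    avail_inds: dict[str, tuple[str, ...]] = {}
    decl_inds: dict[str, tuple[str, ...]] = {}
    depleted: set[str] = set()
    dim_of: dict[str, str] = {}
    for dom in cfg.domains:
        inds = cfg.domain_indicators(dom.domain_id)
        present = tuple(i.indicator_id for i in inds if i.indicator_id in good)
        m = len(present)
        ds = len(inds)
        missing_required = any(
            i.required and i.indicator_id not in good for i in inds
        )
        avail_count[dom.domain_id] = m
        designed[dom.domain_id] = ds
        miss_req[dom.domain_id] = missing_required
        avail_inds[dom.domain_id] = present
        decl_inds[dom.domain_id] = tuple(i.indicator_id for i in inds)
        dim_of[dom.domain_id] = dom.dimension_id
        if (m < ds and missing_required) or (m == 1 and ds > 1):
            depleted.add(dom.domain_id)
    dim_counts = {
        dim.dimension_id: sum(
            1
            for d in cfg.dimension_domains(dim.dimension_id)
            if avail_count[d.domain_id] >= 1
        )
        for dim in cfg.dimensions
    }
    return AvailabilityProfile(
        available_count=avail_count,
        designed_size=designed,
        missing_required=miss_req,
        available_indicators=avail_inds,
        declared_indicators=decl_inds,
        available_domain_count=dim_counts,
        depleted_domains=frozenset(depleted),
        dimension_of_domain=dim_of,
    )
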