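"""End-to-end orchestration: config → scores → classified, exported results.

The stages run in a fixed order — load, validate, profile, normalize, align,
tier, weights (or the PCA fallback), aggregate, classify, export — each
logged to standard error with a stage tag.  Outputs are deterministic given
the same inputs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

from .aggregate import ClassificationScheme, SVIResult, assemble_result
from .errors import ConfigurationError
from .geo import JoinReport, join_and_export, read_geometry
from .hierarchy import (
    AvailabilityProfile,
    HierarchyConfig,
    availability_profile,
    load_hierarchy,
    validate_hierarchy,
)
from .normalize import (
    IndicatorTable,
    align_direction,
    handle_missing,
    zscore_normalize,
)
from .pca import pca_decompose, pca_index
from .weighting import (
    TierAssignment,
    apply_weights,
    build_weights,
    classify_tier,
)

__all__ = ["PipelineOutput", "compute_svi", "run_pipeline"]

log = logging.getLogger("svikit")
if not log.handlers:  # stage-tagged lines to stderr, results only to files
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage(stage: str, msg: str) -> None:
    log.info(msg, extra={"stage": stage})


@dataclass(frozen=True)
class PipelineOutput:
    result: SVIResult
    profile: AvailabilityProfile
    tier: TierAssignment
    join_report: JoinReport | None = None
    decomposition: object | None = None  # PCADecomposition on the tier-4 path


def compute_svi(
    cfg: HierarchyConfig,
    table: IndicatorTable,
    *,
    missing_policy: str = "renormalize_weights",
    scheme: ClassificationScheme | None = None,
    tier_override: int | None = None,
) -> PipelineOutput:
    """Run the full computation on in-memory inputs.

    ``tier_override`` forces a tier (logged with a warning when it contradicts
    the automatic classification); tier 4 — forced or automatic — routes to
    the principal-component index.
    """
    report = validate_hierarchy(cfg)
    for v in report.violations:
        _stage("validate", f"{v.severity}: {v.message}")
    if not report.is_valid():
        raise ConfigurationError(
            "invalid hierarchy: " + "; ".join(v.message for v in report.errors)
        )
    profile = availability_profile(cfg, table)
    tier = classify_tier(profile)
    _stage("tier", f"automatic tier: {tier.tier} ({'; '.join(tier.reasons)})")
    if tier_override is not None and tier_override != tier.tier:
        log.warning(
            "manual tier %d overrides automatic tier %d",
            tier_override,
            tier.tier,
            extra={"stage": "tier"},
        )
        tier = TierAssignment(
            tier=tier_override,
            reasons=(f"manual override (automatic: {tier.tier})",) + tier.reasons,
            robustness_caveats=tier.robustness_caveats
            or (("manually overridden tier",) if tier_override >= 3 else ()),
        )
    table, missing_report = handle_missing(table, missing_policy)
    _stage(
        "normalize",
        f"{len(missing_report.missing_cells)} missing cell(s), "
        f"policy={missing_policy}",
    )
    keep = [c for c in table.df.columns if c in set(cfg.indicator_ids)]
    z = zscore_normalize(IndicatorTable(table.df[keep]), on_degenerate="drop")
    z = align_direction(z, cfg)
    if tier.tier == 4:
        _stage("weights", "tier 4: principal-component fallback")
        if z.df.isna().any().any():
            _stage(
                "weights",
                "imputing column medians for the PCA path (it needs a "
                "complete matrix)",
            )
            zdf = z.df.apply(lambda c: c.fillna(c.median()))
            z = type(z)(
                df=zdf, normalization_params=z.normalization_params, aligned=True
            )
        decomp = pca_decompose(z)
        st = pca_index(z, decomp)
    else:
        decomp = None
        scheme_w = build_weights(profile, tier)
        _stage(
            "weights",
            f"tier {tier.tier} weights over "
            f"{sum(1 for w in scheme_w.weights.values() if w > 0)} indicators",
        )
        st = apply_weights(z, scheme_w, missing_report)
    result = assemble_result(z, st, cfg, tier, scheme)
    _stage("aggregate", f"scored {len(result.area_ids)} areas")
    return PipelineOutput(
        result=result, profile=profile, tier=tier, decomposition=decomp
    )


def run_pipeline(
    config_path,
    indicators_path,
    *,
    geometry_path=None,
    id_field: str = "area_id",
    out_dir=".",
    missing_policy: str = "renormalize_weights",
    classes: str = "sd_bands",
    tier: str | int = "auto",
    seed: int | None = None,
) -> PipelineOutput:
    """File-to-file pipeline behind ``svi compute``.

    Writes ``scores.csv`` (and ``weights.csv`` for tiers 1–3, plus
    ``scores.geojson`` when a geometry is given) into ``out_dir``.  ``seed``
    is accepted for interface symmetry; the computation itself is
    deterministic.
    """
    _stage("load", f"config={config_path} indicators={indicators_path}")
    cfg = load_hierarchy(config_path)
    table = IndicatorTable.read_csv(indicators_path, cfg=cfg)
    tier_override = None if tier in (None, "auto") else int(tier)
    scheme = ClassificationScheme(mode=classes)
    out = compute_svi(
        cfg,
        table,
        missing_policy=missing_policy,
        scheme=scheme,
        tier_override=tier_override,
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores_path = out_dir / "scores.csv"
    out.result.to_frame().to_csv(scores_path, na_rep="NA")
    _stage("export", f"wrote {scores_path}")
    if out.tier.tier != 4:
        build_weights(out.profile, out.tier).to_frame().to_csv(
            out_dir / "weights.csv", index=False
        )
        _stage("export", f"wrote {out_dir / 'weights.csv'}")
    elif out.decomposition is not None:
        audit = out.decomposition.loadings.copy()
        audit.loc["__variance_proportion__"] = out.decomposition.variance_proportions
        audit.to_csv(out_dir / "pca_loadings.csv")
        _stage("export", f"wrote {out_dir / 'pca_loadings.csv'}")
    join_report = None
    if geometry_path is not None:
        units = read_geometry(geometry_path, id_field)
        join_report = join_and_export(
            out.result, units, out_dir / "scores.geojson"
        )
        _stage(
            "export",
            f"wrote {out_dir / 'scores.geojson'} "
            f"({len(join_report.matched_ids)} matched, "
            f"{len(join_report.unmatched_table_ids)} unmatched table id(s), "
            f"{len(join_report.unmatched_geometry_ids)} unmatched geometr(ies))",
        )
    return PipelineOutput(
        result=out.result,
        profile=out.profile,
        tier=out.tier,
        join_report=join_report,
        decomposition=out.decomposition,
    )
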