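"""End-to-end orchestration: boundaries -> null model -> fits -> partitioning.

``run_study`` drives the full per-region, per-group analysis and returns the
province-fit table, the latitude trends and the climate variance partition,
together with a manifest sufficient to reproduce every output.
``replay_table1`` recomputes the cross-province summaries (latitude trends,
significance census, R^2 ranges) directly from the packaged published fit
table, skipping simulation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boundaries import BoundaryRule, compute_domain
from .flora import (
    ClimateRecord,
    FloweringRecord,
    RichnessCurve,
    Table1Row,
    load_table1_fixture,
    observed_richness,
    truncated_durations,
)
from .null_model import MdePrediction, simulate_mde
from .partition import ModelFrame, PartitionResult, assemble_frame, compute_vif, hierarchical_partition
from .regressions import (
    GROUPS,
    LatitudeFit,
    ProvinceFit,
    count_below_p,
    fit_observed_vs_predicted,
    latitude_regression,
    latitude_regression_from_table1,
)
from .synth import StudyBundle, SynthConfig, demo_config, generate_study

logger = logging.getLogger("mdephen")


@dataclass(frozen=True)
class RunConfig:
    """Study-level settings; defaults mirror the published analysis (5%/95%
    boundaries in the main text, 5000 random-placement replicates, 95% CI)."""

    q_low: float = 0.05
    n_reps: int = 5000
    ci_level: float = 0.95
    seed: int = 0
    groups: tuple[str, ...] = GROUPS
    record_definition: str = "species_month"
    boundary_rule: str = "quantile"
    min_species: int = 3
    min_domain_months: int = 3
    log_offset: float = 1.0
    use_analytic: bool = False  # regress on the analytic curve instead of the MC mean

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)


@dataclass(frozen=True)
class GroupResult:
    region_id: str
    group: str
    domain_rule: BoundaryRule
    prediction: MdePrediction
    observed: RichnessCurve
    fit: ProvinceFit


@dataclass(frozen=True)
class RegionResult:
    region_id: str
    groups: dict[str, GroupResult] = field(hash=False)
    skipped: dict[str, str] = field(hash=False)


@dataclass(frozen=True)
class StudyResult:
    regions: dict[str, RegionResult]
    latitude_fits: dict[str, LatitudeFit]
    partitions: dict[str, PartitionResult]
    vifs: dict[str, dict[str, float]]
    manifest: dict

    def fits_frame(self) -> pd.DataFrame:
        """Province-fit table (one row per region, per-group F/R^2/P/period)."""
        rows = []
        for region, res in self.regions.items():
            row: dict = {"region_id": region}
            lat = self.manifest.get("latitudes", {}).get(region)
            if lat is not None:
                row["latitude"] = lat
            for g, gr in res.groups.items():
                row[f"{g}_f"] = gr.fit.f_stat
                row[f"{g}_r2"] = gr.fit.r2
                row[f"{g}_p"] = gr.fit.p
                row[f"{g}_period"] = str(gr.prediction.domain)
            rows.append(row)
        return pd.DataFrame(rows)

    def predictions_frame(self) -> pd.DataFrame:
        """Long table: region, group, month, observed, mde_mean, ci, analytic."""
        rows = []
        for region, res in self.regions.items():
            for g, gr in res.groups.items():
                for i, month in enumerate(gr.prediction.domain.months()):
                    rows.append(
                        {
                            "region_id": region,
                            "group": g,
                            "month": month,
                            "observed": gr.observed.counts[i],
                            "mde_mean": gr.prediction.mean[i],
                            "ci_low": gr.prediction.ci_low[i],
                            "ci_high": gr.prediction.ci_high[i],
                            "analytic": gr.prediction.analytic[i],
                        }
                    )
        return pd.DataFrame(rows)


def _group_records(records: Iterable[FloweringRecord], group: str) -> list[FloweringRecord]:
    if group == "all":
        return list(records)
    form = "herbaceous" if group == "herb" else "woody"
    return [r for r in records if r.growth_form == form]


def _derive_seed(seed: int, region: str, group: str) -> int:
    # stable across processes (unlike hash()); kept below 2**31
    return (seed ^ zlib.crc32(f"{region}:{group}".encode())) & 0x7FFFFFFF


def run_region(
    records: Sequence[FloweringRecord],
    config: RunConfig,
    region_id: str | None = None,
) -> RegionResult:
    """Boundary -> null model -> observed-vs-predicted fit for one region.

    Each group gets its own domain from its own cumulative records. Groups
    with too few species or a degenerate (< 3 month) domain are skipped with
    a logged reason.
    """
    if region_id is None:
        region_id = records[0].region_id if records else "?"
    rule = BoundaryRule(
        q_low=config.q_low, record_definition=config.record_definition, rule=config.boundary_rule
    )
    groups: dict[str, GroupResult] = {}
    skipped: dict[str, str] = {}
    for group in config.groups:
        subset = _group_records(records, group)
        if len(subset) < config.min_species:
            skipped[group] = f"too few species ({len(subset)} < {config.min_species})"
            logger.info("%s/%s skipped: %s", region_id, group, skipped[group])
            continue
        domain = compute_domain(subset, rule)
        if domain.n_bins < config.min_domain_months:
            skipped[group] = f"degenerate domain ({domain.n_bins} months)"
            logger.info("%s/%s skipped: %s", region_id, group, skipped[group])
            continue
        durations = truncated_durations(subset, domain)
        prediction = simulate_mde(
            durations,
            domain.n_bins,
            n_reps=config.n_reps,
            seed=_derive_seed(config.seed, region_id, group),
            ci_level=config.ci_level,
            domain=domain,
        )
        observed = observed_richness(subset, domain)
        predictor = prediction.analytic if config.use_analytic else prediction.mean
        try:
            fit = fit_observed_vs_predicted(observed, predictor, region_id=region_id, group=group)
        except ValueError as exc:
            skipped[group] = f"fit failed: {exc}"
            logger.info("%s/%s skipped: %s", region_id, group, skipped[group])
            continue
        groups[group] = GroupResult(
            region_id=region_id,
            group=group,
            domain_rule=rule,
            prediction=prediction,
            observed=observed,
            fit=fit,
        )
    return RegionResult(region_id=region_id, groups=groups, skipped=skipped)


def run_study(
    bundle: StudyBundle,
    config: RunConfig | None = None,
    partition_groups: Sequence[str] | None = None,
) -> StudyResult:
    """Full analysis over a study bundle (synthetic or read from files)."""
    config = config or RunConfig()
    by_region: dict[str, list[FloweringRecord]] = {}
    for rec in bundle.flora:
        by_region.setdefault(rec.region_id, []).append(rec)
    regions: dict[str, RegionResult] = {}
    for region, recs in by_region.items():
        regions[region] = run_region(recs, config, region_id=region)
    latitude_fits: dict[str, LatitudeFit] = {}
    for group in config.groups:
        fits = [res.groups[group].fit for res in regions.values() if group in res.groups]
        lats = [bundle.latitudes[r] for r, res in regions.items() if group in res.groups]
        if len(fits) >= 3:
            latitude_fits[group] = latitude_regression(fits, lats, group=group)
    partitions: dict[str, PartitionResult] = {}
    vifs: dict[str, dict[str, float]] = {}
    if bundle.climate:
        for group in partition_groups if partition_groups is not None else config.groups:
            richness = {
                r: res.groups[group].observed for r, res in regions.items() if group in res.groups
            }
            predictions = {
                r: res.groups[group].prediction for r, res in regions.items() if group in res.groups
            }
            if len(richness) < 2:
                continue
            frame = assemble_frame(richness, predictions, bundle.climate, offset=config.log_offset)
            partitions[group] = hierarchical_partition(frame)
            vifs[group] = compute_vif(frame)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "q_low": config.q_low,
        "n_reps": config.n_reps,
        "ci_level": config.ci_level,
        "boundary_rule": config.boundary_rule,
        "record_definition": config.record_definition,
        "groups": list(config.groups),
        "latitudes": dict(bundle.latitudes),
        "truth": dict(bundle.truth),
    }
    return StudyResult(
        regions=regions,
        latitude_fits=latitude_fits,
        partitions=partitions,
        vifs=vifs,
        manifest=manifest,
    )


def run_sensitivity(
    bundle: StudyBundle, config: RunConfig | None = None, q_values: Sequence[float] = (0.025, 0.05)
) -> dict[float, StudyResult]:
    """Run the study at each boundary tail fraction and report side by side.

    The manifest of each result gains a soft cross-q comparison (latitude
    slope signs, partition rankings) — reported, not asserted.
    """
    config = config or RunConfig()
    results = {q: run_study(bundle, replace(config, q_low=q)) for q in q_values}
    summary = {}
    for q, res in results.items():
        summary[str(q)] = {
            "latitude_slope_sign": {
                g: int(np.sign(f.slope)) for g, f in res.latitude_fits.items()
            },
            "i_perc_ranking": {
                g: sorted(p.i_perc, key=p.i_perc.get, reverse=True)
                for g, p in res.partitions.items()
            },
        }
    for res in results.values():
        res.manifest["sensitivity"] = summary
    return results


# ---------------------------------------------------------------------------
# Published-table replay
# ---------------------------------------------------------------------------


def replay_table1(rows: Sequence[Table1Row] | None = None) -> dict:
    """Cross-province summaries recomputed from the published fit table.

    Returns latitude trends per group, the woody p < 0.10 census, and the
    per-group R^2 ranges.
    """
    rows = rows if rows is not None else load_table1_fixture()
    out: dict = {"n_provinces": len(rows)}
    for group in GROUPS:
        fit = latitude_regression_from_table1(rows, group)
        r2s = [row.fit(group).r2 for row in rows]
        out[group] = {
            "latitude_slope": fit.slope,
            "latitude_r2": fit.r2,
            "latitude_r2_adj": fit.r2_adj,
            "latitude_p": fit.p,
            "r2_min": min(r2s),
            "r2_max": max(r2s),
        }
    out["woody_n_p_below_0.10"] = count_below_p(rows, "woody", 0.10)
    return out


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def write_outputs(result: StudyResult, outdir: str | Path) -> dict[str, Path]:
    """Write the result tables and manifest as delimited text + JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fits": outdir / "province_fits.csv",
        "predictions": outdir / "predictions.csv",
        "latitude": outdir / "latitude_fits.csv",
        "partition": outdir / "partition.csv",
        "manifest": outdir / "manifest.json",
    }
    result.fits_frame().to_csv(paths["fits"], index=False)
    result.predictions_frame().to_csv(paths["predictions"], index=False)
    pd.DataFrame(
        [
            {
                "group": g,
                "slope": f.slope,
                "r2": f.r2,
                "r2_adj": f.r2_adj,
                "p": f.p,
                "n_points": f.n_points,
            }
            for g, f in result.latitude_fits.items()
        ]
    ).to_csv(paths["latitude"], index=False)
    part_rows = []
    for g, p in result.partitions.items():
        for pred in p.predictors:
            part_rows.append(
                {
                    "group": g,
                    "predictor": pred,
                    "t": p.t[pred],
                    "p": p.p[pred],
                    "vif": p.vif[pred],
                    "i_perc": p.i_perc[pred],
                    "marginal_r2": p.marginal_r2,
                }
            )
    pd.DataFrame(part_rows).to_csv(paths["partition"], index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    return paths


def demo_study(seed: int = 0, **overrides) -> StudyBundle:
    """Convenience wrapper for the small end-to-end demo bundle."""
    return generate_study(demo_config(seed=seed, **overrides))
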