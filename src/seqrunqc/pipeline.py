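"""End-to-end orchestration of the run-QC diagnostics.

``run_pipeline`` takes a :class:`PipelineConfig` pointing at the four input
tables (or a synthetic-study spec), executes the stages
qc -> alpha -> beta -> diagnose -> variability, and renders one
:class:`DiagnosticReport` as deterministic JSON plus a human-readable
markdown summary.  Every flag in the report carries the rule, statistic and
threshold that produced it, and the provenance block (config hash + seeds)
is sufficient to reproduce the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import (
    fit_lineweaver_burk,
    fit_michaelis_menten,
    rarefy_table,
    richness_anova,
    richness_table,
)
from .beta import bray_curtis, hellinger_transform, permanova, variance_partition
from .diagnostics import (
    evaluate_mocks,
    flag_outlier_runs,
    reference_similarity,
    within_run_similarity,
)
from .funnel import (
    DiagnosticThresholds,
    control_read_fraction,
    funnel_report,
    funnels_from_frame,
    read_funnels,
)
from .synthetic import (
    SyntheticConfig,
    config_from_dict,
    mock_expected_profile,
    simulate_study,
)
from .tables import (
    aggregate_to_rank,
    cpm_normalize,
    read_count_table,
    read_lineage,
    read_metadata,
)
from .variability import (
    log2fc_range,
    log2fc_vs_reference,
    rm_anova_variability,
)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full diagnostic run."""

    counts_path: str | None = None
    lineage_path: str | None = None
    metadata_path: str | None = None
    funnel_path: str | None = None
    simulate: dict | None = None          # SyntheticConfig fields, alternative to paths
    reference_runs: list[str] = field(default_factory=list)
    thresholds: DiagnosticThresholds = field(default_factory=DiagnosticThresholds)
    rarefaction_seed: int = 0
    permanova_permutations: int = 999
    permanova_seed: int = 0
    metric: str = "bc-hellinger"
    pseudocount: float = 0.5
    output_dir: str = "."

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("counts_path", "lineage_path", "metadata_path", "funnel_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when not simulating")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file {p!r}")
        if self.thresholds.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw and not isinstance(raw["thresholds"], DiagnosticThresholds):
            t = dict(raw["thresholds"])
            if "quality_removal_band" in t:
                t["quality_removal_band"] = tuple(t["quality_removal_band"])
            raw["thresholds"] = DiagnosticThresholds(**t)
        return cls(**raw)


def _provenance_config(config: PipelineConfig) -> dict:
    d = config.to_dict()
    d.pop("output_dir", None)  # where the report lands does not shape it
    return d


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(_provenance_config(config), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _round(x, nd=6):
    if isinstance(x, float):
        if not np.isfinite(x):
            return None
        return round(x, nd)
    return x


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute all diagnostic stages; return (and optionally write) the report.

    On a stage failure the report marks the stage failed and downstream
    stages that depend on its outputs are skipped.
    """
    config.validate()
    report: dict = {
        "provenance": {
            "tool": "seqrunqc",
            "version": __version__,
            "config_hash": _config_hash(config),
            "config": _jsonable(_provenance_config(config)),
        },
        "stages": {},
    }

    # ----- inputs -----------------------------------------------------
    if config.simulate is not None:
        sim_cfg = (config.simulate if isinstance(config.simulate, SyntheticConfig)
                   else config_from_dict(config.simulate))
        table, metadata, funnel_df, truth = simulate_study(sim_cfg)
        funnels = funnels_from_frame(funnel_df)
        from .synthetic import build_taxonomy
        lineage = build_taxonomy(sim_cfg)
        if not config.reference_runs:
            config = dataclasses.replace(config, reference_runs=truth.reference_runs)
    else:
        table = read_count_table(config.counts_path)
        lineage = read_lineage(config.lineage_path)
        metadata = read_metadata(config.metadata_path)
        funnels = read_funnels(config.funnel_path)

    thr = config.thresholds
    results = report["stages"]

    # ----- qc ---------------------------------------------------------
    try:
        funnel_tab = funnel_report(funnels, thr)
        ctrl = control_read_fraction(table, metadata, thr)
        results["qc"] = {
            "status": "ok",
            "funnel": _jsonable(funnel_tab.reset_index().to_dict(orient="records")),
            "control_read_fraction": _jsonable(
                ctrl.reset_index().to_dict(orient="records")),
        }
    except Exception as exc:  # pragma: no cover - defensive
        results["qc"] = {"status": "failed", "error": str(exc)}

    meta = metadata.for_samples(table.sample_ids)
    soil_ids = list(meta.index[meta["sample_type"] == "soil"])
    soil = table.subset_samples(soil_ids)
    genus = aggregate_to_rank(table, lineage, "genus")

    # ----- alpha ------------------------------------------------------
    try:
        rar = rarefy_table(soil, thr.rarefaction_depth, seed=config.rarefaction_seed)
        rich = richness_table(rar.table)
        anova = richness_anova(rich, metadata)
        reads = soil.library_sizes().loc[rich.index]
        sites = metadata.for_samples(rich.index)["site"]
        runs = metadata.for_samples(rich.index)["run"]
        mm = fit_michaelis_menten(reads, rich, sites)
        # runs mostly excluded by rarefaction cannot support a per-run fit
        run_sizes = runs.value_counts()
        fit_ok = runs.isin(run_sizes.index[run_sizes >= 3])
        skipped_runs = sorted(set(runs[~fit_ok]))
        lb = fit_lineweaver_burk(reads[fit_ok.values], rich[fit_ok.values],
                                 runs[fit_ok.values])
        results["alpha"] = {
            "lb_skipped_runs": skipped_runs,
            "status": "ok",
            "rarefaction_depth": thr.rarefaction_depth,
            "excluded_samples": rar.excluded,
            "anova": _jsonable(anova.reset_index().rename(
                columns={"index": "effect"}).to_dict(orient="records")),
            "michaelis_menten": [_jsonable(dataclasses.asdict(f)) for f in mm],
            "lineweaver_burk": [_jsonable(dataclasses.asdict(t)) for t in lb],
        }
    except Exception as exc:
        results["alpha"] = {"status": "failed", "error": str(exc)}

    # ----- beta -------------------------------------------------------
    try:
        genus_soil = genus.subset_samples(soil_ids)
        D = bray_curtis(hellinger_transform(genus_soil))
        soil_meta = metadata.for_samples(soil_ids)
        f_site, p_site = permanova(D, soil_meta["site"],
                                   n_perm=config.permanova_permutations,
                                   seed=config.permanova_seed)
        vp = variance_partition(D, soil_meta[["site", "run", "library"]])
        results["beta"] = {
            "status": "ok",
            "metric": "bc-hellinger",
            "permanova_site": {"pseudo_F": _round(f_site), "p": _round(p_site)},
            "variance_partition": _jsonable(
                vp.reset_index().to_dict(orient="records")),
        }
    except Exception as exc:
        results["beta"] = {"status": "failed", "error": str(exc)}

    # ----- diagnose ---------------------------------------------------
    try:
        within = within_run_similarity(genus, metadata, metric=config.metric)
        pairs, ref_sum = reference_similarity(genus, metadata,
                                              config.reference_runs,
                                              metric=config.metric)
        flags = flag_outlier_runs(ref_sum)
        mocks = evaluate_mocks(genus, metadata, mock_expected_profile(), thr)
        results["diagnose"] = {
            "status": "ok",
            "metric": config.metric,
            "within_run": [_jsonable(dict(run=s.run, library=s.library,
                                          median=s.median, iqr=s.stats.iqr,
                                          n_pairs=s.n_pairs)) for s in within],
            "reference": [_jsonable(dict(run=s.run, library=s.library,
                                         median=s.median, iqr=s.stats.iqr,
                                         n_pairs=s.n_pairs)) for s in ref_sum],
            "flags": [_jsonable(dataclasses.asdict(f)) for f in flags],
            "mock": [_jsonable(dataclasses.asdict(m)) for m in mocks],
        }
    except Exception as exc:
        results["diagnose"] = {"status": "failed", "error": str(exc)}

    # ----- variability ------------------------------------------------
    try:
        cpm = cpm_normalize(genus.subset_samples(soil_ids))
        lfc = log2fc_vs_reference(cpm, metadata, config.reference_runs,
                                  pseudocount=config.pseudocount)
        ranges = log2fc_range(lfc)
        rm = rm_anova_variability(ranges, rank="genus")
        results["variability"] = {
            "status": "ok",
            "rank": "genus",
            "pseudocount": config.pseudocount,
            "mean_ranges": _jsonable(rm.mean_ranges.to_dict()),
            "ci_low": _jsonable(rm.ci_low.to_dict()),
            "ci_high": _jsonable(rm.ci_high.to_dict()),
            "rm_anova": {"F": _round(rm.f_statistic), "p": _round(rm.p_value),
                         "gg_epsilon": _round(rm.gg_epsilon)},
            "pairwise": _jsonable(rm.pairwise.to_dict(orient="records")),
        }
    except Exception as exc:
        results["variability"] = {"status": "failed", "error": str(exc)}

    report["failed_stages"] = [k for k, v in results.items()
                               if v.get("status") != "ok"]
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        (outdir / "report.md").write_text(render_markdown(report))
    return report


def render_markdown(report: dict) -> str:
    """Small human-readable summary mirroring the report's main tables."""
    lines = ["# Sequencing-run diagnostic report", ""]
    lines.append(f"tool: seqrunqc {report['provenance']['version']}  "
                 f"config hash: {report['provenance']['config_hash']}")
    lines.append("")
    qc = report["stages"].get("qc", {})
    if qc.get("status") == "ok":
        lines.append("## Read-accounting funnel")
        lines.append("| run | raw | demux | qualfilt | lenfilt | demux rem. | quality rem. | flag |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for r in qc["funnel"]:
            lines.append(
                f"| {r['run']} | {r['raw_reads']} | {r['demux_reads']} | "
                f"{r['qualfilt_reads']} | {r['lenfilt_reads']} | "
                f"{r['demux_removed']:.3f} | {r['quality_removed']:.3f} | "
                f"{'FLAG' if r['quality_flagged'] else ''} |")
        lines.append("")
    alpha = report["stages"].get("alpha", {})
    if alpha.get("status") == "ok":
        lines.append("## Lineweaver-Burk run tests")
        lines.append("| run | slope | intercept | p(slope) | p(intercept) |")
        lines.append("|---|---|---|---|---|")
        for t in alpha["lineweaver_burk"]:
            lines.append(f"| {t['run']} | {t['slope']:.3g} | {t['intercept']:.3g} "
                         f"| {t['p_slope']:.3g} | {t['p_intercept']:.3g} |")
        lines.append("")
    diag = report["stages"].get("diagnose", {})
    if diag.get("status") == "ok":
        lines.append("## Similarity flags")
        if diag["flags"]:
            lines.append("| run | library | rule | median | band low |")
            lines.append("|---|---|---|---|---|")
            for f in diag["flags"]:
                lines.append(f"| {f['run']} | {f['library']} | {f['rule']} | "
                             f"{f['value']:.3f} | {f['reference_band'][0]:.3f} |")
        else:
            lines.append("No runs flagged.")
        lines.append("")
    if report["failed_stages"]:
        lines.append(f"Failed stages: {', '.join(report['failed_stages'])}")
    return "\n".join(lines) + "\n"
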