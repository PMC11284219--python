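"""Run-level community diagnostics.

Three complementary checks per (run, library):

* within-run replicate similarity — how alike the replicate subsamples of
  each plot are within one run;
* reference-soil similarity — how alike each soil sample is to the matching
  (site, plot) samples produced by designated reference (primary-lab) runs;
* mock-community evaluation — Bray-Curtis similarity of each run's mock
  sample to the theoretical 8-genome profile, plus its contaminant mass.

Similarity summaries are boxplot-style (type-7 quartiles, 1.5xIQR
whiskers) and a (run, library) is flagged when its median similarity drops
below the reference pool's median minus one pool IQR — low similarity being
the failure mode of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta import bray_curtis, hellinger_transform, morisita
from .funnel import DiagnosticThresholds
from .tables import (
    AbundanceTable,
    SampleMetadata,
    TaxonCountTable,
    to_relative_abundance,
)

METRICS = ("bc-hellinger", "morisita")


@dataclass
class BoxplotStats:
    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def boxplot_stats(values) -> BoxplotStats:
    """Quartiles by linear interpolation (type 7) with 1.5xIQR whiskers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotStats(float(q1), float(med), float(q3), float(iqr),
                        float(inside.min()), float(inside.max()),
                        [float(x) for x in np.sort(outliers)])


@dataclass
class SimilaritySummary:
    run: str
    library: str
    values: list[float]
    stats: BoxplotStats = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.stats is None:
            self.stats = boxplot_stats(self.values)

    @property
    def median(self) -> float:
        return self.stats.median

    @property
    def n_pairs(self) -> int:
        return len(self.values)


@dataclass
class RunFlag:
    run: str
    library: str
    rule: str
    value: float
    reference_band: tuple
    severity: str = "warning"
    note: str = ""


def _similarity_matrix(table: TaxonCountTable, metric: str) -> pd.DataFrame:
    if metric == "bc-hellinger":
        D = bray_curtis(hellinger_transform(table))
    elif metric == "morisita":
        D = morisita(table)
    else:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return 1.0 - D.to_frame()


def within_run_similarity(table: TaxonCountTable, metadata: SampleMetadata,
                          metric: str = "bc-hellinger") -> list[SimilaritySummary]:
    """Replicate-pair similarities pooled per (run, library).

    For each (run, library, site, plot) the similarity between every pair of
    replicate soil subsamples is computed at the table's rank (genus by
    convention) and pooled into one summary per (run, library).
    """
    meta = metadata.for_samples(table.sample_ids)
    soil = meta[meta["sample_type"] == "soil"]
    sims = _similarity_matrix(table.subset_samples(list(soil.index)), metric)
    summaries = []
    for (run, lib), sub in soil.groupby(["run", "library"], sort=False):
        values = []
        for _, grp in sub.groupby(["site", "plot"], sort=False):
            ids = list(grp.index)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    values.append(float(sims.loc[ids[i], ids[j]]))
        if values:
            summaries.append(SimilaritySummary(str(run), str(lib), values))
    if not summaries:
        raise ValueError("no replicate pairs found")
    return summaries


def reference_similarity(table: TaxonCountTable, metadata: SampleMetadata,
                         reference_runs: list[str],
                         metric: str = "bc-hellinger",
                         ) -> tuple[pd.DataFrame, list[SimilaritySummary]]:
    """Similarity of each evaluated soil sample to the reference-run soils.

    Each evaluated sample is compared to the matching (site, plot, library)
    samples of each reference run, contributing one similarity per reference
    run (the mean over that run's matching replicates).  Returns the
    per-sample long table and per-(run, library) summaries.
    """
    meta = metadata.for_samples(table.sample_ids)
    soil = meta[meta["sample_type"] == "soil"]
    sims = _similarity_matrix(table.subset_samples(list(soil.index)), metric)
    refs = soil[soil["run"].isin(reference_runs)]
    if refs.empty:
        raise ValueError(f"no soil samples in reference runs {reference_runs}")
    evaluated = soil[~soil["run"].isin(reference_runs)]
    records = []
    skipped = []
    for sid, row in evaluated.iterrows():
        for ref_run in reference_runs:
            match = refs[(refs["run"] == ref_run) & (refs["site"] == row["site"])
                         & (refs["plot"] == row["plot"])
                         & (refs["library"] == row["library"])]
            if match.empty:
                skipped.append((sid, ref_run))
                continue
            value = float(sims.loc[sid, list(match.index)].mean())
            records.append(dict(sample_id=sid, run=row["run"],
                                library=row["library"], site=row["site"],
                                plot=row["plot"], reference_run=ref_run,
                                similarity=value))
    pairs = pd.DataFrame(records)
    if pairs.empty:
        raise ValueError("no (site, plot) matches between evaluated and reference runs")
    summaries = [SimilaritySummary(str(run), str(lib), list(sub["similarity"]))
                 for (run, lib), sub in pairs.groupby(["run", "library"], sort=False)]
    return pairs, summaries


def flag_outlier_runs(summaries: list[SimilaritySummary],
                      pool_runs: list[str] | None = None,
                      rule: str = "reference_similarity",
                      iqr_factor: float = 1.0) -> list[RunFlag]:
    """Flag (run, library) whose median similarity falls below the pool band.

    The pool band is the pooled similarity values' median minus
    ``iqr_factor`` x IQR, computed over the summaries of ``pool_runs``
    (default: all runs).  Flagging is one-sided: only low similarity fails.
    """
    if pool_runs is None:
        pool_runs = sorted({s.run for s in summaries})
    pool_values = [v for s in summaries if s.run in pool_runs for v in s.values]
    if len(pool_runs) < 2 or not pool_values:
        raise ValueError("reference pool needs at least 2 runs with values")
    stats = boxplot_stats(pool_values)
    lower = stats.median - iqr_factor * stats.iqr
    flags = []
    for s in summaries:
        if s.median < lower:
            flags.append(RunFlag(run=s.run, library=s.library, rule=rule,
                                 value=s.median,
                                 reference_band=(lower, stats.median),
                                 note=f"median below pool median - {iqr_factor}*IQR"))
    return flags


@dataclass
class MockEvaluation:
    sample_id: str
    similarity: float
    contaminant_fraction: float
    passed: bool
    threshold: float


def mock_evaluation(observed: pd.Series, expected: AbundanceTable,
                    thresholds: DiagnosticThresholds | None = None,
                    sample_id: str = "mock") -> MockEvaluation:
    """Evaluate one mock-community sample against the theoretical profile.

    ``observed`` is a genus-level count (or abundance) vector.  Similarity is
    the Bray-Curtis similarity of relative abundances on the union of taxa;
    contaminant fraction is the relative-abundance mass outside the expected
    genera.  The sample passes iff similarity >= the 0.860 default threshold.
    """
    thresholds = thresholds or DiagnosticThresholds()
    if float(np.asarray(observed, dtype=float).sum()) <= 0:
        raise ValueError(f"mock sample {sample_id!r} has zero counts")
    exp = expected.data.iloc[0]
    exp_rel = exp / exp.sum()
    obs_rel = observed / observed.sum()
    union = sorted(set(exp_rel.index) | set(obs_rel.index))
    x = obs_rel.reindex(union, fill_value=0.0).to_numpy(float)
    y = exp_rel.reindex(union, fill_value=0.0).to_numpy(float)
    bc = np.abs(x - y).sum() / (x + y).sum()
    similarity = float(1.0 - bc)
    contaminant = float(obs_rel[~obs_rel.index.isin(exp_rel.index)].sum())
    return MockEvaluation(sample_id=sample_id, similarity=similarity,
                          contaminant_fraction=contaminant,
                          passed=similarity >= thresholds.mock_similarity_min,
                          threshold=thresholds.mock_similarity_min)


def expected_profile_at_rank(expected: AbundanceTable, rank: str) -> AbundanceTable:
    """Aggregate the species-level expected mock profile to a coarser rank."""
    if rank == "species":
        return expected
    from .synthetic import mock_lineage

    labels = mock_lineage().labels_at(rank)
    agg = expected.data.T.groupby(labels.reindex(expected.data.columns).values).sum().T
    return AbundanceTable(agg, rank=rank, kind=expected.kind)


def evaluate_mocks(table: TaxonCountTable, metadata: SampleMetadata,
                   expected: AbundanceTable,
                   thresholds: DiagnosticThresholds | None = None,
                   ) -> list[MockEvaluation]:
    """Evaluate every mock sample in a table against the expected profile.

    The species-level expected profile is aggregated to the table's rank
    before comparison.
    """
    exp = expected_profile_at_rank(expected, table.rank)
    meta = metadata.for_samples(table.sample_ids)
    mock_ids = meta.index[meta["sample_type"] == "mock"]
    return [mock_evaluation(table.data.loc[sid], exp, thresholds, sample_id=sid)
            for sid in mock_ids]
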