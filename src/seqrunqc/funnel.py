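"""Per-run read-accounting diagnostics.

A run's QC funnel is the read count surviving each processing stage:
raw -> demultiplexed -> quality-filtered -> length-filtered.  Stage-wise
removal fractions are screened against simple published-style thresholds:
quality filtering should remove roughly 2-5% of demultiplexed reads, and
negative-control reads should stay below 0.4% of a run's total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .tables import SampleMetadata, TaxonCountTable


@dataclass(frozen=True)
class RunQCFunnel:
    run: str
    raw_reads: int
    demux_reads: int
    qualfilt_reads: int
    lenfilt_reads: int

    def validate(self) -> None:
        counts = (self.raw_reads, self.demux_reads, self.qualfilt_reads,
                  self.lenfilt_reads)
        if any(c < 0 for c in counts):
            raise ValueError(f"run {self.run}: negative read counts")
        if not (self.raw_reads >= self.demux_reads >= self.qualfilt_reads
                >= self.lenfilt_reads):
            raise ValueError(
                f"run {self.run}: funnel not monotone non-increasing: {counts}")


@dataclass
class DiagnosticThresholds:
    """Flagging thresholds for the run-level diagnostics."""

    quality_removal_band: tuple[float, float] = (0.02, 0.05)
    control_read_fraction_max: float = 0.004
    mock_similarity_min: float = 0.860
    rarefaction_depth: int = 12_000

    def __post_init__(self) -> None:
        low, high = self.quality_removal_band
        if not (0.0 <= low < high <= 1.0):
            raise ValueError("quality_removal_band must satisfy 0 <= low < high <= 1")


@dataclass
class FunnelFlag:
    run: str
    rule: str
    value: float
    band: tuple
    flagged: bool
    note: str = ""


def read_funnels(path: str | Path) -> list[RunQCFunnel]:
    df = pd.read_csv(path, sep="\t")
    funnels = [RunQCFunnel(str(r.run), int(r.raw_reads), int(r.demux_reads),
                           int(r.qualfilt_reads), int(r.lenfilt_reads))
               for r in df.itertuples()]
    for f in funnels:
        f.validate()
    return funnels


def funnels_from_frame(df: pd.DataFrame) -> list[RunQCFunnel]:
    """Build funnels from a DataFrame indexed by run (simulate_study output)."""
    funnels = [RunQCFunnel(str(run), int(r.raw_reads), int(r.demux_reads),
                           int(r.qualfilt_reads), int(r.lenfilt_reads))
               for run, r in df.iterrows()]
    for f in funnels:
        f.validate()
    return funnels


def funnel_fractions(funnel: RunQCFunnel) -> dict[str, float]:
    """Stage-wise removal fractions: at demux, quality and length filtering."""
    funnel.validate()
    if funnel.raw_reads == 0:
        raise ValueError(f"run {funnel.run}: raw read count is zero")
    demux_removed = 1.0 - funnel.demux_reads / funnel.raw_reads
    quality_removed = (1.0 - funnel.qualfilt_reads / funnel.demux_reads
                       if funnel.demux_reads else 0.0)
    length_removed = (1.0 - funnel.lenfilt_reads / funnel.qualfilt_reads
                      if funnel.qualfilt_reads else 0.0)
    return {"demux_removed": demux_removed,
            "quality_removed": quality_removed,
            "length_removed": length_removed}


def flag_quality_removal(run: str, fractions: dict[str, float],
                         thresholds: DiagnosticThresholds) -> FunnelFlag:
    """Flag a run whose quality-filter removal falls outside the accepted band.

    The band endpoints are inclusive: removing exactly 2% or 5% is fine.
    """
    low, high = thresholds.quality_removal_band
    value = fractions["quality_removed"]
    flagged = not (low <= value <= high)
    return FunnelFlag(run=run, rule="quality_removal_band", value=value,
                      band=(low, high), flagged=flagged)


def control_read_fraction(table: TaxonCountTable, metadata: SampleMetadata,
                          thresholds: DiagnosticThresholds | None = None,
                          per_sample: bool = False) -> pd.DataFrame:
    """Fraction of each run's reads carried by its negative-control samples.

    By default control reads are summed over a run's controls; with
    ``per_sample=True`` each control is screened individually and the run's
    reported fraction is the worst (largest) one.
    """
    thresholds = thresholds or DiagnosticThresholds()
    meta = metadata.for_samples(table.sample_ids)
    sizes = table.library_sizes()
    rows = []
    for run, sub in meta.groupby("run", sort=False):
        total = sizes.loc[sub.index].sum()
        is_ctrl = sub["sample_type"].isin(["ext_control", "pcr_control"])
        if not is_ctrl.any():
            rows.append(dict(run=run, fraction=float("nan"), flagged=False,
                             note="no control samples; fraction undefined"))
            continue
        ctrl_sizes = sizes.loc[sub.index[is_ctrl]]
        if per_sample:
            frac = float((ctrl_sizes / total).max())
        else:
            frac = float(ctrl_sizes.sum() / total)
        rows.append(dict(run=run, fraction=frac,
                         flagged=frac > thresholds.control_read_fraction_max,
                         note=""))
    return pd.DataFrame(rows).set_index("run")


def funnel_report(funnels: list[RunQCFunnel],
                  thresholds: DiagnosticThresholds | None = None) -> pd.DataFrame:
    """Per-run fractions plus the quality-removal flag, as one table."""
    thresholds = thresholds or DiagnosticThresholds()
    rows = []
    for f in funnels:
        fr = funnel_fractions(f)
        flag = flag_quality_removal(f.run, fr, thresholds)
        rows.append(dict(run=f.run, raw_reads=f.raw_reads,
                         demux_reads=f.demux_reads,
                         qualfilt_reads=f.qualfilt_reads,
                         lenfilt_reads=f.lenfilt_reads, **fr,
                         quality_flagged=flag.flagged))
    return pd.DataFrame(rows).set_index("run")
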