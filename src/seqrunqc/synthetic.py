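"""Synthetic multi-laboratory amplicon study generator.

Emulates a cross-laboratory soil-microbiome ring trial: two field sites,
several single-flow-cell sequence runs (one per laboratory), and within each
run three libraries of increasing workflow autonomy (``Seq`` < ``PCR/Seq`` <
``Ext/PCR/Seq``).  Soil subsamples are taken in replicate per plot, every
run carries a defined 8-species mock community and extraction/PCR negative
controls, and one run can be made *aberrant* by injecting a phylum-wide
per-genus bias at a chosen workflow stage.  The generator returns the
pooled species-level count table, sample metadata, per-run read-accounting
funnels, and a ground-truth record for diagnostics testing.

All randomness flows from the single config seed through named substreams,
so every artefact is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    LIBRARY_LEVELS,
    SampleMetadata,
    TaxonCountTable,
    TaxonomyLineage,
)

# ZymoBIOMICS D6305 theoretical 16S composition (percent).
_MOCK_PROFILE_PCT = {
    "Pseudomonas aeruginosa": 4.2,
    "Escherichia coli": 10.1,
    "Salmonella enterica": 10.4,
    "Lactobacillus fermentum": 18.4,
    "Enterococcus faecalis": 9.9,
    "Staphylococcus aureus": 15.5,
    "Listeria monocytogenes": 14.1,
    "Bacillus subtilis": 17.4,
}

_MOCK_LINEAGE = {
    "Pseudomonas aeruginosa": ("Pseudomonas", "Gammaproteobacteria", "Pseudomonadota"),
    "Escherichia coli": ("Escherichia", "Gammaproteobacteria", "Pseudomonadota"),
    "Salmonella enterica": ("Salmonella", "Gammaproteobacteria", "Pseudomonadota"),
    "Lactobacillus fermentum": ("Lactobacillus", "Bacilli", "Bacillota"),
    "Enterococcus faecalis": ("Enterococcus", "Bacilli", "Bacillota"),
    "Staphylococcus aureus": ("Staphylococcus", "Bacilli", "Bacillota"),
    "Listeria monocytogenes": ("Listeria", "Bacilli", "Bacillota"),
    "Bacillus subtilis": ("Bacillus", "Bacilli", "Bacillota"),
}

_STAGE_LIBRARIES = {
    "extraction": {"Ext/PCR/Seq"},
    "pcr": {"PCR/Seq", "Ext/PCR/Seq"},
    "sequencing": {"Seq", "PCR/Seq", "Ext/PCR/Seq"},
}


class ConfigError(ValueError):
    """Raised when a synthetic study configuration violates its invariants."""


@dataclass
class RunSpec:
    """One sequence run (one laboratory flow cell)."""

    name: str
    depth: int = 40_000            # mean reads per soil sample
    demux_removed: float = 0.42    # fraction lost at demultiplexing
    quality_removed: float = 0.03  # fraction of demuxed lost at quality filter
    length_removed: float = 0.005  # fraction of quality-filtered lost at length filter
    aberrant: bool = False
    reference: bool = False        # primary-lab run (Log2FC / similarity baseline)


@dataclass
class SiteEffect:
    """True between-site community difference."""

    fraction_affected: float = 0.2
    log2fc_sd: float = 1.0


@dataclass
class AberrantBias:
    """Phylum-wide per-genus bias injected into the aberrant run."""

    n_biased_phyla: int = 2
    per_genus_log2_sd: float = 1.5
    entry_stage: str = "pcr"  # extraction | pcr | sequencing


@dataclass
class SyntheticConfig:
    """Full description of a simulated multi-lab study.

    Defaults give 2 sites x 4 plots x 2 replicates x 3 libraries x 6 runs
    = 288 soil samples, with one PCR-stage aberrant run (Lab2a), one
    low-depth run (Lab5, which also over-removes at the quality filter) and
    one high-depth run (Lab6).
    """

    n_phyla: int = 8
    n_classes_per_phylum: int = 3
    n_genera_per_class: int = 5
    n_species_per_genus: int = 4
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    n_sites: int = 2
    site_effect: SiteEffect = field(default_factory=SiteEffect)
    runs: list[RunSpec] = field(default_factory=lambda: [
        RunSpec("Lab1", depth=40_000, reference=True),
        RunSpec("Lab2a", depth=35_000, aberrant=True),
        RunSpec("Lab2b", depth=30_000),
        RunSpec("Lab4", depth=45_000, reference=True),
        RunSpec("Lab5", depth=8_000, quality_removed=0.30),
        RunSpec("Lab6", depth=110_000),
    ])
    aberrant_bias: AberrantBias = field(default_factory=AberrantBias)
    # per-library multiplicative lognormal noise sigma, increasing with autonomy
    library_noise: Mapping[str, float] = field(default_factory=lambda: {
        "Seq": 0.0, "PCR/Seq": 0.10, "Ext/PCR/Seq": 0.20,
    })
    n_plots: int = 4
    n_replicates: int = 2
    overdispersion: float = 3000.0  # Dirichlet concentration scale theta
    mock_contaminant_fraction: float = 0.001
    control_depth_mean: float = 50.0
    depth_jitter_sigma: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("n_phyla", "n_classes_per_phylum", "n_genera_per_class",
                     "n_species_per_genus", "n_sites", "n_plots", "n_replicates"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.overdispersion <= 0:
            problems.append("overdispersion must be > 0")
        for run in self.runs:
            if run.depth < 1:
                problems.append(f"run {run.name}: depth must be >= 1")
            for fname in ("demux_removed", "quality_removed", "length_removed"):
                v = getattr(run, fname)
                if not 0.0 <= v <= 1.0:
                    problems.append(f"run {run.name}: {fname} outside [0, 1]")
        if not 0.0 <= self.mock_contaminant_fraction <= 1.0:
            problems.append("mock_contaminant_fraction outside [0, 1]")
        if not 0.0 <= self.site_effect.fraction_affected <= 1.0:
            problems.append("site_effect.fraction_affected outside [0, 1]")
        if self.aberrant_bias.n_biased_phyla > self.n_phyla:
            problems.append("biased phyla must be a subset of simulated phyla")
        if self.aberrant_bias.entry_stage not in _STAGE_LIBRARIES:
            problems.append(f"unknown entry stage {self.aberrant_bias.entry_stage!r}")
        unknown = set(self.library_noise) - set(LIBRARY_LEVELS)
        if unknown:
            problems.append(f"unknown library levels: {sorted(unknown)}")
        if problems:
            raise ConfigError("invalid config: " + "; ".join(problems))

    @property
    def sites(self) -> list[str]:
        return [f"Site{i + 1}" for i in range(self.n_sites)]

    @property
    def libraries(self) -> list[str]:
        return [lvl for lvl in LIBRARY_LEVELS if lvl in self.library_noise]


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery testing."""

    proportions: dict  # (site, run, library) -> pd.Series over species
    site_log2fc: pd.Series  # per species, site2 vs site1 (0 where unaffected)
    aberrant_runs: list[str]
    biased_phyla: list[str]
    biased_taxa: list[str]
    bias_entry_stage: str
    reference_runs: list[str]
    run_depths: dict  # run -> mean soil depth


def _rng(seed: int, *keys) -> np.random.Generator:
    """Named substream: deterministic child generator of the config seed."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def mock_expected_profile() -> AbundanceTable:
    """Theoretical 8-genome mock community profile, in percent."""
    df = pd.DataFrame([_MOCK_PROFILE_PCT], index=["MOCK_expected"])
    return AbundanceTable(df, rank="species", kind="percent")


def mock_lineage() -> TaxonomyLineage:
    df = pd.DataFrame.from_dict(_MOCK_LINEAGE, orient="index",
                                columns=["genus", "class", "phylum"])
    return TaxonomyLineage(df)


def build_taxonomy(config: SyntheticConfig) -> TaxonomyLineage:
    """Balanced synthetic lineage with deterministic labels.

    Soil species are labelled ``p<i>c<j>g<k>s<l>``; the 8 mock-community
    species (with their real lineages) are appended so pooled tables always
    have lineage coverage.
    """
    config.validate()
    rows = {}
    for p in range(config.n_phyla):
        phylum = f"Phylum{p + 1}"
        for c in range(config.n_classes_per_phylum):
            cls = f"{phylum}_Class{c + 1}"
            for g in range(config.n_genera_per_class):
                genus = f"{cls}_Genus{g + 1}"
                for s in range(config.n_species_per_genus):
                    rows[f"{genus}_sp{s + 1}"] = (genus, cls, phylum)
    rows.update(_MOCK_LINEAGE)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["genus", "class", "phylum"])
    return TaxonomyLineage(df)


def soil_species(lineage: TaxonomyLineage) -> list[str]:
    return [t for t in lineage.data.index if t not in _MOCK_LINEAGE]


def simulate_base_community(lineage: TaxonomyLineage, config: SyntheticConfig,
                            seed: int | None = None) -> pd.Series:
    """Lognormal base abundance profile over the soil species; sums to 1."""
    species = soil_species(lineage)
    rng = _rng(config.seed if seed is None else seed, "base")
    logabund = rng.normal(config.lognormal_mu, config.lognormal_sigma, len(species))
    prop = np.exp(logabund)
    prop /= prop.sum()
    return pd.Series(prop, index=species)


@dataclass
class _EffectDraws:
    """All systematic (non-sampling) effect draws, fixed by the config seed."""

    site_multiplier: pd.DataFrame    # sites x species, 2**log2fc
    site_log2fc: pd.Series
    bias_multiplier: pd.Series       # per species, 2**per-genus bias
    biased_phyla: list[str]
    biased_taxa: list[str]
    noise_multiplier: dict           # (run, library) -> pd.Series per species

    @classmethod
    def from_config(cls, config: SyntheticConfig, lineage: TaxonomyLineage) -> "_EffectDraws":
        species = soil_species(lineage)
        sub = lineage.data.loc[species]

        rng_site = _rng(config.seed, "site-effect")
        n_affected = int(round(config.site_effect.fraction_affected * len(species)))
        affected = rng_site.choice(len(species), size=n_affected, replace=False)
        site_lfc = np.zeros(len(species))
        site_lfc[affected] = rng_site.normal(0.0, config.site_effect.log2fc_sd, n_affected)
        site_log2fc = pd.Series(site_lfc, index=species)
        # site 1 is the baseline; later sites scale affected taxa by 2**lfc
        mult = pd.DataFrame(1.0, index=config.sites, columns=species)
        for site in config.sites[1:]:
            mult.loc[site] = 2.0 ** site_log2fc.values
        site_multiplier = mult

        phyla = [f"Phylum{p + 1}" for p in range(config.n_phyla)]
        biased_phyla = phyla[: config.aberrant_bias.n_biased_phyla]
        rng_bias = _rng(config.seed, "aberrant-bias")
        genera = sub["genus"].unique()
        genus_bias = pd.Series(0.0, index=genera)
        biased_genera = sub.loc[sub["phylum"].isin(biased_phyla), "genus"].unique()
        genus_bias.loc[biased_genera] = rng_bias.normal(
            0.0, config.aberrant_bias.per_genus_log2_sd, len(biased_genera))
        bias_multiplier = pd.Series(
            2.0 ** genus_bias.loc[sub["genus"]].values, index=species)
        biased_taxa = list(sub.index[sub["phylum"].isin(biased_phyla)])

        noise_multiplier = {}
        for run in config.runs:
            for lib in config.libraries:
                sigma = config.library_noise[lib]
                if sigma > 0:
                    rng_n = _rng(config.seed, "autonomy-noise", run.name, lib)
                    noise = np.exp(rng_n.normal(0.0, sigma, len(species)))
                else:
                    noise = np.ones(len(species))
                noise_multiplier[(run.name, lib)] = pd.Series(noise, index=species)
        return cls(site_multiplier, site_log2fc, bias_multiplier,
                   biased_phyla, biased_taxa, noise_multiplier)


def apply_effects(base: pd.Series, config: SyntheticConfig,
                  context: tuple[str, str, str],
                  lineage: TaxonomyLineage | None = None,
                  draws: _EffectDraws | None = None) -> pd.Series:
    """True proportions for one (site, run, library) context.

    Applies the site effect, then (if the run is aberrant and the library's
    autonomy includes the bias entry stage) the phylum-wide per-genus bias,
    then multiplicative autonomy noise, and renormalises.
    """
    site, run_name, library = context
    if draws is None:
        if lineage is None:
            lineage = build_taxonomy(config)
        draws = _EffectDraws.from_config(config, lineage)
    if site not in config.sites:
        raise KeyError(f"unknown site {site!r}")
    run = next((r for r in config.runs if r.name == run_name), None)
    if run is None:
        raise KeyError(f"unknown run {run_name!r}")
    if library not in config.libraries:
        raise KeyError(f"unknown library {library!r}")

    prop = base * draws.site_multiplier.loc[site, base.index]
    if run.aberrant and library in _STAGE_LIBRARIES[config.aberrant_bias.entry_stage]:
        prop = prop * draws.bias_multiplier.loc[base.index]
    prop = prop * draws.noise_multiplier[(run_name, library)].loc[base.index]
    return prop / prop.sum()


def sample_counts(proportions: pd.Series | np.ndarray, depth: int,
                  theta: float, rng: np.random.Generator | int) -> np.ndarray:
    """Dirichlet-multinomial draw: p ~ Dir(theta*prop), counts ~ Mult(depth, p)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if theta <= 0:
        raise ValueError("overdispersion theta must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    prop = np.asarray(proportions, dtype=float)
    counts = np.zeros(len(prop), dtype=np.int64)
    nz = prop > 0
    alpha = theta * prop[nz]
    if nz.sum() == 1:
        counts[nz] = depth
        return counts
    p = rng.dirichlet(alpha)
    counts[nz] = rng.multinomial(int(depth), p)
    return counts


def _sample_id(run: str, library: str, *parts: str) -> str:
    lib = library.replace("/", "")
    return "_".join([run, lib, *parts])


def simulate_study(config: SyntheticConfig):
    """Simulate the full study.

    Returns
    -------
    (TaxonCountTable, SampleMetadata, funnels DataFrame, GroundTruth)
        The species-level pooled count table (soil + mock + control
        samples), the matching metadata, the per-run read-accounting
        funnel table, and the injected ground truth.
    """
    config.validate()
    lineage = build_taxonomy(config)
    species = soil_species(lineage)
    mock_taxa = list(_MOCK_LINEAGE)
    all_taxa = species + mock_taxa
    base = simulate_base_community(lineage, config)
    draws = _EffectDraws.from_config(config, lineage)

    mock_prop_base = pd.Series(
        np.array(list(_MOCK_PROFILE_PCT.values())) / 100.0, index=mock_taxa)

    counts_rows: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    truth_props: dict[tuple, pd.Series] = {}
    funnel_rows = []

    for run in config.runs:
        rng_depth = _rng(config.seed, "depth", run.name)
        rng_counts = _rng(config.seed, "counts", run.name)
        rng_ctrl = _rng(config.seed, "controls", run.name)
        for lib in config.libraries:
            for site in config.sites:
                prop = apply_effects(base, config, (site, run.name, lib),
                                     lineage=lineage, draws=draws)
                truth_props[(site, run.name, lib)] = prop
                full = np.zeros(len(all_taxa))
                full[: len(species)] = prop.values
                for plot in range(1, config.n_plots + 1):
                    for rep_i in range(config.n_replicates):
                        rep = chr(ord("A") + rep_i)
                        depth = max(1, int(round(run.depth * np.exp(
                            rng_depth.normal(0.0, config.depth_jitter_sigma)))))
                        c = sample_counts(full, depth, config.overdispersion, rng_counts)
                        sid = _sample_id(run.name, lib, site, f"P{plot}", rep)
                        counts_rows[sid] = c
                        meta_rows[sid] = dict(run=run.name, library=lib, site=site,
                                              plot=f"P{plot}", replicate=rep,
                                              sample_type="soil")
            # one mock per (run, library)
            contam_idx = rng_ctrl.choice(len(species), size=3, replace=False)
            mock_full = np.zeros(len(all_taxa))
            mock_full[len(species):] = mock_prop_base.values * (1 - config.mock_contaminant_fraction)
            contam_w = rng_ctrl.dirichlet(np.ones(3))
            mock_full[contam_idx] = config.mock_contaminant_fraction * contam_w
            mc = sample_counts(mock_full, run.depth, config.overdispersion * 10,
                               rng_counts)
            sid = _sample_id(run.name, lib, "MOCK")
            counts_rows[sid] = mc
            meta_rows[sid] = dict(run=run.name, library=lib, site="NA", plot="NA",
                                  replicate="NA", sample_type="mock")
        # negative controls: a trickle of contaminant taxa only
        for ctype, short in (("ext_control", "ExtH2O"), ("pcr_control", "PCR1H2O")):
            cdepth = max(1, int(rng_ctrl.poisson(config.control_depth_mean)))
            ctaxa = rng_ctrl.choice(len(species), size=5, replace=False)
            cfull = np.zeros(len(all_taxa))
            cfull[ctaxa] = rng_ctrl.dirichlet(np.ones(5))
            cc = sample_counts(cfull, cdepth, config.overdispersion, rng_counts)
            sid = f"{run.name}_{short}"
            counts_rows[sid] = cc
            meta_rows[sid] = dict(run=run.name, library="Seq", site="NA", plot="NA",
                                  replicate="NA", sample_type=ctype)

        run_total = sum(int(c.sum()) for sid, c in counts_rows.items()
                        if meta_rows[sid]["run"] == run.name)
        lenfilt = run_total
        qualfilt = int(round(lenfilt / (1 - run.length_removed)))
        demux = int(round(qualfilt / (1 - run.quality_removed)))
        raw = int(round(demux / (1 - run.demux_removed)))
        funnel_rows.append(dict(run=run.name, raw_reads=raw, demux_reads=demux,
                                qualfilt_reads=qualfilt, lenfilt_reads=lenfilt))

    table = TaxonCountTable(
        pd.DataFrame.from_dict(counts_rows, orient="index", columns=all_taxa),
        rank="species")
    metadata = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))
    funnels = pd.DataFrame(funnel_rows).set_index("run")
    truth = GroundTruth(
        proportions=truth_props,
        site_log2fc=draws.site_log2fc,
        aberrant_runs=[r.name for r in config.runs if r.aberrant],
        biased_phyla=draws.biased_phyla,
        biased_taxa=draws.biased_taxa,
        bias_entry_stage=config.aberrant_bias.entry_stage,
        reference_runs=[r.name for r in config.runs if r.reference],
        run_depths={r.name: r.depth for r in config.runs},
    )
    return table, metadata, funnels, truth


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)


def config_from_dict(d: Mapping) -> SyntheticConfig:
    d = dict(d)
    if "runs" in d:
        d["runs"] = [RunSpec(**r) if not isinstance(r, RunSpec) else r for r in d["runs"]]
    if "site_effect" in d and not isinstance(d["site_effect"], SiteEffect):
        d["site_effect"] = SiteEffect(**d["site_effect"])
    if "aberrant_bias" in d and not isinstance(d["aberrant_bias"], AberrantBias):
        d["aberrant_bias"] = AberrantBias(**d["aberrant_bias"])
    return SyntheticConfig(**d)
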