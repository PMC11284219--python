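"""Taxon-abundance variability across runs and libraries.

Per-taxon log2 fold-changes (Log2FC) of CPM abundances are computed for
each (run, library) against the averaged primary-lab baseline, and between
the two field sites.  The headline between-run variability statistic is the
per-taxon *range* of Log2FC values across runs (max - min), compared across
library-autonomy levels with a one-way repeated-measures ANOVA (taxon as
subject, library as the within factor, Greenhouse-Geisser corrected) and
Benjamini-Hochberg-adjusted pairwise contrasts.

Site contrasts use median-of-ratios (RLE) size-factor normalisation and a
label-permutation test in place of a parametric count model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, SampleMetadata, TaxonCountTable, cpm_normalize


def rle_size_factors(table: TaxonCountTable) -> pd.Series:
    """Median-of-ratios (relative log expression) size factors.

    Computed on taxa with positive counts in every sample, then rescaled so
    the factors have geometric mean 1.
    """
    X = table.data.to_numpy(float)
    all_pos = (X > 0).all(axis=0)
    if not all_pos.any():
        raise ValueError("no taxon has positive counts in every sample; "
                         "consider a pseudocount before RLE normalisation")
    Xp = X[:, all_pos]
    log_geo = np.log(Xp).mean(axis=0)
    factors = np.exp(np.median(np.log(Xp) - log_geo, axis=1))
    factors /= np.exp(np.log(factors).mean())
    return pd.Series(factors, index=table.data.index, name="size_factor")


@dataclass
class Log2FCTable:
    """Taxon x (run, library) Log2FC values against a stated baseline."""

    values: pd.DataFrame  # index taxon, columns MultiIndex (run, library)
    baseline: str
    pseudocount: float
    rank: str


def log2fc_vs_reference(cpm: AbundanceTable, metadata: SampleMetadata,
                        reference_runs: list[str],
                        pseudocount: float = 0.5) -> Log2FCTable:
    """Per-(run, library) taxon Log2FC against the averaged reference runs.

    The baseline is the mean of the per-reference-run mean CPM over soil
    samples (so each primary lab weighs equally); Log2FC =
    log2((run mean + pc) / (baseline + pc)).
    """
    if not reference_runs:
        raise ValueError("at least one reference run is required")
    meta = metadata.for_samples(cpm.sample_ids)
    soil = meta[meta["sample_type"] == "soil"]
    missing = [r for r in reference_runs if r not in set(soil["run"])]
    if missing:
        raise ValueError(f"reference runs absent from table: {missing}")
    ref_means = []
    for ref in reference_runs:
        ids = soil.index[soil["run"] == ref]
        ref_means.append(cpm.data.loc[ids].mean(axis=0))
    baseline = pd.concat(ref_means, axis=1).mean(axis=1)
    cols = {}
    for (run, lib), sub in soil.groupby(["run", "library"], sort=False):
        if run in reference_runs:
            continue
        run_mean = cpm.data.loc[sub.index].mean(axis=0)
        cols[(run, lib)] = np.log2((run_mean + pseudocount) / (baseline + pseudocount))
    values = pd.DataFrame(cols)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["run", "library"])
    return Log2FCTable(values, baseline=f"mean of runs {reference_runs}",
                       pseudocount=pseudocount, rank=cpm.rank)


@dataclass
class SiteContrastResult:
    run: str
    library: str
    log2fc: pd.Series          # per taxon, site2 vs site1
    p_values: pd.Series        # permutation p per taxon
    p_adjusted: pd.Series      # BH across taxa
    sites: tuple[str, str]
    n_permutations: int


def log2fc_site_contrast(table: TaxonCountTable, metadata: SampleMetadata,
                         pseudocount: float = 0.5, n_perm: int = 1000,
                         seed: int = 0) -> list[SiteContrastResult]:
    """Between-site Log2FC per (run, library) with a permutation test.

    Counts are RLE-normalised within each (run, library) context; the
    statistic per taxon is log2((mean site2 + pc)/(mean site1 + pc)), tested
    two-sided by permuting site labels within the context and BH-adjusted
    across taxa.  Contexts missing a site are skipped with a warning record.
    """
    meta = metadata.for_samples(table.sample_ids)
    soil = meta[meta["sample_type"] == "soil"]
    sites = sorted(soil["site"].unique())
    if len(sites) != 2:
        raise ValueError(f"site contrast needs exactly 2 sites, found {sites}")
    results = []
    rng = np.random.default_rng(seed)
    for (run, lib), sub in soil.groupby(["run", "library"], sort=False):
        present = set(sub["site"])
        if not set(sites) <= present:
            import warnings
            warnings.warn(f"context ({run}, {lib}) missing a site; skipped")
            continue
        counts = table.subset_samples(list(sub.index))
        try:
            factors = rle_size_factors(counts)
        except ValueError:
            factors = pd.Series(1.0, index=counts.data.index)
        norm = counts.data.div(factors, axis=0).to_numpy(float)
        is_b = (sub["site"] == sites[1]).to_numpy()

        def stat(mask: np.ndarray) -> np.ndarray:
            mb = norm[mask].mean(axis=0)
            ma = norm[~mask].mean(axis=0)
            return np.log2((mb + pseudocount) / (ma + pseudocount))

        obs = stat(is_b)
        count_ge = np.zeros(len(obs))
        n_b = int(is_b.sum())
        for _ in range(n_perm):
            perm = np.zeros(len(is_b), dtype=bool)
            perm[rng.choice(len(is_b), size=n_b, replace=False)] = True
            count_ge += np.abs(stat(perm)) >= np.abs(obs)
        p = (1 + count_ge) / (1 + n_perm)
        p_adj = multipletests(p, method="fdr_bh")[1]
        taxa = counts.taxon_ids
        results.append(SiteContrastResult(
            run=str(run), library=str(lib),
            log2fc=pd.Series(obs, index=taxa),
            p_values=pd.Series(p, index=taxa),
            p_adjusted=pd.Series(p_adj, index=taxa),
            sites=(sites[0], sites[1]), n_permutations=n_perm))
    return results


def log2fc_range(log2fc: Log2FCTable) -> pd.DataFrame:
    """Per-taxon range (max - min) of Log2FC across runs, per library."""
    out = {}
    for lib in log2fc.values.columns.get_level_values("library").unique():
        sub = log2fc.values.xs(lib, axis=1, level="library")
        if sub.shape[1] < 2:
            raise ValueError(f"library {lib!r} has fewer than 2 runs")
        out[lib] = sub.max(axis=1) - sub.min(axis=1)
    return pd.DataFrame(out)


@dataclass
class VariabilityResult:
    """Repeated-measures comparison of Log2FC ranges across libraries."""

    rank: str
    mean_ranges: pd.Series        # per library
    ci_low: pd.Series
    ci_high: pd.Series
    f_statistic: float
    p_value: float                # Greenhouse-Geisser corrected
    p_uncorrected: float
    gg_epsilon: float
    pairwise: pd.DataFrame        # columns: a, b, t, p, p_fdr
    n_subjects: int
    n_dropped: int


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity estimate from the subjects x levels matrix."""
    S = np.cov(data, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((S ** 2).sum() - 2 * k * (row_means ** 2).sum()
                     + k ** 2 * grand ** 2)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def rm_anova_variability(ranges: pd.DataFrame, rank: str = "genus",
                         gg_correction: bool = True) -> VariabilityResult:
    """One-way within-subject ANOVA on Log2FC ranges (taxon as subject).

    Taxa with a missing range in any library are dropped listwise.  The
    omnibus F uses Greenhouse-Geisser-corrected degrees of freedom by
    default; pairwise paired t-tests are BH-adjusted.
    """
    complete = ranges.dropna()
    n_dropped = len(ranges) - len(complete)
    X = complete.to_numpy(float)
    n, k = X.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 libraries and >= 2 complete taxa")
    grand = X.mean()
    subj_means = X.mean(axis=1)
    treat_means = X.mean(axis=0)
    ss_treat = n * ((treat_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_treat - ss_subj
    df_treat, df_err = k - 1, (k - 1) * (n - 1)
    ms_treat = ss_treat / df_treat
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f, p_unc = 0.0, 1.0
        eps = 1.0
        p = 1.0
    else:
        f = ms_treat / ms_err
        p_unc = float(scipy.stats.f.sf(f, df_treat, df_err))
        eps = _gg_epsilon(X) if gg_correction else 1.0
        p = float(scipy.stats.f.sf(f, df_treat * eps, df_err * eps))

    sem = complete.sem(axis=0)
    tcrit = scipy.stats.t.ppf(0.975, n - 1)
    means = complete.mean(axis=0)

    pairs = []
    libs = list(complete.columns)
    for i, a in enumerate(libs):
        for b in libs[i + 1:]:
            t, pv = scipy.stats.ttest_rel(complete[a], complete[b])
            pairs.append(dict(a=a, b=b, t=float(t), p=float(pv)))
    pw = pd.DataFrame(pairs)
    if not pw.empty:
        pw["p_fdr"] = multipletests(pw["p"], method="fdr_bh")[1]
    return VariabilityResult(
        rank=rank, mean_ranges=means, ci_low=means - tcrit * sem,
        ci_high=means + tcrit * sem, f_statistic=float(f), p_value=p,
        p_uncorrected=p_unc, gg_epsilon=float(eps), pairwise=pw,
        n_subjects=n, n_dropped=n_dropped)
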