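"""Alpha diversity and richness-saturation diagnostics.

Observed species richness after rarefaction still carries a strong
signature of the original per-sample read count, because soil communities
are far from fully sampled at typical nanopore depths.  The richness-read
relationship is modelled with a rectangular hyperbola (Michaelis-Menten
form) ``S = Smax * R / (K + R)``, whose Lineweaver-Burk linearisation
``1/S = 1/Smax + (K/Smax) * (1/R)`` allows per-run slope/intercept outlier
tests against the pooled remaining runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .tables import SampleMetadata, TaxonCountTable


def rarefy(counts: np.ndarray | pd.Series, depth: int,
           rng: np.random.Generator | int) -> np.ndarray:
    """Subsample one sample's counts to ``depth`` reads without replacement.

    A multivariate hypergeometric draw; the result sums to ``depth`` and is
    taxon-wise bounded by the input.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    arr = np.asarray(counts, dtype=np.int64)
    total = int(arr.sum())
    if total < depth:
        raise ValueError(f"sample total {total} is below rarefaction depth {depth}")
    if total == depth:
        return arr.copy()
    return rng.multivariate_hypergeometric(arr, depth, method="marginals")


@dataclass
class RarefactionResult:
    table: TaxonCountTable
    excluded: list[str] = field(default_factory=list)  # samples below depth


def rarefy_table(table: TaxonCountTable, depth: int, seed: int = 0) -> RarefactionResult:
    """Rarefy every sample; samples below ``depth`` are excluded and recorded."""
    rng = np.random.default_rng(seed)
    sizes = table.library_sizes()
    keep = sizes.index[sizes >= depth]
    excluded = [s for s in table.sample_ids if s not in set(keep)]
    rows = {s: rarefy(table.data.loc[s].to_numpy(), depth, rng) for s in keep}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.taxon_ids)
    return RarefactionResult(TaxonCountTable(out, rank=table.rank), excluded)


def observed_richness(counts: np.ndarray | pd.Series) -> int:
    """Number of taxa with a non-zero count."""
    return int((np.asarray(counts) > 0).sum())


def richness_table(table: TaxonCountTable) -> pd.Series:
    return (table.data > 0).sum(axis=1).rename("richness")


def richness_anova(richness: pd.Series, metadata: SampleMetadata) -> pd.DataFrame:
    """ANOVA of richness on site, library and run-within-library.

    Type-II sums of squares; partial eta^2 = SS_effect / (SS_effect + SS_resid).
    """
    meta = metadata.for_samples(richness.index)
    df = pd.DataFrame({"richness": richness.astype(float),
                       "site": meta["site"], "library": meta["library"],
                       "run": meta["run"]})
    for factor in ("site", "library", "run"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has a single level")
    model = smf.ols("richness ~ C(site) + C(library) + C(library):C(run)",
                    data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    ss_resid = tab.loc["Residual", "sum_sq"]
    denom = tab["sum_sq"] + ss_resid
    # constant response: all sums of squares are float noise; effects are nil
    tol = 1e-12 * len(df) * (1.0 + float(df["richness"].mean()) ** 2)
    effect_ss = tab["sum_sq"].where(tab["sum_sq"] > tol, 0.0)
    tab["partial_eta_sq"] = np.where(effect_ss > 0,
                                     effect_ss / denom.where(denom > 0, 1.0), 0.0)
    tab.loc["Residual", "partial_eta_sq"] = np.nan
    return tab.rename(index={"C(site)": "site", "C(library)": "library",
                             "C(library):C(run)": "run(library)"})


@dataclass
class SaturationFit:
    """Michaelis-Menten saturation fit for one group."""

    group: str
    smax: float
    smax_se: float
    k: float
    k_se: float
    df_resid: int
    flagged: bool = False  # negative/degenerate parameter estimate
    note: str = ""


def _lb_init(reads: np.ndarray, richness: np.ndarray) -> tuple[float, float]:
    """Lineweaver-Burk initial values (Smax0, K0) for the nonlinear fit."""
    x, y = 1.0 / reads, 1.0 / richness
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0:
        return float(richness.max()) * 1.5, float(np.median(reads))
    smax0 = 1.0 / intercept
    k0 = slope * smax0
    if k0 <= 0:
        k0 = float(np.median(reads))
    return smax0, k0


def fit_michaelis_menten(reads: pd.Series | np.ndarray,
                         richness: pd.Series | np.ndarray,
                         groups: pd.Series | np.ndarray | None = None
                         ) -> list[SaturationFit]:
    """Least-squares fit of S = Smax*R/(K+R), one fit per group.

    Initialised from the Lineweaver-Burk linearisation; standard errors come
    from the asymptotic covariance of the nonlinear fit.
    """
    reads = np.asarray(reads, dtype=float)
    richness = np.asarray(richness, dtype=float)
    if groups is None:
        groups = np.array(["all"] * len(reads))
    groups = np.asarray(groups)
    if (reads <= 0).any():
        raise ValueError("read counts must be positive")

    def mm(r, smax, k):
        return smax * r / (k + r)

    fits = []
    for g in pd.unique(groups):
        m = groups == g
        r, s = reads[m], richness[m]
        if m.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 points")
        if np.allclose(s, s[0]):
            # saturated limit: constant richness
            fits.append(SaturationFit(str(g), float(s[0]), 0.0, 0.0, 0.0,
                                      int(m.sum() - 2), flagged=True,
                                      note="constant richness; K degenerate at 0"))
            continue
        p0 = _lb_init(r, s)
        try:
            popt, pcov = scipy.optimize.curve_fit(mm, r, s, p0=p0, maxfev=20_000)
        except RuntimeError as exc:
            raise RuntimeError(
                f"Michaelis-Menten fit did not converge for group {g!r}; "
                f"initial values Smax0={p0[0]:.4g}, K0={p0[1]:.4g}") from exc
        se = np.sqrt(np.diag(pcov))
        flagged = bool(popt[0] <= 0 or popt[1] <= 0)
        fits.append(SaturationFit(str(g), float(popt[0]), float(se[0]),
                                  float(popt[1]), float(se[1]),
                                  int(m.sum() - 2), flagged=flagged,
                                  note="negative parameter estimate" if flagged else ""))
    return fits


@dataclass
class LBRunTest:
    """Per-run Lineweaver-Burk fit and deviation test vs the pooled others."""

    run: str
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    p_slope: float
    p_intercept: float
    p_slope_fdr: float = np.nan
    p_intercept_fdr: float = np.nan
    n_points: int = 0
    excluded_points: int = 0


def _contrast_pvalue(estimate: float, se: float, df: int, scale: float) -> float:
    """Two-sided t p-value with a guard for the zero-residual exact-fit case."""
    if se == 0 or not np.isfinite(se) or se < 1e-12 * max(scale, 1e-300):
        return 1.0 if abs(estimate) <= 1e-8 * max(scale, 1e-300) else 0.0
    return float(2 * scipy.stats.t.sf(abs(estimate) / se, df))


def fit_lineweaver_burk(reads: pd.Series | np.ndarray,
                        richness: pd.Series | np.ndarray,
                        runs: pd.Series | np.ndarray) -> list[LBRunTest]:
    """Per-run OLS fits of 1/S on 1/R plus deviation tests.

    Each run's intercept and slope are contrasted against a pooled fit of
    all remaining runs via an indicator-interaction model; two-sided t
    p-values, with Benjamini-Hochberg adjusted versions across runs.
    Points with zero richness are excluded with a record.
    """
    reads = np.asarray(reads, dtype=float)
    richness = np.asarray(richness, dtype=float)
    runs = np.asarray(runs)
    ok = richness > 0
    n_excl_total = int((~ok).sum())
    reads, richness, runs = reads[ok], richness[ok], runs[ok]
    if (reads <= 0).any():
        raise ValueError("read counts must be positive")
    x, y = 1.0 / reads, 1.0 / richness

    tests = []
    for run in pd.unique(runs):
        m = runs == run
        if m.sum() < 3:
            raise ValueError(f"run {run!r} has fewer than 3 usable points")
        b1, b0 = np.polyfit(x[m], y[m], 1)
        resid = y[m] - (b0 + b1 * x[m])
        dfree = m.sum() - 2
        s2 = resid @ resid / dfree if dfree > 0 else 0.0
        sxx = np.sum((x[m] - x[m].mean()) ** 2)
        slope_se = float(np.sqrt(s2 / sxx))
        int_se = float(np.sqrt(s2 * (1 / m.sum() + x[m].mean() ** 2 / sxx)))

        # deviation model: y = a0 + a1 x + g0 I(run) + g1 I(run) x
        X = np.column_stack([np.ones_like(x), x, m.astype(float), m * x])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        rss = float(np.sum((y - fitted) ** 2))
        df_full = len(y) - rank
        sigma2 = rss / df_full if df_full > 0 else 0.0
        xtx_inv = np.linalg.pinv(X.T @ X)
        se_g0 = float(np.sqrt(sigma2 * xtx_inv[2, 2]))
        se_g1 = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
        scale_y = float(np.abs(y).max())
        scale_slope = scale_y / float(np.abs(x).max())
        ss_y = float(np.sum((y - y.mean()) ** 2))
        if rss <= 1e-16 * max(ss_y, 1e-300):
            # exact fit: contrasts are either truly zero or truly nonzero
            p_int = 1.0 if abs(beta[2]) <= 1e-8 * scale_y else 0.0
            p_slo = 1.0 if abs(beta[3]) <= 1e-8 * scale_slope else 0.0
        else:
            p_int = _contrast_pvalue(beta[2], se_g0, df_full, scale_y)
            p_slo = _contrast_pvalue(beta[3], se_g1, df_full, scale_slope)
        tests.append(LBRunTest(run=str(run), slope=float(b1), slope_se=slope_se,
                               intercept=float(b0), intercept_se=int_se,
                               p_slope=p_slo, p_intercept=p_int,
                               n_points=int(m.sum()),
                               excluded_points=n_excl_total))
    if tests:
        fdr_s = multipletests([t.p_slope for t in tests], method="fdr_bh")[1]
        fdr_i = multipletests([t.p_intercept for t in tests], method="fdr_bh")[1]
        for t, ps, pi in zip(tests, fdr_s, fdr_i):
            t.p_slope_fdr, t.p_intercept_fdr = float(ps), float(pi)
    return tests
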