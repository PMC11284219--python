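"""Beta-diversity distances, ordination and distance-based statistics.

Two sample-by-sample metrics are supported: Bray-Curtis on
Hellinger-transformed relative abundances (depth-sensitive) and the
classical Morisita index on raw integer counts (largely depth-insensitive,
because its lambda term corrects for finite sampling).  On top of the
distance matrices sit classical PCoA, a permutation MANOVA, and variance
partitioning by redundancy analysis on the PCoA axes (db-RDA) with
Ezekiel-adjusted R-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.spatial.distance

from .tables import AbundanceTable, TaxonCountTable, to_relative_abundance


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str
    raw_values: np.ndarray | None = None  # pre-clamp values when clamping applied
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def submatrix(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)],
                              self.metric)


def hellinger_transform(table: TaxonCountTable | AbundanceTable) -> AbundanceTable:
    """Square root of relative abundances; squared rows sum to 1.

    Depth-invariant: scaling a sample's counts leaves its transform unchanged.
    """
    rel = to_relative_abundance(table)
    out = np.sqrt(rel.data)
    return AbundanceTable(out, rank=rel.rank, kind="hellinger",
                          warnings=list(rel.warnings))


def bray_curtis(table: TaxonCountTable | AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y) between all pairs."""
    X = np.asarray(table.data, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    with np.errstate(invalid="ignore"):
        D = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(X, metric="braycurtis"))
    notes = []
    if np.isnan(D).any():
        notes.append("pairs of all-zero samples assigned distance 0")
        warnings.warn(notes[-1])
        D = np.nan_to_num(D, nan=0.0)
    return DistanceMatrix(list(table.data.index), D, "bray-curtis", notes=notes)


def morisita(table: TaxonCountTable, clamp: bool = True) -> DistanceMatrix:
    """Classical Morisita dissimilarity on integer counts.

    Similarity C = 2*sum(x_i*y_i) / ((lambda_x + lambda_y) * N_x * N_y) with
    lambda = sum x(x-1) / (N(N-1)); distance = 1 - C.  For small counts C can
    exceed 1; by default the distance is clamped to [0, 1] with the raw
    values retained in ``raw_values``.
    """
    X = np.asarray(table.data)
    if not np.issubdtype(X.dtype, np.integer):
        raise TypeError("Morisita requires integer counts; use Morisita-Horn "
                        "for relative abundances")
    N = X.sum(axis=1).astype(float)
    if (N < 2).any():
        bad = [table.sample_ids[i] for i in np.where(N < 2)[0]]
        raise ValueError(f"Morisita needs sample totals >= 2; offending: {bad}")
    Xf = X.astype(float)
    lam = (Xf * (Xf - 1)).sum(axis=1) / (N * (N - 1))
    cross = Xf @ Xf.T
    denom = (lam[:, None] + lam[None, :]) * N[:, None] * N[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    D_raw = 1.0 - C
    np.fill_diagonal(D_raw, 0.0)
    D = np.clip(D_raw, 0.0, 1.0) if clamp else D_raw
    return DistanceMatrix(list(table.data.index), D, "morisita",
                          raw_values=D_raw if clamp else None)


def morisita_horn(table: TaxonCountTable | AbundanceTable) -> DistanceMatrix:
    """Morisita-Horn dissimilarity; accepts non-integer abundances."""
    X = np.asarray(table.data, dtype=float)
    N = X.sum(axis=1)
    if (N <= 0).any():
        raise ValueError("Morisita-Horn requires positive sample totals")
    lam = (X ** 2).sum(axis=1) / N ** 2
    cross = X @ X.T
    denom = (lam[:, None] + lam[None, :]) * N[:, None] * N[None, :]
    C = 2.0 * cross / denom
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(table.data.index), np.clip(D, 0.0, 1.0),
                          "morisita-horn")


def distance_to_similarity(D: DistanceMatrix) -> pd.DataFrame:
    """Elementwise s = 1 - d."""
    return 1.0 - D.to_frame()


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray          # samples x positive axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    explained: np.ndarray            # per positive axis, over positive eigvals
    negative_eigenvalue_note: str = ""

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(D: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) MDS by double centering and eigendecomposition.

    Negative eigenvalues (from non-Euclidean distances) are reported but
    excluded from the explained-variance denominator.
    """
    n = len(D.sample_ids)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    A = -0.5 * D.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    explained = eigvals[pos] / eigvals[pos].sum()
    note = ""
    neg = eigvals[eigvals < -1e-10 * max(abs(eigvals[0]), 1.0)]
    if len(neg):
        note = (f"{len(neg)} negative eigenvalues (min {neg.min():.3g}) "
                "excluded from the explained-variance denominator")
    return OrdinationResult(list(D.sample_ids), coords, eigvals, explained, note)


def permanova(D: DistanceMatrix, grouping, n_perm: int = 999,
              seed: int = 0) -> tuple[float, float]:
    """One-way permutational MANOVA on a distance matrix.

    Pseudo-F from the within/between decomposition of squared distances;
    p = (1 + #{perm F >= obs F}) / (1 + n_perm) with free label permutations.
    """
    groups = np.asarray(grouping)
    n = len(D.sample_ids)
    if len(groups) != n:
        raise ValueError("grouping length does not match distance matrix")
    labels, inv = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("perMANOVA needs at least 2 groups")
    counts = np.bincount(inv)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    D2 = D.values ** 2
    sst = D2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(assign: np.ndarray) -> float:
        ssw = 0.0
        for g in range(k):
            idx = np.where(assign == g)[0]
            sub = D2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssb = sst - ssw
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(inv)) >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return float(f_obs), float(p)


def _ezekiel(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_partition(D: DistanceMatrix, factors: pd.DataFrame) -> pd.DataFrame:
    """Marginal adjusted R-squared per factor by db-RDA.

    Each factor is regressed (as dummy variables) on the positive PCoA axes;
    R-squared is the explained fraction of total axis variance, adjusted with
    the Ezekiel correction.  Confounded factor pairs produce a warning note.
    """
    ord_res = pcoa(D)
    Y = ord_res.coordinates
    Yc = Y - Y.mean(axis=0)
    total = float((Yc ** 2).sum())
    n = Y.shape[0]
    factors = factors.loc[D.sample_ids]
    rows = []
    for name in factors.columns:
        dummies = pd.get_dummies(factors[name], drop_first=True).to_numpy(float)
        p = dummies.shape[1]
        if p == 0:
            rows.append(dict(factor=name, r2=0.0, r2_adj=0.0, df=0, note="single level"))
            continue
        Xc = dummies - dummies.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        fitted = Xc @ beta
        r2 = float((fitted ** 2).sum() / total)
        rows.append(dict(factor=name, r2=r2, r2_adj=_ezekiel(r2, n, p), df=p, note=""))
    out = pd.DataFrame(rows).set_index("factor")
    # crude confounding screen: two factors with identical groupings
    for i, a in enumerate(factors.columns):
        for b in factors.columns[i + 1:]:
            tab = pd.crosstab(factors[a], factors[b])
            if ((tab > 0).sum(axis=1) == 1).all() and ((tab > 0).sum(axis=0) == 1).all():
                msg = f"factors {a!r} and {b!r} are confounded; shared fraction not separable"
                warnings.warn(msg)
                out.loc[a, "note"] = (out.loc[a, "note"] + "; " + msg).strip("; ")
    return out
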