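import subprocess

import numpy as np
import pandas as pd
import pytest

from seqrunqc import (
    TaxonCountTable,
    bray_curtis,
    distance_to_similarity,
    hellinger_transform,
    morisita,
    morisita_horn,
    pcoa,
    permanova,
    rarefy,
    variance_partition,
)

from conftest import random_count_table


# -- independent brute-force oracles (kept deliberately naive) --------------

def bc_brute(x, y):
    return sum(abs(a - b) for a, b in zip(x, y)) / sum(a + b for a, b in zip(x, y))


def hellinger_brute(row):
    total = sum(row)
    return [np.sqrt(v / total) for v in row]


def morisita_brute(x, y):
    nx, ny = sum(x), sum(y)
    lam_x = sum(v * (v - 1) for v in x) / (nx * (nx - 1))
    lam_y = sum(v * (v - 1) for v in y) / (ny * (ny - 1))
    c = 2 * sum(a * b for a, b in zip(x, y)) / ((lam_x + lam_y) * nx * ny)
    return 1 - c


class TestHellinger:
    def test_hand_values(self):
        t = TaxonCountTable(pd.DataFrame([[1, 1, 2]], index=["s"], columns=list("abc")))
        h = hellinger_transform(t)
        np.testing.assert_allclose(h.data.loc["s"], [0.5, 0.5, 0.70710678], atol=1e-8)

    def test_single_taxon_row(self):
        t = TaxonCountTable(pd.DataFrame([[7]], index=["s"], columns=["a"]))
        assert hellinger_transform(t).data.loc["s", "a"] == 1.0

    def test_depth_invariance(self):
        t1 = TaxonCountTable(pd.DataFrame([[1, 2, 3]], index=["s"], columns=list("abc")))
        t10 = TaxonCountTable(pd.DataFrame([[10, 20, 30]], index=["s"], columns=list("abc")))
        pd.testing.assert_frame_equal(hellinger_transform(t1).data,
                                      hellinger_transform(t10).data)

    def test_squared_rows_sum_to_one(self):
        t = random_count_table(np.random.default_rng(0))
        h = hellinger_transform(t)
        np.testing.assert_allclose((h.data ** 2).sum(axis=1), 1.0, atol=1e-9)


class TestBrayCurtis:
    def test_disjoint_and_identical(self):
        t = TaxonCountTable(pd.DataFrame([[1, 0], [0, 1], [1, 0]],
                                         index=["a", "b", "c"], columns=["x", "y"]))
        D = bray_curtis(t)
        assert D.to_frame().loc["a", "b"] == 1.0
        assert D.to_frame().loc["a", "c"] == 0.0

    def test_hand_value(self):
        t = TaxonCountTable(pd.DataFrame([[2, 2], [1, 3]], index=["a", "b"],
                                         columns=["x", "y"]))
        assert bray_curtis(t).to_frame().loc["a", "b"] == pytest.approx(0.25)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            t = random_count_table(rng, n_samples=4, n_taxa=6, depth=100)
            D = bray_curtis(t).values
            X = t.data.to_numpy()
            for i in range(4):
                for j in range(i + 1, 4):
                    assert D[i, j] == pytest.approx(bc_brute(X[i], X[j]), abs=1e-10)

    def test_all_zero_pair_warns_and_is_zero(self):
        t = TaxonCountTable(pd.DataFrame([[0, 0], [0, 0], [1, 1]],
                                         index=["z1", "z2", "s"], columns=["x", "y"]))
        with pytest.warns(UserWarning):
            D = bray_curtis(t)
        assert D.to_frame().loc["z1", "z2"] == 0.0


class TestMorisita:
    def test_shared_single_taxon(self):
        t = TaxonCountTable(pd.DataFrame([[10, 0], [10, 0]], index=["a", "b"],
                                         columns=["x", "y"]))
        assert morisita(t).to_frame().loc["a", "b"] == pytest.approx(0.0)

    def test_no_shared_taxa(self):
        t = TaxonCountTable(pd.DataFrame([[10, 0], [0, 10]], index=["a", "b"],
                                         columns=["x", "y"]))
        assert morisita(t).to_frame().loc["a", "b"] == pytest.approx(1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = random_count_table(rng, n_samples=3, n_taxa=6, depth=80)
            D = morisita(t)
            raw = D.raw_values
            X = t.data.to_numpy()
            for i in range(3):
                for j in range(i + 1, 3):
                    assert raw[i, j] == pytest.approx(morisita_brute(X[i], X[j]),
                                                      abs=1e-10)

    def test_non_integer_rejected(self):
        from seqrunqc import to_relative_abundance
        t = random_count_table(np.random.default_rng(0))
        with pytest.raises(TypeError, match="Morisita-Horn"):
            morisita(to_relative_abundance(t))  # type: ignore[arg-type]
        # the suggested alternative does accept relative abundances
        morisita_horn(to_relative_abundance(t))

    def test_depth_robustness_vs_bray_curtis(self):
        # scaling both samples 100x barely moves Morisita while Bray-Curtis
        # on unequal-depth raw counts moves a lot
        rng = np.random.default_rng(3)
        t1 = random_count_table(rng, n_samples=2, n_taxa=10, depth=2000)
        t100 = TaxonCountTable(t1.data * 100)
        d1 = morisita(t1).to_frame().iloc[0, 1]
        d100 = morisita(t100).to_frame().iloc[0, 1]
        assert abs(d1 - d100) < 0.01


@pytest.mark.parametrize("method,ours", [("bray", bray_curtis), ("morisita", morisita)])
def test_vegan_oracle_agreement(tmp_path, method, ours):
    """Dual-route check against R vegan's vegdist on one random table."""
    rng = np.random.default_rng(9)
    t = random_count_table(rng, n_samples=5, n_taxa=8, depth=150)
    counts_path = tmp_path / "counts.tsv"
    t.data.to_csv(counts_path, sep="\t")
    out_path = tmp_path / "d.tsv"
    script = (
        f'x <- as.matrix(read.delim("{counts_path}", row.names=1));'
        f'd <- vegan::vegdist(x, method="{method}");'
        f'write.table(as.matrix(d), "{out_path}", sep="\\t", col.names=NA)'
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    expected = pd.read_csv(out_path, sep="\t", index_col=0).to_numpy()
    np.testing.assert_allclose(ours(t).values, expected, atol=1e-8)


def test_distance_to_similarity_involution():
    t = random_count_table(np.random.default_rng(5))
    D = bray_curtis(t)
    S = distance_to_similarity(D)
    np.testing.assert_allclose(1.0 - S, D.to_frame(), atol=1e-12)
    assert float(S.to_numpy().min()) >= 0.0


class TestPCoA:
    def test_three_equidistant_points(self):
        ids = ["a", "b", "c"]
        from seqrunqc import DistanceMatrix
        D = DistanceMatrix(ids, np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]),
                           "test")
        res = pcoa(D)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_euclidean_round_trip(self):
        # distances from known 2-D points must be reproduced up to rotation
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform
        from seqrunqc import DistanceMatrix
        D = DistanceMatrix([f"s{i}" for i in range(10)],
                           squareform(pdist(pts)), "euclidean")
        res = pcoa(D)
        got = squareform(pdist(res.coordinates[:, :2]))
        np.testing.assert_allclose(got, D.values, atol=1e-8)

    def test_explained_proportions(self, genus_table):
        sub = genus_table.subset_samples(genus_table.sample_ids[:20])
        res = pcoa(bray_curtis(hellinger_transform(sub)))
        assert np.all(np.diff(res.explained) <= 1e-12)
        assert res.explained.sum() <= 1.0 + 1e-9

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        t = random_count_table(rng, n_samples=8, n_taxa=10, depth=200)
        D = bray_curtis(t)
        ours = pcoa(D)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D.values, ids=D.sample_ids))
        np.testing.assert_allclose(
            ours.eigenvalues[:3], theirs.eigvals.to_numpy()[:3], atol=1e-8)


class TestPermanova:
    def test_uniform_distances_give_unit_p(self):
        from seqrunqc import DistanceMatrix
        n = 8
        vals = np.ones((n, n)) - np.eye(n)
        D = DistanceMatrix([f"s{i}" for i in range(n)], vals, "test")
        _, p = permanova(D, ["a"] * 4 + ["b"] * 4, n_perm=199, seed=0)
        assert p > 0.5

    def test_separated_clusters_reach_floor_p(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        from scipy.spatial.distance import pdist, squareform
        from seqrunqc import DistanceMatrix
        D = DistanceMatrix([f"s{i}" for i in range(20)], squareform(pdist(pts)),
                           "euclidean")
        _, p = permanova(D, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        t = random_count_table(rng, n_samples=10, n_taxa=8, depth=150)
        D = bray_curtis(t)
        g1 = ["a"] * 5 + ["b"] * 5
        g2 = ["zzz"] * 5 + ["qqq"] * 5
        assert permanova(D, g1, 99, seed=3) == permanova(D, g2, 99, seed=3)

    def test_singleton_group_rejected(self):
        t = random_count_table(np.random.default_rng(0), n_samples=4)
        with pytest.raises(ValueError):
            permanova(bray_curtis(t), ["a", "b", "b", "b"])

    def test_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        t = random_count_table(rng, n_samples=12, n_taxa=10, depth=150)
        D = bray_curtis(t)
        grouping = ["a"] * 6 + ["b"] * 6
        f_ours, _ = permanova(D, grouping, n_perm=9, seed=0)
        res = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D.values, ids=D.sample_ids), grouping,
            permutations=9)
        assert f_ours == pytest.approx(res["test statistic"], rel=1e-9)


class TestVariancePartition:
    def test_single_level_explains_nothing(self):
        t = random_count_table(np.random.default_rng(0), n_samples=8)
        D = bray_curtis(t)
        factors = pd.DataFrame({"site": ["only"] * 8}, index=D.sample_ids)
        res = variance_partition(D, factors)
        assert res.loc["site", "r2_adj"] == 0.0

    def test_site_shift_dominates(self):
        rng = np.random.default_rng(1)
        base = rng.dirichlet(np.ones(12))
        shift = base.copy()
        shift[:4] *= 6
        shift /= shift.sum()
        rows, site, run = [], [], []
        for i in range(16):
            p = base if i < 8 else shift
            rows.append(rng.multinomial(400, p))
            site.append("A" if i < 8 else "B")
            run.append(f"r{i % 4}")
        t = TaxonCountTable(pd.DataFrame(rows, index=[f"s{i}" for i in range(16)],
                                         columns=[f"t{j}" for j in range(12)]))
        D = bray_curtis(hellinger_transform(t))
        res = variance_partition(D, pd.DataFrame({"site": site, "run": run},
                                                 index=t.sample_ids))
        assert res.loc["site", "r2_adj"] > 3 * max(res.loc["run", "r2_adj"], 0.01)

    def test_adjusted_r2_bounded(self, genus_table, study):
        meta = study["metadata"].data
        soil_ids = [s for s in genus_table.sample_ids
                    if meta.loc[s, "sample_type"] == "soil"][:40]
        D = bray_curtis(hellinger_transform(genus_table.subset_samples(soil_ids)))
        factors = meta.loc[soil_ids, ["site", "run", "library"]]
        res = variance_partition(D, factors)
        assert (res["r2_adj"] <= 1.0).all()


def test_morisita_less_depth_sensitive_than_bray_curtis():
    # a sample vs its own rarefied copy: Morisita similarity should beat
    # Bray-Curtis-on-counts similarity nearly always
    rng = np.random.default_rng(77)
    wins = 0
    trials = 100
    for _ in range(trials):
        p = rng.dirichlet(np.full(30, 0.4))
        deep = rng.multinomial(20_000, p)
        shallow = rarefy(deep, 2_000, rng)
        t = TaxonCountTable(pd.DataFrame([deep, shallow], index=["deep", "shallow"],
                                         columns=[f"t{i}" for i in range(30)]))
        sim_m = 1 - morisita(t).to_frame().iloc[0, 1]
        sim_bc = 1 - bray_curtis(t).to_frame().iloc[0, 1]
        wins += sim_m > sim_bc
    assert wins >= 0.95 * trials
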