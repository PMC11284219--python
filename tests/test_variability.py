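import numpy as np
import pandas as pd
import pytest

from seqrunqc import (
    SampleMetadata,
    TaxonCountTable,
    aggregate_to_rank,
    cpm_normalize,
    log2fc_range,
    log2fc_site_contrast,
    log2fc_vs_reference,
    rle_size_factors,
    rm_anova_variability,
)


class TestRLE:
    def test_median_of_ratios_hand_value(self):
        t = TaxonCountTable(pd.DataFrame([[2, 4], [1, 2]], index=["s1", "s2"],
                                         columns=["a", "b"]))
        f = rle_size_factors(t)
        assert f["s1"] == pytest.approx(np.sqrt(2))
        assert f["s2"] == pytest.approx(1 / np.sqrt(2))

    def test_identical_samples_unit_factors(self):
        t = TaxonCountTable(pd.DataFrame([[5, 7, 9]] * 3,
                                         index=list("abc"), columns=list("xyz")))
        np.testing.assert_allclose(rle_size_factors(t), 1.0)

    def test_invariant_to_taxon_permutation(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.integers(1, 100, (4, 6)),
                            index=list("abcd"), columns=list("uvwxyz"))
        f1 = rle_size_factors(TaxonCountTable(data))
        f2 = rle_size_factors(TaxonCountTable(data[list("zyxwvu")]))
        np.testing.assert_allclose(f1, f2)

    def test_no_common_taxon_rejected(self):
        t = TaxonCountTable(pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"],
                                         columns=["x", "y"]))
        with pytest.raises(ValueError, match="pseudocount"):
            rle_size_factors(t)


def _soil_meta(ids, runs, libs, sites):
    n = len(ids)
    return SampleMetadata(pd.DataFrame({
        "run": runs, "library": libs, "site": sites,
        "plot": [f"p{i}" for i in range(n)], "replicate": ["A"] * n,
        "sample_type": ["soil"] * n}, index=ids))


class TestLog2FCReference:
    def test_identical_to_reference_is_zero(self):
        row = [100, 200, 700]
        ids = ["ref1", "ref2", "ev1"]
        t = TaxonCountTable(pd.DataFrame([row] * 3, index=ids, columns=list("abc")))
        meta = _soil_meta(ids, ["Lab1", "Lab4", "LabX"], ["Seq"] * 3, ["S"] * 3)
        lfc = log2fc_vs_reference(cpm_normalize(t), meta, ["Lab1", "Lab4"])
        np.testing.assert_allclose(lfc.values[("LabX", "Seq")], 0.0, atol=1e-12)

    def test_doubled_taxon_approaches_one(self):
        ids = ["ref", "ev"]
        t = TaxonCountTable(pd.DataFrame([[1000, 1000], [2000, 1000]],
                                         index=ids, columns=["a", "b"]))
        meta = _soil_meta(ids, ["Lab1", "LabX"], ["Seq"] * 2, ["S"] * 2)
        cpm = cpm_normalize(t)
        for pc, tol in ((0.5, 0.01), (1e-6, 1e-6)):
            lfc = log2fc_vs_reference(cpm, meta, ["Lab1"], pseudocount=pc)
            # CPM renormalises within sample; check the a-vs-b contrast
            vals = lfc.values[("LabX", "Seq")]
            assert vals["a"] - vals["b"] == pytest.approx(1.0, abs=tol)

    def test_missing_reference_rejected(self):
        ids = ["r", "e"]
        t = TaxonCountTable(pd.DataFrame([[1, 1]] * 2, index=ids, columns=["a", "b"]))
        meta = _soil_meta(ids, ["Lab1", "LabX"], ["Seq"] * 2, ["S"] * 2)
        with pytest.raises(ValueError, match="absent"):
            log2fc_vs_reference(cpm_normalize(t), meta, ["Lab9"])

    def test_scale_invariance(self):
        ids = ["ref", "ev"]
        t = TaxonCountTable(pd.DataFrame([[500, 300], [100, 900]],
                                         index=ids, columns=["a", "b"]))
        meta = _soil_meta(ids, ["Lab1", "LabX"], ["Seq"] * 2, ["S"] * 2)
        cpm = cpm_normalize(t)
        lfc1 = log2fc_vs_reference(cpm, meta, ["Lab1"])
        cpm.data *= 1.0  # CPM already fixes total mass; identity by contract
        lfc2 = log2fc_vs_reference(cpm, meta, ["Lab1"])
        pd.testing.assert_frame_equal(lfc1.values, lfc2.values)


class TestLog2FCRange:
    def test_hand_values(self):
        vals = pd.DataFrame({("r1", "Seq"): [1.0], ("r2", "Seq"): [-2.0],
                             ("r3", "Seq"): [0.5]})
        vals.columns = pd.MultiIndex.from_tuples(vals.columns,
                                                 names=["run", "library"])
        from seqrunqc.variability import Log2FCTable
        r = log2fc_range(Log2FCTable(vals, "b", 0.5, "genus"))
        assert r.loc[0, "Seq"] == pytest.approx(3.0)

    def test_adding_a_run_never_decreases_range(self):
        rng = np.random.default_rng(0)
        from seqrunqc.variability import Log2FCTable
        base_cols = {(f"r{i}", "Seq"): rng.normal(size=5) for i in range(3)}
        vals = pd.DataFrame(base_cols)
        vals.columns = pd.MultiIndex.from_tuples(vals.columns, names=["run", "library"])
        r3 = log2fc_range(Log2FCTable(vals, "b", 0.5, "genus"))
        vals2 = vals.copy()
        vals2[("r9", "Seq")] = rng.normal(size=5)
        r4 = log2fc_range(Log2FCTable(vals2, "b", 0.5, "genus"))
        assert (r4["Seq"] >= r3["Seq"] - 1e-12).all()


class TestSiteContrast:
    def _study(self, rng, effect=0.0, n_per_site=6, depth=5000):
        taxa = [f"t{i}" for i in range(30)]
        p = rng.dirichlet(np.ones(30))
        # put the true effect on a well-covered taxon
        j = int(np.argmax(p))
        p[[0, j]] = p[[j, 0]]
        p2 = p.copy()
        p2[0] *= 2 ** effect
        p2 /= p2.sum()
        rows, sites, ids = [], [], []
        for i in range(n_per_site * 2):
            use = p if i < n_per_site else p2
            rows.append(rng.multinomial(depth, use))
            sites.append("A" if i < n_per_site else "B")
            ids.append(f"s{i}")
        t = TaxonCountTable(pd.DataFrame(rows, index=ids, columns=taxa))
        meta = _soil_meta(ids, ["r1"] * len(ids), ["Seq"] * len(ids), sites)
        return t, meta

    def test_swapping_site_labels_negates_log2fc(self):
        rng = np.random.default_rng(1)
        t, meta = self._study(rng, effect=1.0)
        res = log2fc_site_contrast(t, meta, n_perm=20, seed=0)[0]
        flipped_meta = SampleMetadata(meta.data.assign(
            site=meta.data["site"].map({"A": "B", "B": "A"})))
        res2 = log2fc_site_contrast(t, flipped_meta, n_perm=20, seed=0)[0]
        np.testing.assert_allclose(res.log2fc, -res2.log2fc, atol=1e-10)

    def test_true_effect_detected_with_positive_sign(self):
        rng = np.random.default_rng(2)
        detected = 0
        n_sims = 20
        for _ in range(n_sims):
            t, meta = self._study(rng, effect=2.0, n_per_site=8, depth=8000)
            res = log2fc_site_contrast(t, meta, n_perm=1000, seed=int(rng.integers(2**31)))[0]
            if res.p_adjusted["t0"] < 0.05 and res.log2fc["t0"] > 0:
                detected += 1
        assert detected >= 0.9 * n_sims

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        rejections, total = 0, 0
        for _ in range(40):
            t, meta = self._study(rng, effect=0.0)
            res = log2fc_site_contrast(t, meta, n_perm=200,
                                       seed=int(rng.integers(2**31)))[0]
            rejections += (res.p_values < 0.05).sum()
            total += len(res.p_values)
        assert 0.01 < rejections / total < 0.09


class TestRMAnova:
    def test_identical_ranges_null_result(self):
        ranges = pd.DataFrame({"Seq": [1, 2, 3.0], "PCR/Seq": [1, 2, 3.0],
                               "Ext/PCR/Seq": [1, 2, 3.0]})
        res = rm_anova_variability(ranges)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_pvalues_valid_and_bh_monotone(self):
        rng = np.random.default_rng(0)
        ranges = pd.DataFrame(rng.gamma(2, 1, (30, 3)),
                              columns=["Seq", "PCR/Seq", "Ext/PCR/Seq"])
        res = rm_anova_variability(ranges)
        assert 0 <= res.p_value <= 1
        assert (res.pairwise["p_fdr"] >= res.pairwise["p"] - 1e-12).all()
        assert (res.ci_low <= res.mean_ranges).all()
        assert (res.mean_ranges <= res.ci_high).all()

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        k, n = 3, 25
        wide = pd.DataFrame(rng.normal(size=(n, k)) + [0, 0.3, 0.8],
                            columns=["Seq", "PCR/Seq", "Ext/PCR/Seq"])
        res = rm_anova_variability(wide)
        long = wide.reset_index().melt(id_vars="index", var_name="lib",
                                       value_name="y")
        aov = pg.rm_anova(data=long, dv="y", within="lib", subject="index",
                          correction=True)
        assert res.f_statistic == pytest.approx(float(aov["F"][0]), rel=1e-6)
        assert res.p_uncorrected == pytest.approx(float(aov["p_unc"][0]), rel=1e-6)
        assert res.p_value == pytest.approx(float(aov["p_GG_corr"][0]), rel=1e-3)
        assert res.gg_epsilon == pytest.approx(float(aov["eps"][0]), rel=1e-6)

    def test_missing_levels_dropped_with_count(self):
        ranges = pd.DataFrame({"Seq": [1, 2, np.nan], "PCR/Seq": [1, 2, 3.0],
                               "Ext/PCR/Seq": [1, 2, 3.0]})
        res = rm_anova_variability(ranges)
        assert res.n_dropped == 1
        assert res.n_subjects == 2


def test_autonomy_noise_ordering_on_simulated_study(genus_table, study):
    """Mean Log2FC range should increase Seq -> PCR/Seq -> Ext/PCR/Seq."""
    meta = study["metadata"]
    truth = study["truth"]
    soil_ids = [s for s in genus_table.sample_ids
                if meta.data.loc[s, "sample_type"] == "soil"]
    cpm = cpm_normalize(genus_table.subset_samples(soil_ids))
    lfc = log2fc_vs_reference(cpm, meta, truth.reference_runs)
    ranges = log2fc_range(lfc)
    means = ranges.mean()
    assert means["Seq"] < means["PCR/Seq"] < means["Ext/PCR/Seq"]
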