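"""Transcriptome arm: filtering, size factors, paired NB test, attenuation."""
import numpy as np
import pandas as pd
import pytest

from zfwound import atten, simgen


def toy_counts(rows, samples=None):
    samples = samples or [f"{t}_r{r}" for t in ("control", "amp")
                          for r in (1, 2, 3)]
    counts = pd.DataFrame(rows, columns=samples)
    counts.index = [f"g{i}" for i in range(len(counts))]
    counts.index.name = "gene"
    meta = pd.DataFrame({
        "sample": samples,
        "treatment": [s.rsplit("_r", 1)[0] for s in samples],
        "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
    })
    return counts, meta


class TestFilterLowCounts:
    def test_boundary_sum_29_removed_30_retained(self):
        counts, meta = toy_counts([
            [5, 5, 5, 4, 4, 4],   # sum 29 -> removed
            [5, 5, 5, 5, 5, 5],   # sum 30 -> retained
        ])
        kept = atten.filter_low_counts(counts, meta, "amp")
        assert list(kept) == ["g1"]

    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(0)
        counts, meta = toy_counts(rng.integers(0, 20, size=(100, 6)))
        kept = atten.filter_low_counts(counts, meta, "amp")
        oracle = counts.index[counts.sum(axis=1) >= 30]
        assert list(kept) == list(oracle)

    def test_missing_treatment_rejected(self):
        counts, meta = toy_counts([[10] * 6])
        with pytest.raises(ValueError):
            atten.filter_low_counts(counts, meta, "beclo")


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts, _ = toy_counts(np.tile([[10], [20], [400]], (1, 6)))
        np.testing.assert_allclose(atten.size_factors(counts), 1.0)

    def test_doubled_sample_detected(self):
        base = np.tile([[10], [20], [400], [7]], (1, 6)).astype(float)
        base[:, 2] *= 2
        counts, _ = toy_counts(base)
        sf = atten.size_factors(counts)
        geo_adjust = 2.0 ** (1 / 6)   # the doubled column shifts the geomean
        np.testing.assert_allclose(sf.iloc[2], 2.0 / geo_adjust, rtol=1e-12)
        np.testing.assert_allclose(sf.drop(sf.index[2]), 1.0 / geo_adjust,
                                   rtol=1e-12)

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(1)
        counts, _ = toy_counts(rng.poisson(100, size=(60, 6)))
        got = atten.size_factors(counts).to_numpy()
        mat = counts.to_numpy(float)
        ok = (mat > 0).all(axis=1)
        geo = np.exp(np.mean(np.log(mat[ok]), axis=1))
        oracle = np.median(mat[ok] / geo[:, None], axis=0)
        np.testing.assert_allclose(got, oracle, rtol=1e-12)

    def test_no_common_nonzero_gene_rejected(self):
        counts, _ = toy_counts([[0, 5, 5, 5, 5, 5], [5, 0, 5, 5, 5, 5]])
        with pytest.raises(ValueError):
            atten.size_factors(counts)


class TestPairedNBTest:
    def test_identical_groups_give_null_result(self):
        counts, meta = toy_counts(np.tile([[100], [50], [200]], (1, 6)))
        res = atten.paired_nb_test(counts, meta, "amp")
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        assert (res["pvalue"] > 0.9).all()

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(200, size=(50, 6)).astype(float)
        base[0, 3:] *= 8    # one gene strongly up in the treated samples
        counts, meta = toy_counts(base.astype(int))
        res = atten.paired_nb_test(counts, meta, "amp")
        assert res.loc["g0", "padj"] < 0.01
        assert res.loc["g0", "log2fc"] == pytest.approx(3.0, abs=0.3)

    def test_wald_matches_statsmodels_glm(self):
        # same fixed dispersion, design and offsets: per-gene cross-check of
        # the batched IRLS fit against the reference GLM implementation
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        counts, meta = toy_counts(rng.poisson(150, size=(10, 6)))
        res = atten.paired_nb_test(counts, meta, "amp")
        sf = atten.size_factors(counts)
        X = np.zeros((6, 4))
        X[:, 0] = 1.0
        X[[1, 4], 1] = 1.0
        X[[2, 5], 2] = 1.0
        X[3:, 3] = 1.0
        for gene in counts.index[:5]:
            y = counts.loc[gene].to_numpy(float)
            alpha = float(res.loc[gene, "dispersion"])
            glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                         offset=np.log(sf.to_numpy()))
            fit = glm.fit()
            assert res.loc[gene, "pvalue"] == pytest.approx(fit.pvalues[3],
                                                            rel=1e-4, abs=1e-8)

    def test_unequal_replicates_rejected(self):
        counts, meta = toy_counts(np.full((3, 6), 50))
        meta = meta.drop(index=5)
        with pytest.raises(ValueError):
            atten.paired_nb_test(counts.drop(columns=["amp_r3"]), meta, "amp")

    def test_pipeline_deterministic(self, null_counts):
        counts, meta, _ = null_counts
        r1 = atten.paired_nb_test(counts, meta, "amp")
        r2 = atten.paired_nb_test(counts, meta, "amp")
        pd.testing.assert_frame_equal(r1, r2)

    def test_log2fc_unbiased_at_moderate_baseline(self):
        # planted effects (500 genes among a mostly null background, so the
        # median-of-ratios reference stays valid) show no systematic bias
        config = simgen.CountSimConfig(
            n_genes=2500, frac_amp_responsive=0.2, frac_gc_insensitive=1.0,
            frac_beclo_responsive=0.0, lfc_amp_magnitude=(1.0, 2.5),
            baseline_log_mean=np.log(300.0), baseline_log_sd=0.3, seed=6)
        counts, meta, truth = simgen.simulate_counts(config)
        res = atten.paired_nb_test(counts, meta, "amp")
        merged = res.join(truth.set_index("gene"), how="inner")
        merged = merged[merged["lfc_amp"] != 0]
        assert len(merged) >= 500
        bias = (merged["log2fc"] - merged["lfc_amp"]).mean()
        assert abs(bias) < 0.1


class TestRegulationSets:
    def make_results(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])
        df["fold_change"] = 2.0 ** df["log2fc"]
        df["contrast"] = "amp"
        return df.set_index("gene", drop=False)

    def test_cutoff_rules(self):
        res = self.make_results([
            ("up_ok", np.log2(2.5), 0.04),     # FC 2.5, significant -> up
            ("fc_too_small", np.log2(1.8), 0.04),
            ("not_sig", np.log2(3.0), 0.06),
            ("down_ok", np.log2(0.3), 0.01),   # FC 0.3 < 1/2 -> down
            ("down_weak", np.log2(0.6), 0.01),
        ])
        sets = atten.classify_regulation({"amp": res})
        assert sets.up["amp"] == {"up_ok"}
        assert sets.down["amp"] == {"down_ok"}

    def test_venn_counts_match_set_algebra(self):
        sets = {"amp": {"A", "B", "C"}, "amp_beclo": {"B"}, "beclo": {"B", "C"}}
        venn = atten.venn_counts(sets)
        assert venn["amp"] == 3
        assert venn["amp&amp_beclo"] == 1
        assert venn["amp&beclo"] == 2
        assert venn["amp&amp_beclo&beclo"] == 1


class TestAttenuationFraction:
    def make_contrast(self, lfcs):
        df = pd.DataFrame({"gene": list(lfcs), "log2fc": list(lfcs.values())})
        return df.set_index("gene", drop=False)

    def test_classification_rules(self):
        amp = self.make_contrast({"a": 2.0, "b": -1.5, "c": 1.0, "d": 2.0})
        combo = self.make_contrast({"a": 1.0, "b": -2.0, "c": -0.5, "d": 2.0})
        rep = atten.attenuation_fraction(amp, combo, ["a", "b", "c", "d"])
        klass = rep.table.set_index("gene")["klass"]
        assert klass["a"] == "attenuated"
        assert klass["b"] == "enhanced"
        assert klass["c"] == "sign_flipped"
        assert klass["d"] == "unchanged"

    def test_fraction_arithmetic(self):
        amp = self.make_contrast({g: 2.0 for g in "abcd"})
        combo = self.make_contrast({"a": 1.0, "b": 0.5, "c": 1.5, "d": 3.0})
        rep = atten.attenuation_fraction(amp, combo, list("abcd"))
        assert rep.fraction_attenuated == pytest.approx(0.75)

    def test_classes_partition_the_set(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(50)]
        amp = self.make_contrast(dict(zip(genes, rng.normal(0, 2, 50))))
        combo = self.make_contrast(dict(zip(genes, rng.normal(0, 2, 50))))
        rep = atten.attenuation_fraction(amp, combo, genes)
        assert (rep.n_attenuated + rep.n_enhanced + rep.n_unchanged
                + rep.n_sign_flipped) == 50

    def test_missing_combo_gene_flagged_unchanged(self):
        amp = self.make_contrast({"a": 2.0, "b": 1.5})
        combo = self.make_contrast({"a": 1.0})
        rep = atten.attenuation_fraction(amp, combo, ["a", "b"])
        row = rep.table.set_index("gene").loc["b"]
        assert row["flagged"] and row["klass"] == "unchanged"

    def test_tolerance_widens_unchanged_band(self):
        amp = self.make_contrast({"a": 2.0})
        combo = self.make_contrast({"a": 1.8})
        strict = atten.attenuation_fraction(amp, combo, ["a"], tol=0.0)
        loose = atten.attenuation_fraction(amp, combo, ["a"], tol=0.5)
        assert strict.table["klass"].iloc[0] == "attenuated"
        assert loose.table["klass"].iloc[0] == "unchanged"

    def test_empty_set_rejected(self):
        amp = self.make_contrast({"a": 2.0})
        with pytest.raises(ValueError):
            atten.attenuation_fraction(amp, amp, [])

    def test_scale_invariance_under_count_multiplication(self):
        # multiplying every count by an integer leaves size-factor-normalized
        # fold changes (hence the attenuation classes) essentially unchanged
        config = simgen.CountSimConfig(n_genes=300, seed=9)
        counts, meta, _ = simgen.simulate_counts(config)
        reports = []
        for k in (1, 3):
            results = atten.run_all_contrasts(counts * k, meta)
            sets = atten.classify_regulation(results)
            amp_sig = sorted(sets.up["amp"] | sets.down["amp"])
            reports.append(atten.attenuation_fraction(
                results["amp"], results["amp_beclo"], amp_sig))
        assert reports[0].fraction_attenuated == pytest.approx(
            reports[1].fraction_attenuated, abs=0.02)


class TestImmuneGeneTable:
    def make_results(self):
        rows = {"tnfa": 2.0, "il1b": 1.0, "arg2": -1.0}
        out = {}
        for contrast in ("amp", "beclo", "amp_beclo"):
            df = pd.DataFrame({"gene": list(rows), "log2fc": list(rows.values())})
            df["fold_change"] = 2.0 ** df["log2fc"]
            out[contrast] = df.set_index("gene", drop=False)
        return out

    def test_empty_gene_list(self):
        assert atten.immune_gene_table(self.make_results(), []).empty

    def test_one_gene_three_rows(self):
        table = atten.immune_gene_table(self.make_results(), ["tnfa"])
        assert len(table) == 3
        assert set(table["contrast"]) == {"amp", "beclo", "amp_beclo"}

    def test_values_join_back_to_results(self):
        results = self.make_results()
        table = atten.immune_gene_table(results, ["tnfa", "arg2"])
        for _, row in table.iterrows():
            assert row["fold_change"] == results[row["contrast"]].loc[
                row["gene"], "fold_change"]
        # down-regulated genes expressed as negative ratios
        arg2 = table[table["gene"] == "arg2"]["signed_fold_change"]
        np.testing.assert_allclose(arg2, -2.0)

    def test_unknown_gene_warned_and_skipped(self):
        with pytest.warns(UserWarning):
            table = atten.immune_gene_table(self.make_results(), ["nope"])
        assert table.empty


class TestDdctFoldChange:
    def make_ct(self):
        return pd.DataFrame({
            "sample": ["c1", "c2", "t1", "t2"] * 2,
            "gene": ["il6"] * 4 + ["ppiab"] * 4,
            "ct": [22.0, 22.0, 20.0, 20.0, 15.0, 15.0, 15.0, 15.0],
        })

    def test_two_cycles_earlier_is_fourfold(self):
        fc = atten.ddct_fold_change(self.make_ct(), control_samples=["c1", "c2"])
        out = fc.set_index("sample")["fold_change"]
        assert out["t1"] == pytest.approx(4.0)
        assert out["c1"] == pytest.approx(1.0)

    def test_reference_shift_cancels(self):
        ct = self.make_ct()
        # shifting one sample's reference and target equally leaves FC fixed
        ct.loc[(ct["sample"] == "t1"), "ct"] += 1.0
        fc = atten.ddct_fold_change(ct, control_samples=["c1", "c2"])
        assert fc.set_index("sample")["fold_change"]["t1"] == pytest.approx(4.0)

    def test_matches_spreadsheet_oracle(self):
        rng = np.random.default_rng(10)
        samples = [f"s{i}" for i in range(6)]
        genes = ["il6", "tnfa", "mmp9"]
        rows = []
        for s in samples:
            ref = rng.uniform(14, 16)
            rows.append((s, "ppiab", ref))
            for g in genes:
                rows.append((s, g, rng.uniform(18, 26)))
        ct = pd.DataFrame(rows, columns=["sample", "gene", "ct"])
        controls = samples[:3]
        fc = atten.ddct_fold_change(ct, control_samples=controls)
        ref_ct = ct[ct["gene"] == "ppiab"].set_index("sample")["ct"]
        for g in genes:
            sub = ct[ct["gene"] == g].set_index("sample")["ct"]
            dct = sub - ref_ct
            ddct = dct - dct[controls].mean()
            expected = 2.0 ** (-ddct)
            got = fc[fc["gene"] == g].set_index("sample")["fold_change"]
            np.testing.assert_allclose(got[expected.index], expected, rtol=1e-12)

    def test_missing_reference_rejected(self):
        ct = self.make_ct()
        ct = ct[~((ct["sample"] == "t1") & (ct["gene"] == "ppiab"))]
        with pytest.raises(ValueError):
            atten.ddct_fold_change(ct, control_samples=["c1", "c2"])
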