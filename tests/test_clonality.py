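import numpy as np
import pandas as pd
import pytest

from ascna.clonality import (LOGR_WEIGHT, _best_c, compute_snv_clonality_table,
                             compute_scna_clonality_table, discretize_clonality,
                             expected_signal, expected_snv_vaf,
                             scna_clonality_fit, snv_adjusted_vaf,
                             snv_clonality)
from ascna.ploidy_admixture import AdmixtureEstimate, PloidyEstimate
from ascna.simulate import SegmentSpec, SNVSpec, TumorModel, simulate_tumor
from ascna.beta_core import compute_beta_table

from conftest import synthetic_beta_table


class TestExpectedSignal:
    def test_pure_clonal_hemizygous_deletion(self):
        beta, logr = expected_signal(1, 0, 1.0, 0.0)
        assert beta == 0.0 and logr == pytest.approx(-1.0)

    def test_half_admixed_clonal_deletion(self):
        beta, logr = expected_signal(1, 0, 1.0, 0.5)
        assert beta == pytest.approx(2 / 3)
        assert logr == pytest.approx(np.log2(3 / 4))

    def test_clonal_homozygous_deletion_at_zero_admixture(self):
        beta, logr = expected_signal(0, 0, 1.0, 0.0)
        assert beta == 1.0 and logr == -np.inf

    @pytest.mark.parametrize("a", [1, 2, 3])
    @pytest.mark.parametrize("c", [0.3, 1.0])
    @pytest.mark.parametrize("g", [0.0, 0.4])
    def test_balanced_states_always_beta_one(self, a, c, g):
        beta, _ = expected_signal(a, a, c, g)
        assert beta == pytest.approx(1.0)

    def test_shift_is_additive(self):
        _, l0 = expected_signal(2, 1, 0.7, 0.2, shift=0.0)
        _, l1 = expected_signal(2, 1, 0.7, 0.2, shift=-0.34)
        assert l1 - l0 == pytest.approx(-0.34)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_signal(1, 2, 1.0, 0.0)
        with pytest.raises(ValueError):
            expected_signal(1, 0, 1.5, 0.0)


class TestScnaFit:
    def test_pure_sample_half_clonal_deletion(self):
        """beta 2/3 with logRp log2(3/4) in a pure sample: the deletion is
        carried by half the tumor cells."""
        fit = scna_clonality_fit(2 / 3, np.log2(3 / 4), 2 / 3 - 0.03,
                                 2 / 3 + 0.03, 0.0, 0.0, 0.0)
        assert fit.state == (1, 0)
        assert fit.clonality == pytest.approx(0.5, abs=1e-6)

    def test_clonal_deletion_at_admixture(self):
        beta, logr = expected_signal(1, 0, 1.0, 0.3)
        fit = scna_clonality_fit(beta, logr, beta - 0.03, beta + 0.03,
                                 0.3, 0.27, 0.33)
        assert fit.state == (1, 0)
        assert 0.95 <= fit.clonality <= 1.0
        assert fit.clonality_min <= fit.clonality <= fit.clonality_max

    def test_wild_type_not_analysed(self):
        fit = scna_clonality_fit(0.97, 0.01, 0.93, 1.0, 0.3, 0.27, 0.33)
        assert not fit.analysed

    def test_poor_fit_not_analysed(self):
        # strong allelic imbalance at an extreme deletion logR fits no
        # single-state mixture
        fit = scna_clonality_fit(0.5, -2.5, 0.47, 0.53, 0.1, 0.08, 0.12)
        assert not fit.analysed
        assert fit.residual > 0.05

    def test_subclonal_homozygous_deletion_is_recognized(self):
        # balanced beta with a deep logR: both alleles lost in part of the
        # tumor cells; handled by the general enumeration via (0, 0)
        fit = scna_clonality_fit(0.98, -0.9, 0.95, 1.0, 0.1, 0.08, 0.12)
        assert fit.analysed
        assert fit.state == (0, 0)
        assert 0 < fit.clonality < 1

    @pytest.mark.parametrize("seed", range(10))
    def test_per_state_optimizer_matches_exhaustive_grid(self, seed):
        """Bounded refinement is at least as good as a 1e-4 clonality grid."""
        rng = np.random.default_rng(seed)
        beta = float(rng.uniform(0.1, 0.95))
        logrp = float(rng.uniform(-1.2, 1.0))
        g = float(rng.uniform(0.0, 0.6))
        cs = np.linspace(0, 1, 10001)
        for a in range(4):
            for b in range(a + 1):
                if (a, b) == (1, 1):
                    continue
                c_opt, d_opt = _best_c(a, b, g, beta, logrp)
                grid_d = np.empty_like(cs)
                for i, c in enumerate(cs):
                    be, le = expected_signal(a, b, c, g)
                    grid_d[i] = ((be - beta) ** 2
                                 + LOGR_WEIGHT * (le - logrp) ** 2
                                 if np.isfinite(le) else np.inf)
                assert d_opt <= grid_d.min() + 1e-6

    def test_deletion_clonality_decreases_with_beta(self):
        g = 0.2
        cs = []
        for beta in (0.4, 0.5, 0.6, 0.7):
            c, _ = _best_c(1, 0, g, beta, np.log2((1 + beta / (2 - beta)) / 2))
            cs.append(c)
        assert all(x > y for x, y in zip(cs, cs[1:]))


class TestDiscretize:
    @pytest.mark.parametrize("est,lo,hi,status", [
        (0.95, 0.90, 0.99, "clonal"),
        (0.5, 0.3, 0.7, "subclonal"),
        (0.9, 0.8, 0.95, "uncertain.clonal"),
        (0.8, 0.7, 0.9, "uncertain.subclonal"),
    ])
    def test_rules(self, est, lo, hi, status):
        assert discretize_clonality(est, lo, hi, 0.85) == status

    def test_nan_is_not_analysed(self):
        assert discretize_clonality(np.nan, np.nan, np.nan) == "not.analysed"


class TestSnvFormulas:
    def test_adjusted_vaf_identity_at_purity_one(self):
        assert snv_adjusted_vaf(0.5, 0.0, 2) == pytest.approx(0.5)

    def test_adjusted_vaf_doubles_at_half_purity(self):
        assert snv_adjusted_vaf(0.25, 0.5, 2) == pytest.approx(0.5)

    def test_sixty_percent_clonality_from_vaf_03(self):
        assert snv_clonality(0.3, 0.0, 2, 1) == pytest.approx(0.6)

    def test_clonal_snv_in_cn3_pure_sample(self):
        assert snv_clonality(1 / 3, 0.0, 3, 1) == pytest.approx(1.0)
        assert expected_snv_vaf(1.0, 0.0, 3, 1) == pytest.approx(1 / 3)

    def test_zero_vaf_zero_clonality(self):
        assert snv_clonality(0.0, 0.3, 2, 1) == 0.0

    def test_linearity_and_multiplicity(self):
        base = snv_clonality(0.2, 0.2, 2, 1)
        assert snv_clonality(0.4, 0.2, 2, 1) == pytest.approx(2 * base)
        assert snv_clonality(0.4, 0.2, 2, 2) == pytest.approx(base)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            snv_clonality(0.5, 0.0, 0.0, 1)
        with pytest.raises(ValueError):
            snv_adjusted_vaf(0.5, 1.0, 2)


def _snv_frame(chrom, pos, ref_counts, alt_counts):
    return pd.DataFrame({
        "sample": "s", "chrom": chrom, "pos": pos, "ref": "A", "alt": "T",
        "rc_ref_tumor": ref_counts, "rc_alt_tumor": alt_counts})


class TestSnvTable:
    def test_unmapped_snv_not_analysed(self):
        bt = synthetic_beta_table([0.0], [1.0])
        snv = _snv_frame("chr9", [555], [50], [50])
        out = compute_snv_clonality_table(
            snv, bt, PloidyEstimate(0.0, 2.0), AdmixtureEstimate(0.0, 0.0, 0.0))
        assert out["SNV_clonality_status"].iloc[0] == "not.analysed"

    def test_empty_table_gives_empty_output(self):
        bt = synthetic_beta_table([0.0], [1.0])
        out = compute_snv_clonality_table(
            _snv_frame("chr1", [], [], []), bt,
            PloidyEstimate(0.0, 2.0), AdmixtureEstimate(0.0, 0.0, 0.0))
        assert out.empty and "SNV_clonality" in out.columns

    def test_clonal_snvs_on_wild_type_at_g04(self):
        model = TumorModel(
            admixture=0.4,
            segments=[SegmentSpec("chr1", i * 500_001 + 1,
                                  (i + 1) * 500_000, 1, 1) for i in range(8)],
            snvs=[SNVSpec("chr1", 200_000 + i * 430_000, 1, 1.0)
                  for i in range(8)],
            mean_coverage_tumor=500, mean_coverage_normal=200,
            sample="snvtest")
        sim = simulate_tumor(model, seed=31)
        bt = compute_beta_table(sim.seg_tb, sim.pileup_tumor, sim.pileup_normal)
        out = compute_snv_clonality_table(
            sim.snv_tb, bt, PloidyEstimate(0.0, 2.0),
            AdmixtureEstimate(0.4, 0.37, 0.43))
        analysed = out.loc[out["SNV_clonality_status"] != "not.analysed"]
        assert len(analysed) >= 6
        assert np.allclose(analysed["SNV_clonality"], 1.0, atol=0.1)
        assert set(analysed["SNV_clonality_status"]) <= {
            "clonal", "uncertain.clonal"}

    def test_forty_percent_clonality_recovered_at_cov500(self):
        model = TumorModel(
            admixture=0.2,
            segments=[SegmentSpec("chr1", i * 500_001 + 1,
                                  (i + 1) * 500_000, 1, 1) for i in range(8)],
            snvs=[SNVSpec("chr1", 150_000 + i * 240_000, 1, 0.4)
                  for i in range(16)],
            mean_coverage_tumor=500, mean_coverage_normal=200,
            sample="subsnv")
        sim = simulate_tumor(model, seed=37)
        bt = compute_beta_table(sim.seg_tb, sim.pileup_tumor, sim.pileup_normal)
        out = compute_snv_clonality_table(
            sim.snv_tb, bt, PloidyEstimate(0.0, 2.0),
            AdmixtureEstimate(0.2, 0.18, 0.22))
        analysed = out.loc[out["SNV_clonality_status"] != "not.analysed"]
        assert analysed["SNV_clonality"].mean() == pytest.approx(0.4, abs=0.05)

    def test_upper_tail_exclusion_flags_expected_fraction(self):
        bt = synthetic_beta_table([0.0], [1.0], length=10_000_000)
        rng = np.random.default_rng(4)
        n = 100
        alt = rng.binomial(200, 0.45, size=n)
        snv = _snv_frame("chr1", np.arange(n) * 50_000 + 1000, 200 - alt, alt)
        out = compute_snv_clonality_table(
            snv, bt, PloidyEstimate(0.0, 2.0),
            AdmixtureEstimate(0.1, 0.08, 0.12), error_rate=0.05)
        assert 0 < out["excluded"].sum() <= np.ceil(0.05 * n) + 1


class TestFullPipelineClassRecovery:
    def test_discretized_classes_match_truth(self):
        """Simulated genomes: discretized SCNA and SNV clonality classes
        agree with truth-derived classes for >= 85% of analysable calls."""
        from ascna.ploidy_admixture import compute_dna_admixture, compute_ploidy
        from ascna.simulate import random_tumor_model
        ok = tot = 0
        for i in range(4):
            sim = simulate_tumor(random_tumor_model(seed=700 + i), seed=800 + i)
            bt = compute_beta_table(sim.seg_tb, sim.pileup_tumor,
                                    sim.pileup_normal)
            pl = compute_ploidy(bt)
            adm = compute_dna_admixture(bt, pl)
            ct = compute_scna_clonality_table(bt, pl, adm)
            truth = sim.truth["segments"]
            for st, tc, state in zip(ct["clonality_status"],
                                     truth["clonality"],
                                     truth[["cn_a", "cn_b"]].itertuples(
                                         index=False)):
                if tuple(state) == (1, 1) or st == "not.analysed":
                    continue
                tot += 1
                truth_cls = "clonal" if tc >= 0.85 else "subclonal"
                pred_cls = ("clonal" if st in ("clonal", "uncertain.clonal")
                            else "subclonal")
                ok += truth_cls == pred_cls
            snv_out = compute_snv_clonality_table(sim.snv_tb, bt, pl, adm)
            truth_snv = sim.truth["snvs"]
            for st, tc in zip(snv_out["SNV_clonality_status"],
                              truth_snv["clonality"]):
                if st == "not.analysed":
                    continue
                tot += 1
                truth_cls = "clonal" if tc >= 0.85 else "subclonal"
                pred_cls = ("clonal" if st in ("clonal", "uncertain.clonal")
                            else "subclonal")
                ok += truth_cls == pred_cls
        assert tot >= 40
        assert ok / tot >= 0.85
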