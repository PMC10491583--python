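"""ADO rates, origin classification, chimerism correction, MRD arithmetic."""

import numpy as np
import pandas as pd
import pytest

import scamplicon as sc
from scamplicon.containers import HET, HOM, NOCALL, WT
from conftest import (
    FLT3_V1,
    FLT3_V2,
    KRAS,
    gm_from_states,
    transplant_mixture,
)

PAIR = sc.MarkerPair(FLT3_V1.id, FLT3_V2.id)


def _ado_estimate(rate, n=2000, variant=FLT3_V1.id, direction="het_to_hom_alt"):
    from statsmodels.stats.proportion import proportion_confint

    k = round(rate * n)
    lo, hi = proportion_confint(k, n, method="wilson")
    return sc.ADOEstimate(
        variant=variant, direction=direction, rate=k / n,
        n_informative=n, ci95=(float(lo), float(hi)),
    )


class TestEstimateAdo:
    def test_zero_dropout_gives_zero_rate_with_zero_lower_bound(self):
        cfg = transplant_mixture(0.0, n_cells=1500, ado=0.0, seed=2,
                                 mean_depth=200.0, error_rate=0.0)
        acm, _ = sc.simulate_dataset(cfg)
        gm = sc.apply_variant_qc(sc.call_genotypes(acm))
        anchor = gm.cells[gm.states[FLT3_V2.id] == HET]
        est = sc.estimate_ado(gm, anchor, FLT3_V1.id, "total")
        assert est.rate == 0.0
        assert est.ci95[0] == 0.0

    def test_directional_rates_match_the_generative_closed_form(self):
        """Per-copy a: het->hom rate (either direction) is a(1-a)/(1-a^2)."""
        a = 0.045
        cfg = transplant_mixture(0.0, n_cells=6000, ado=a, seed=3,
                                 mean_depth=200.0, error_rate=0.0)
        acm, _ = sc.simulate_dataset(cfg)
        gm = sc.apply_variant_qc(sc.call_genotypes(acm))
        anchor = gm.cells[gm.states[FLT3_V2.id] == HET]
        expected = a * (1 - a) / (1 - a**2)
        for direction in ("het_to_hom_alt", "het_to_hom_ref"):
            est = sc.estimate_ado(gm, anchor, FLT3_V1.id, direction)
            sigma = np.sqrt(expected * (1 - expected) / est.n_informative)
            assert abs(est.rate - expected) <= 3 * sigma

    def test_paper_regime_total_ado_lies_in_four_to_five_percent(self):
        """Per-copy a = 0.0235 reproduces an observed per-SNV ADO of 4-5%."""
        cfg = transplant_mixture(0.0, n_cells=8000, ado=0.0235, seed=4)
        acm, _ = sc.simulate_dataset(cfg)
        gm = sc.apply_variant_qc(sc.call_genotypes(acm))
        for v, other in ((FLT3_V1.id, FLT3_V2.id), (FLT3_V2.id, FLT3_V1.id)):
            anchor = gm.cells[gm.states[other] == HET]
            est = sc.estimate_ado(gm, anchor, v, "total")
            assert 0.04 <= est.rate <= 0.05

    def test_anchor_via_clone_partition(self):
        labels = ["HET"] * 8 + ["HOM"] * 2
        gm = gm_from_states({FLT3_V1.id: labels, FLT3_V2.id: labels},
                            [FLT3_V1, FLT3_V2])
        part = sc.assign_clones(gm, [FLT3_V2.id])
        est = sc.estimate_ado(gm, (part, "HET"), FLT3_V1.id, "het_to_hom_alt")
        assert est.rate == 0.0 and est.n_informative == 8

    def test_uncallable_anchor_raises(self):
        gm = gm_from_states({FLT3_V1.id: ["NOCALL"] * 3,
                             FLT3_V2.id: ["HET"] * 3}, [FLT3_V1, FLT3_V2])
        with pytest.raises(ValueError, match="insufficient"):
            sc.estimate_ado(gm, gm.cells, FLT3_V1.id)


class TestClassifyOrigin:
    def _gm(self, v1, v2, kras=None):
        states = {FLT3_V1.id: v1, FLT3_V2.id: v2}
        sites = [FLT3_V1, FLT3_V2]
        if kras is not None:
            states[KRAS.id] = kras
            sites.append(KRAS)
        return gm_from_states(states, sites)

    def test_category_rules(self):
        gm = self._gm(
            ["HET", "HOM", "WT", "HET", "NOCALL", "HOM"],
            ["HET", "HOM", "WT", "HOM", "HET", "WT"],
        )
        cat, counts = sc.classify_origin(gm, PAIR)
        assert cat.tolist() == [
            "donor", "recipient", "ado_ref_ref",
            "mixed_zygosity", "nocall", "mixed_zygosity",
        ]
        assert counts == {
            "donor": 1, "recipient": 1, "ado_ref_ref": 1,
            "mixed_zygosity": 2, "nocall": 1,
        }

    def test_recipient_genotype_cell_carrying_the_somatic_mutation(self):
        gm = self._gm(["HOM"], ["HOM"], kras=["HET"])
        cat, _ = sc.classify_origin(gm, PAIR)
        assert cat.iloc[0] == "recipient"
        assert gm.states[KRAS.id].iloc[0] == HET  # tumour-flagged in reports

    def test_categories_partition_the_cell_set(self):
        cfg = transplant_mixture(0.01, n_cells=3000, ado=0.045, seed=5)
        acm, _ = sc.simulate_dataset(cfg)
        gm = sc.apply_variant_qc(sc.call_genotypes(acm))
        _, counts = sc.classify_origin(gm, PAIR)
        assert sum(counts.values()) == 3000

    def test_missing_marker_rejected(self):
        gm = gm_from_states({FLT3_V1.id: ["HET"]}, [FLT3_V1])
        with pytest.raises(ValueError):
            sc.classify_origin(gm, PAIR)


class TestCorrectChimerism:
    COUNTS = {"donor": 3722, "recipient": 23, "ado_ref_ref": 6,
              "mixed_zygosity": 0, "nocall": 100}

    def test_parametric_product_worked_example(self):
        """3722 donor cells at 4% dropout per marker -> ~6 expected false recipients."""
        res = sc.correct_chimerism(
            self.COUNTS, _ado_estimate(0.04), _ado_estimate(0.04, variant=FLT3_V2.id),
        )
        assert res.expected_false_recipient == pytest.approx(3722 * 0.04**2)
        assert res.corrected_recipient_count == pytest.approx(23 - 5.9552)

    def test_empirical_symmetric_uses_wt_wt_count(self):
        res = sc.correct_chimerism(self.COUNTS, estimator="empirical_symmetric")
        assert res.expected_false_recipient == 6
        assert res.corrected_recipient_count == 17
        assert res.counts["recipient"] == 23

    def test_zero_rates_leave_observed_count_unchanged(self):
        res = sc.correct_chimerism(
            self.COUNTS, _ado_estimate(0.0), _ado_estimate(0.0, variant=FLT3_V2.id),
        )
        assert res.corrected_recipient_count == 23

    def test_over_correction_clamps_to_zero_with_flag(self):
        counts = dict(self.COUNTS, recipient=2)
        res = sc.correct_chimerism(
            counts, _ado_estimate(0.05), _ado_estimate(0.05, variant=FLT3_V2.id),
        )
        assert res.corrected_recipient_count == 0.0
        assert res.over_corrected

    @pytest.mark.parametrize("rates", [(0.0, 0.01), (0.01, 0.02), (0.02, 0.05)])
    def test_larger_ado_never_increases_corrected_count(self, rates):
        lo, hi = rates
        res_lo = sc.correct_chimerism(
            self.COUNTS, _ado_estimate(lo), _ado_estimate(lo, variant=FLT3_V2.id))
        res_hi = sc.correct_chimerism(
            self.COUNTS, _ado_estimate(hi), _ado_estimate(hi, variant=FLT3_V2.id))
        assert res_hi.corrected_recipient_count <= res_lo.corrected_recipient_count

    def test_bootstrap_ci_is_seeded_and_reproducible(self):
        kw = dict(ado1=_ado_estimate(0.04),
                  ado2=_ado_estimate(0.04, variant=FLT3_V2.id), seed=11)
        assert sc.correct_chimerism(self.COUNTS, **kw).ci95 == \
            sc.correct_chimerism(self.COUNTS, **kw).ci95

    def test_denominator_is_genotyped_cells(self):
        res = sc.correct_chimerism(self.COUNTS, estimator="empirical_symmetric")
        assert res.n_genotyped == 3722 + 23 + 6
        assert res.corrected_fraction == pytest.approx(17 / (3722 + 23 + 6))


class TestDualMarkerGain:
    def test_gain_factor_is_at_least_twenty_for_rates_up_to_five_percent(self):
        for a in np.linspace(0.01, 0.05, 9):
            _, _, factor = sc.misclassification_gain(a, a)
            assert factor >= 20.0 - 1e-9  # exact 1/a up to float roundoff

    def test_analytic_values(self):
        p1, p2, factor = sc.misclassification_gain(0.04, 0.05)
        assert p1 == 0.04
        assert p2 == pytest.approx(0.002)
        assert factor == pytest.approx(20.0)


class TestEstimatorRecovery:
    def test_corrected_count_is_less_biased_than_naive(self):
        """Small-replicate version of the recovery experiment."""
        naive_err, corr_err = [], []
        for seed in range(15):
            cfg = transplant_mixture(0.005, n_cells=4000, ado=0.045, seed=100 + seed)
            acm, truth = sc.simulate_dataset(cfg)
            gm = sc.apply_variant_qc(sc.call_genotypes(acm))
            est = sc.ChimerismEstimator(pair=PAIR, random_state=seed).fit(gm)
            true_n = int((truth.origin == "recipient").sum())
            naive_err.append(est.result_.counts["recipient"] - true_n)
            corr_err.append(est.result_.corrected_recipient_count - true_n)
        assert abs(np.mean(corr_err)) < abs(np.mean(naive_err))


class TestMrdFraction:
    def test_three_carriers_among_6090_prints_as_0_05_percent(self):
        labels = ["HET"] * 3 + ["WT"] * 6087
        gm = gm_from_states({KRAS.id: labels}, [KRAS])
        res = sc.mrd_fraction(gm, KRAS.id)
        assert (res.carriers, res.genotyped) == (3, 6090)
        assert res.fraction == pytest.approx(3 / 6090)
        assert res.percent == 0.05

    def test_no_carriers_gives_zero(self):
        gm = gm_from_states({KRAS.id: ["WT"] * 50}, [KRAS])
        res = sc.mrd_fraction(gm, KRAS.id)
        assert res.fraction == 0.0 and res.percent == 0.0

    def test_equals_brute_force_count(self):
        cfg = transplant_mixture(0.2, n_cells=800, ado=0.1, seed=6)
        acm, _ = sc.simulate_dataset(cfg)
        gm = sc.apply_variant_qc(sc.call_genotypes(acm))
        res = sc.mrd_fraction(gm, FLT3_V1.id, states={HOM})
        col = gm.states[FLT3_V1.id]
        brute_carriers = sum(1 for s in col if s == HOM)
        brute_genotyped = sum(1 for s in col if s != NOCALL)
        assert (res.carriers, res.genotyped) == (brute_carriers, brute_genotyped)

    def test_low_frequency_detection_within_poisson_error(self):
        """True tumour fraction 5e-4 at n = 6000 with realistic dropout."""
        true_frac = 0.0005
        clones = [
            sc.CloneSpec("donor", {FLT3_V1.id: "HET", KRAS.id: "WT"},
                         1 - true_frac, origin="donor"),
            sc.CloneSpec("tumor", {FLT3_V1.id: "HOM", KRAS.id: "HET"}, true_frac),
        ]
        cfg = sc.SimConfig(
            sites=[FLT3_V1, KRAS], clones=clones, n_cells=6000,
            ado={FLT3_V1.id: 0.045, KRAS.id: 0.045}, seed=7,
        )
        acm, truth = sc.simulate_dataset(cfg)
        gm = sc.apply_variant_qc(sc.call_genotypes(acm))
        res = sc.mrd_fraction(gm, KRAS.id)
        lam = true_frac * 6000
        assert abs(res.carriers - lam) <= 3 * np.sqrt(lam) + 1

    def test_zero_genotyped_cells_error(self):
        gm = gm_from_states({KRAS.id: ["NOCALL"] * 4}, [KRAS])
        gm.genotyped_fraction[KRAS.id] = 0.0
        with pytest.raises(ValueError, match="no cells genotyped"):
            sc.mrd_fraction(gm, KRAS.id)
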