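"""In vitro kinetics: Michaelis-Menten fitting, ISEF and in vivo scaling."""

import numpy as np
import pytest

from cpftk import params as P
from cpftk.kinetics import (
    FitFailure,
    MichaelisMentenParams,
    ProbeAssay,
    compute_isef,
    eadie_hofstee_diagnostic,
    fit_michaelis_menten,
    scale_hlm_vmax,
    scale_plasma_vmax,
    scale_supersome_vmax,
    summed_scaled_ce,
)
from cpftk.workbench import default_isoform_records

DESIGN_2B6 = P.INCUBATION_DESIGNS["CYP2B6"]


class TestMichaelisMentenFit:
    def test_noiseless_recovery_is_exact(self):
        s = np.array(DESIGN_2B6, dtype=float)
        v = 7.76 * s / (0.14 + s)
        fit = fit_michaelis_menten(s, v)
        assert fit.vmax_app == pytest.approx(7.76, rel=1e-3)
        assert fit.km_app == pytest.approx(0.14, rel=1e-3)
        assert fit.ce_app == pytest.approx(fit.vmax_app / fit.km_app, rel=1e-9)

    @pytest.mark.parametrize("vmax,km,design", [
        (7.76, 0.14, DESIGN_2B6),
        (17.78, 29.77, P.INCUBATION_DESIGNS["CYP3A4"]),
        (1844.0, 290.0, P.INCUBATION_DESIGNS["plasma"]),
    ])
    def test_noiseless_recovery_any_truth_in_design_range(self, vmax, km, design):
        s = np.array(design, dtype=float)
        v = vmax * s / (km + s)
        fit = fit_michaelis_menten(s, v)
        assert fit.vmax_app == pytest.approx(vmax, rel=1e-3)
        assert fit.km_app == pytest.approx(km, rel=1e-3)

    def test_noisy_recovery_within_ten_percent(self):
        """Plasma-design data at 5% CV, 3 replicates: Vmax back within 10%."""
        s = np.repeat(np.array(P.INCUBATION_DESIGNS["plasma"], float), 3)
        truth_v, truth_k = 1844.0, 290.0
        sigma = np.sqrt(np.log(1 + 0.05 ** 2))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = truth_v * s / (truth_k + s) * np.exp(rng.normal(0, sigma, s.size))
            fit = fit_michaelis_menten(s, v)
            assert abs(fit.vmax_app / truth_v - 1) < 0.10

    def test_all_zero_velocities_fail(self):
        with pytest.raises(FitFailure):
            fit_michaelis_menten([0.1, 1, 10, 100], [0, 0, 0, 0])

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten([1, 2, 3], [0.5, 0.9, 1.2])


class TestISEF:
    def test_printed_probe_values_reproduce_published_isefs(self):
        low = compute_isef(ProbeAssay("CYP1A2", "phenacetin", 0.15, 39.06), 52.0)
        high = compute_isef(ProbeAssay("CYP2B6", "bupropion", 0.31, 40.77), 15.8)
        assert low == pytest.approx(0.07, rel=0.10)   # rounding-limited
        assert high == pytest.approx(0.48, rel=0.10)

    def test_ratio_identity(self):
        assert compute_isef(ProbeAssay("x", "p", 1.0, 100.0), 10.0) == pytest.approx(1.0)

    def test_perfect_system_has_isef_one(self):
        # HLM Vmax = Supersome Vmax * abundance / 1000 -> ISEF == 1 exactly
        vss, ab = 37.5, 80.0
        probe = ProbeAssay("x", "p", vss * ab / 1000.0, vss)
        assert compute_isef(probe, ab) == 1.0

    def test_zero_abundance_is_an_error(self):
        with pytest.raises(ValueError):
            compute_isef(ProbeAssay("x", "p", 1.0, 1.0), 0.0)


class TestScaling:
    def test_unit_audit_composite_factors(self):
        """Inputs of 1 in natural units return exactly the composite factor."""
        assert scale_supersome_vmax(1, 1, 1, mpl=1, vl=1) == pytest.approx(60 * 1000 / 1e6)
        assert scale_hlm_vmax(1, mpl=1, vl=1) == pytest.approx(60.0)
        assert scale_plasma_vmax(1, vb=1) == pytest.approx(60 * 0.55)

    def test_supersome_scaling_matches_published_2b6_value(self):
        v = scale_supersome_vmax(7.76, 15.8, 0.48, 32, 1.8)
        assert v == pytest.approx(203.94, rel=0.005)

    def test_supersome_scaling_matches_published_2c19_value(self):
        v = scale_supersome_vmax(2.74, 5.4, 0.21, 32, 1.8)
        assert v == pytest.approx(10.81, rel=0.01)

    def test_zero_isef_or_abundance_scales_to_zero(self):
        assert scale_supersome_vmax(7.76, 15.8, 0.0, 32, 1.8) == 0.0
        assert scale_supersome_vmax(7.76, 0.0, 0.48, 32, 1.8) == 0.0

    def test_hlm_low_affinity_ce_is_41(self):
        v = scale_hlm_vmax(0.353, 32, 1.8)
        assert v == pytest.approx(1219.9, rel=0.001)
        assert v / 29.8 == pytest.approx(41.0, rel=0.02)

    def test_hlm_high_affinity_ce(self):
        v = scale_hlm_vmax(0.275, 32, 1.8)
        assert v == pytest.approx(950.4, rel=0.001)
        assert v / 0.270 == pytest.approx(3520, rel=0.01)

    def test_plasma_scaling_matches_published_whole_body_value(self):
        assert scale_plasma_vmax(1844.0, 5.27) == pytest.approx(320937, rel=0.005)
        assert scale_plasma_vmax(1844.0, 0.0) == 0.0
        assert scale_plasma_vmax(100.0, 5.0) == pytest.approx(16500.0)

    def test_scaled_ce_invariant_under_vmax_isef_rebalance(self):
        base = scale_supersome_vmax(3.96, 52.0, 0.07, 32, 1.8) / 0.61
        for c in (0.1, 2.0, 17.0):
            rebal = scale_supersome_vmax(3.96 * c, 52.0, 0.07 / c, 32, 1.8) / 0.61
            assert rebal == pytest.approx(base, rel=1e-12)


class TestSummedCE:
    def test_pathway1_sum_matches_published_total(self):
        records = default_isoform_records()
        assert summed_scaled_ce(records, 1) == pytest.approx(1578.0, rel=0.02)

    def test_single_isoform_equals_its_own_ce(self):
        records = default_isoform_records()[:1]
        from cpftk.kinetics import scale_supersome_pathway

        assert summed_scaled_ce(records, 1) == pytest.approx(
            scale_supersome_pathway(records[0], 1).ce_invivo
        )

    def test_pathway2_affinity_groups_within_14_fold(self):
        """CPF detoxification shows no dominant high-affinity phase: the
        total summed CE exceeds the high-affinity (low-Km) group by less
        than 1.4-fold, unlike bioactivation where the ratio is ~50."""
        records = default_isoform_records()
        def group_ce(pathway, km_below):
            from cpftk.kinetics import scale_supersome_pathway
            mm = lambda r: (r.kinetics_pathway1 if pathway == 1 else r.kinetics_pathway2)
            return sum(
                scale_supersome_pathway(r, pathway).ce_invivo
                for r in records if mm(r).km_app < km_below
            )
        total2 = summed_scaled_ce(records, 2)
        assert total2 / group_ce(2, 10.0) < 1.4
        total1 = summed_scaled_ce(records, 1)
        assert total1 / group_ce(1, 10.0) < 1.1  # high-affinity CYPs dominate

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summed_scaled_ce([], 1)


class TestEadieHofstee:
    S = np.logspace(-2, 2, 30)

    def test_single_enzyme_is_monophasic(self):
        v = 7.76 * self.S / (0.14 + self.S)
        _, flag = eadie_hofstee_diagnostic(self.S, v)
        assert not flag

    def test_well_separated_pair_is_biphasic(self):
        v = 7.76 * self.S / (0.14 + self.S) + 17.78 * self.S / (29.8 + self.S)
        table, flag = eadie_hofstee_diagnostic(self.S, v)
        assert flag
        assert table.shape == (30, 2)

    def test_bioactivation_sum_biphasic_detox_sum_monophasic(self):
        from cpftk.pbk import Scenario

        model = Scenario().liver_model()

        def total(terms):
            return np.array([sum(v * x / (k + x) for v, k in terms) for x in self.S])

        assert eadie_hofstee_diagnostic(self.S, total(model.pathway1_terms))[1]
        assert not eadie_hofstee_diagnostic(self.S, total(model.pathway2_terms))[1]


def test_mm_params_validate_positivity():
    with pytest.raises(ValueError):
        MichaelisMentenParams(-1.0, 2.0)
    with pytest.raises(ValueError):
        MichaelisMentenParams(1.0, 0.0)
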