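"""Placebo-vs-no-treatment contrast and the additive decomposition."""

import math
from dataclasses import replace

import numpy as np
import pytest

from contextfx import (
    ArmSummary,
    SimulationConfig,
    contextual_effect,
    contextual_effect_open_label,
    contextual_proportion_bootstrap,
    decompose_three_arm,
    mean_change,
    simulate_study,
)
from contextfx.contextual import RoleMismatchError
from contextfx.effects import InputError


def arm(role, mb, mf, sd=1.0, n=100, study="S1", sd_change=None):
    return ArmSummary(
        study_id=study, role=role, n=n, mean_baseline=mb, sd_baseline=sd,
        mean_followup=mf, sd_followup=sd, sd_change=sd_change,
    )


NOISE_FREE = SimulationConfig(
    design="three_arm", n_per_arm=50, ns=0.5, c=0.8, s=1.2, sigma=0.0, seed=1
)


class TestContextualEffect:
    def test_identical_arms_zero(self):
        p = arm("placebo", 5.0, 4.0)
        nt = arm("no_treatment", 5.0, 4.0)
        assert contextual_effect(p, nt).estimate == 0.0

    def test_noise_free_simulation_recovers_c_exactly(self):
        study = simulate_study(NOISE_FREE)
        est = contextual_effect(study.arm("placebo"), study.arm("no_treatment"))
        assert est.estimate == pytest.approx(0.8, abs=1e-9)

    def test_role_mismatch_rejected(self):
        a = arm("active", 5.0, 4.0)
        nt = arm("no_treatment", 5.0, 4.0)
        with pytest.raises(RoleMismatchError):
            contextual_effect(a, nt)

    def test_invariant_to_constant_nonspecific_drift(self):
        # adding the same improvement to both arms (a non-specific
        # effect) leaves the contrast unchanged
        p = arm("placebo", 5.0, 3.9)
        nt = arm("no_treatment", 5.0, 4.7)
        base = contextual_effect(p, nt).estimate
        drift = 2.3
        p2 = replace(p, mean_followup=p.mean_followup - drift)
        nt2 = replace(nt, mean_followup=nt.mean_followup - drift)
        assert contextual_effect(p2, nt2).estimate == pytest.approx(base)

    def test_smd_measure_supported(self):
        p = arm("placebo", 5.0, 3.0, sd_change=1.0)
        nt = arm("no_treatment", 5.0, 4.0, sd_change=1.0)
        assert contextual_effect(p, nt, measure="SMD").estimate == pytest.approx(1.0)

    def test_noisy_parameter_recovery_and_coverage(self):
        # c = 0.8, sigma = 1, n = 200/arm, 1000 replicates: the mean
        # estimate recovers c within Monte-Carlo error and the 95% CI
        # covers c at its nominal rate
        config = SimulationConfig(
            design="three_arm", n_per_arm=200, ns=0.5, c=0.8, s=1.2,
            sigma=1.0, seed=20240213,
        )
        reps = 1000
        ests, covered = np.empty(reps), 0
        for i in range(reps):
            study = simulate_study(config, i)
            est = contextual_effect(study.arm("placebo"), study.arm("no_treatment"))
            ests[i] = est.estimate
            covered += est.ci_low <= 0.8 <= est.ci_high
        mc_se = ests.std(ddof=1) / math.sqrt(reps)
        assert abs(ests.mean() - 0.8) < 3 * mc_se
        assert 0.93 <= covered / reps <= 0.97


class TestOpenLabelContrast:
    def test_identical_arms_zero(self):
        p = arm("placebo", 5.0, 4.0)
        pc = arm("placebo_control", 5.0, 4.0)
        assert contextual_effect_open_label(p, pc).estimate == 0.0

    def test_noise_free_exposure_algebra(self):
        # exposures 1.0 vs 0.4 at c = 1: the contrast recovers the
        # exposure gap, not the full contextual effect
        config = SimulationConfig(
            design="two_placebo", n_per_arm=50, ns=0.5, c=1.0, s=0.0, sigma=0.0,
            exposure={"placebo": 1.0, "placebo_control": 0.4}, seed=3,
        )
        study = simulate_study(config)
        est = contextual_effect_open_label(
            study.arm("placebo"), study.arm("placebo_control")
        )
        assert est.estimate == pytest.approx(0.6, abs=1e-9)

    def test_reversing_arms_negates(self):
        p = arm("placebo", 5.0, 3.5)
        pc = arm("placebo_control", 5.0, 4.2)
        fwd = contextual_effect_open_label(p, pc).estimate
        assert fwd == pytest.approx(
            mean_change(p).estimate - mean_change(pc).estimate
        )
        # swapping the arms (with roles swapped accordingly) negates it
        swapped = contextual_effect_open_label(
            replace(pc, role="placebo"), replace(p, role="placebo_control")
        ).estimate
        assert swapped == pytest.approx(-fwd)
        with pytest.raises(RoleMismatchError):
            contextual_effect_open_label(pc, p)


class TestDecomposition:
    def test_identical_arms_trivial_split(self):
        arms = {
            r: arm(r, 5.0, 4.0) for r in ("active", "placebo", "no_treatment")
        }
        d = decompose_three_arm(arms["active"], arms["placebo"], arms["no_treatment"])
        assert d.total.estimate == pytest.approx(1.0)
        assert d.specific.estimate == 0.0
        assert d.contextual.estimate == 0.0
        assert d.non_specific.estimate == pytest.approx(1.0)

    def test_noise_free_components_exact(self):
        study = simulate_study(NOISE_FREE)
        d = decompose_three_arm(
            study.arm("active"), study.arm("placebo"), study.arm("no_treatment")
        )
        assert d.total.estimate == pytest.approx(2.5, abs=1e-9)
        assert d.specific.estimate == pytest.approx(1.2, abs=1e-9)
        assert d.contextual.estimate == pytest.approx(0.8, abs=1e-9)
        assert d.non_specific.estimate == pytest.approx(0.5, abs=1e-9)

    def test_conservation_on_random_and_simulated_studies(self):
        # specific + contextual + non_specific = total, up to floating
        # round-off, whatever the inputs
        rng = np.random.default_rng(99)
        for _ in range(1000):
            mb = rng.uniform(0, 100)
            arms = [
                arm(role, mb, mb - rng.uniform(-5, 15), sd=rng.uniform(0.5, 20),
                    n=int(rng.integers(5, 400)))
                for role in ("active", "placebo", "no_treatment")
            ]
            d = decompose_three_arm(*arms)
            total = (
                d.specific.estimate + d.contextual.estimate + d.non_specific.estimate
            )
            assert abs(total - d.total.estimate) < 1e-12
        config = SimulationConfig(n_per_arm=30, sigma=1.5, seed=5)
        for i in range(100):
            study = simulate_study(config, i)
            d = decompose_three_arm(
                study.arm("active"), study.arm("placebo"), study.arm("no_treatment")
            )
            s = d.specific.estimate + d.contextual.estimate + d.non_specific.estimate
            assert abs(s - d.total.estimate) < 1e-12

    def test_contrast_se_matches_resampling_oracle(self):
        # analytic SE sqrt(s_p^2/n_p + s_nt^2/n_nt) vs the empirical SD
        # of the contrast over independent replicates
        config = SimulationConfig(n_per_arm=100, sigma=2.0, seed=17)
        ests, ses = [], []
        for i in range(400):
            study = simulate_study(config, i)
            est = contextual_effect(study.arm("placebo"), study.arm("no_treatment"))
            ests.append(est.estimate)
            ses.append(est.se)
        empirical = np.std(ests, ddof=1)
        assert np.mean(ses) == pytest.approx(empirical, rel=0.12)

    def test_contextual_proportion_defined_only_for_positive_total(self):
        study = simulate_study(NOISE_FREE)
        d = decompose_three_arm(
            study.arm("active"), study.arm("placebo"), study.arm("no_treatment")
        )
        assert d.contextual_proportion() == pytest.approx(0.8 / 2.5, abs=1e-9)
        bad = arm("active", 5.0, 6.0)  # worsened: total < 0
        d2 = decompose_three_arm(
            bad, arm("placebo", 5.0, 4.0), arm("no_treatment", 5.0, 4.5)
        )
        with pytest.raises(InputError):
            d2.contextual_proportion()

    def test_bootstrap_proportion_brackets_truth(self):
        config = SimulationConfig(n_per_arm=300, sigma=1.0, seed=23)
        study = simulate_study(config)
        point, lo, hi = contextual_proportion_bootstrap(
            study.subjects, n_boot=500, seed=1
        )
        assert lo <= point <= hi
        assert lo < 0.8 / 2.5 < hi  # true share c/(ns+c+s) = 0.32

    def test_missing_role_rejected(self):
        with pytest.raises(RoleMismatchError):
            decompose_three_arm(
                arm("placebo", 5, 4), arm("placebo", 5, 4), arm("no_treatment", 5, 4)
            )
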