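"""Stratum proportions, the mean inversion, and the Wald identity."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cacetrial import (
    Arm,
    EstimationError,
    ObservedCellMeans,
    StrataMeans,
    StrataProportions,
    cace_intuitive,
    cace_wald,
    motivating_trial_config,
    cross_tab,
    equivalence_report,
    estimate_chain,
    generate,
    observed_means,
    solve_potential_quitter_means,
    strata_proportions,
)
from cacetrial.strata import chain_from_arrays
from conftest import make_cohort, random_cohort


class TestStrataProportions:
    def test_table1_counts_give_printed_prevalences(self, table1):
        p = strata_proportions(table1)
        assert p.p_hs == pytest.approx(227 / 295)
        assert p.p_iq == pytest.approx(25 / 287)
        assert p.p_pq == pytest.approx(1 - 227 / 295 - 25 / 287)
        assert (round(p.p_hs, 3), round(p.p_iq, 3), round(p.p_pq, 3)) == (0.769, 0.087, 0.143)
        assert p.valid

    def test_equal_quit_rates_flagged_invalid(self):
        cohort = make_cohort([0, 0, 1, 1], [0, 1, 0, 1], [3000.0] * 4)
        p = strata_proportions(cross_tab(cohort))
        assert p.p_pq == pytest.approx(0.0, abs=1e-15)
        assert not p.valid

    def test_all_compliers(self):
        # control: nobody quits; incentives: everybody quits
        cohort = make_cohort([0, 0, 1, 1], [0, 0, 1, 1], [3000.0] * 4)
        p = strata_proportions(cross_tab(cohort))
        assert p.p_pq == 1.0 and p.p_hs == 0.0 and p.p_iq == 0.0

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(EstimationError):
            StrataProportions(p_hs=0.5, p_iq=0.5, p_pq=0.5)


class TestObservedMeans:
    def test_table1_cells(self, table1):
        cells, partial = observed_means(table1)
        assert (partial.w_hs, partial.w_iq) == (3053.0, 3586.0)
        assert (cells.w0, cells.w1) == (3075.0, 3432.0)
        assert cells.mu0 == pytest.approx(3119.51, abs=0.01)
        assert cells.mu1 == pytest.approx(3140.36, abs=0.01)

    def test_constant_outcome_collapses_all_means(self):
        cohort = make_cohort([0, 0, 1, 1], [0, 1, 0, 1], [3200.0] * 4)
        cells, partial = observed_means(cross_tab(cohort))
        assert {cells.w0, cells.w1, cells.mu0, cells.mu1, partial.w_hs, partial.w_iq} == {3200.0}

    @given(st.integers(0, 10_000))
    def test_matches_direct_per_cell_averaging(self, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng)
        cells, partial = observed_means(cross_tab(cohort))
        df = cohort.to_frame().dropna(subset=["birth_weight"])
        grp = df.groupby([df.arm, df.quit])["birth_weight"].mean()
        assert partial.w_hs == pytest.approx(grp[("incentives", False)], rel=1e-12)
        assert partial.w_iq == pytest.approx(grp[("control", True)], rel=1e-12)
        assert cells.w1 == pytest.approx(grp[("incentives", True)], rel=1e-12)
        assert cells.w0 == pytest.approx(grp[("control", False)], rel=1e-12)

    def test_empty_referenced_cell_named(self):
        cohort = make_cohort([0, 0, 1, 1], [0, 0, 0, 1], [3000.0] * 4)  # no control quitters
        with pytest.raises(EstimationError, match="w_iq"):
            observed_means(cross_tab(cohort))


class TestSolveInversion:
    def test_table1_inputs_give_printed_chain(self, table1):
        props = strata_proportions(table1)
        cells, partial = observed_means(table1)
        m = solve_potential_quitter_means(props, cells, partial)
        # frozen from exact fraction arithmetic on the printed inputs
        assert m.w_pqq == pytest.approx(3338.4533, abs=1e-3)
        assert m.w_pqs == pytest.approx(3193.0527, abs=1e-3)

    def test_mixture_consistency_identities(self, table1):
        """The solved means must re-mix to the observed cell means exactly."""
        props = strata_proportions(table1)
        cells, partial = observed_means(table1)
        m = solve_potential_quitter_means(props, cells, partial)
        lhs_q = props.p_iq * m.w_iq + props.p_pq * m.w_pqq
        assert lhs_q == pytest.approx((props.p_iq + props.p_pq) * cells.w1, rel=1e-12)
        lhs_s = props.p_hs * m.w_hs + props.p_pq * m.w_pqs
        assert lhs_s == pytest.approx((props.p_hs + props.p_pq) * cells.w0, rel=1e-12)

    def test_no_mixing_reduces_to_cell_means(self):
        cells = ObservedCellMeans(w0=3100.0, w1=3400.0, mu0=3100.0, mu1=3400.0)
        props = StrataProportions(p_hs=0.0, p_iq=0.0, p_pq=1.0)
        m = solve_potential_quitter_means(props, cells, StrataMeans())
        assert m.w_pqq == 3400.0 and m.w_pqs == 3100.0

    def test_invalid_proportions_yield_nan_sentinel(self):
        props = StrataProportions(p_hs=0.6, p_iq=0.4, p_pq=0.0)
        cells = ObservedCellMeans(w0=3100.0, w1=3400.0, mu0=3100.0, mu1=3400.0)
        m = solve_potential_quitter_means(props, cells, StrataMeans(w_hs=3000.0, w_iq=3600.0))
        assert math.isnan(m.w_pqq) and math.isnan(m.w_pqs)
        assert math.isnan(cace_intuitive(m, props).point)

    def test_large_cohort_recovers_latent_stratum_means(self):
        cfg = dataclasses.replace(
            motivating_trial_config(seed=5), n_control=50_000, n_incentives=50_000
        )
        cohort = generate(cfg)
        _, props, cells, m, est = estimate_chain(cohort)
        df = cohort.to_frame().dropna(subset=["birth_weight"])
        pq = df[df.stratum == "PQ"]
        true_pqq = pq[pq.arm == "incentives"].birth_weight.mean()
        true_pqs = pq[pq.arm == "control"].birth_weight.mean()
        # inversion vs latent-label averages, within Monte-Carlo error
        assert m.w_pqq == pytest.approx(true_pqq, abs=25)
        assert m.w_pqs == pytest.approx(true_pqs, abs=25)
        # monotone ordering: HS lowest, IQ highest, PQ intermediate
        assert m.w_hs < m.w_pqs < m.w_pqq < m.w_iq


class TestCaceRoutes:
    def test_table1_chain_gives_145g_by_both_routes(self, table1):
        props = strata_proportions(table1)
        cells, partial = observed_means(table1)
        m = solve_potential_quitter_means(props, cells, partial)
        intuitive = cace_intuitive(m, props)
        wald = cace_wald(table1)
        assert intuitive.point == pytest.approx(145.4006, abs=1e-3)
        assert wald.point == pytest.approx(intuitive.point, rel=1e-9)

    def test_null_when_arms_identical(self):
        cohort = make_cohort(
            [0, 0, 0, 1, 1, 1], [0, 0, 1, 0, 1, 1], [3000.0, 3000.0, 3000.0] * 2
        )
        assert cace_wald(cross_tab(cohort)).point == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_wald_identity_on_any_cohort(self, seed):
        """The central identity: both routes agree to 1e-9 relative."""
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng)
        xtab = cross_tab(cohort)
        props = strata_proportions(xtab)
        if props.p_pq <= 1e-6:  # unidentified (or numerically so): no chain
            return
        cells, partial = observed_means(xtab)
        m = solve_potential_quitter_means(props, cells, partial)
        intuitive = cace_intuitive(m, props)
        wald = cace_wald(xtab)
        assert intuitive.point == pytest.approx(wald.point, rel=1e-9, abs=1e-9)
        # and the vectorized array chain agrees with the dataclass chain
        chain = chain_from_arrays(*cohort.analyzable_arrays())
        assert float(chain.cace) == pytest.approx(intuitive.point, rel=1e-9, abs=1e-9)
        assert float(chain.w_pqq) == pytest.approx(m.w_pqq, rel=1e-9)
        assert float(chain.w_pqs) == pytest.approx(m.w_pqs, rel=1e-9)

    def test_equivalence_report_on_synthetic_cohort(self, trial_like_cohort):
        rep = equivalence_report(trial_like_cohort)
        assert rep.both_valid
        assert rep.abs_difference < 1e-6

    def test_equivalence_report_propagates_invalid(self):
        cohort = make_cohort([0, 0, 1, 1], [0, 1, 0, 1], [3000.0] * 4)
        rep = equivalence_report(cohort)
        assert not rep.both_valid
        assert math.isnan(rep.abs_difference)

    def test_estimators_ignore_latent_labels(self, trial_like_cohort):
        with_labels = equivalence_report(trial_like_cohort)
        without = equivalence_report(trial_like_cohort.strip_strata())
        assert with_labels.intuitive.point == without.intuitive.point
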