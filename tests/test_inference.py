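"""Inversion of observable ratios to rates: domain, roots, fallback, ambiguity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssre import (
    EstimationResult,
    ObservableRatios,
    RateTriplet,
    Region,
    Status,
    admissible_domain,
    alpha_from_labeled,
    alpha_from_unlabeled,
    classify_region,
    estimate_all,
    estimate_transcript,
    forward_observe,
    gamma_from_k,
    objective_f,
    objective_reduced,
    ratio_labeled,
    ratio_unlabeled,
    reduced_equation,
    resolve_ambiguity,
    solve_k,
)
from ssre.io import TranscriptRecord


def obs_from(k: float, x: float) -> ObservableRatios:
    """Forward-generate an observable pair from reduced parameters."""
    return ObservableRatios(a=ratio_unlabeled((k, x)), b=ratio_labeled((k, x)))


class TestAdmissibleDomain:
    def test_worked_example(self, example_obs):
        dom = admissible_domain(example_obs)
        a, b = example_obs.a, example_obs.b
        assert dom.lower == pytest.approx(max(1 / b - 1, 1 - a), rel=1e-12)
        assert dom.upper == pytest.approx(1 / a - 1, rel=1e-12)
        assert dom.lower == pytest.approx(0.410633, abs=1e-5)
        assert dom.upper == pytest.approx(0.696734, abs=1e-5)
        assert not dom.empty

    def test_boundary_case_is_empty(self):
        dom = admissible_domain(ObservableRatios(0.5, 0.5))
        assert dom.lower == 1.0 and dom.upper == 1.0
        assert dom.empty

    def test_lower_bound_switches_between_terms(self):
        dom = admissible_domain(ObservableRatios(0.9, 0.95))
        assert dom.lower == pytest.approx(0.1)  # 1-a dominates 1/b-1
        assert dom.upper == pytest.approx(1 / 9, rel=1e-9)

    def test_invalid_ratios_raise(self):
        with pytest.raises(ValueError):
            admissible_domain(ObservableRatios(0.0, 0.5))
        with pytest.raises(ValueError):
            admissible_domain(ObservableRatios(0.5, 1.2))


class TestClassifyRegion:
    def test_unique_region(self, example_obs):
        assert example_obs.b > 1 / (2 - example_obs.a)
        assert classify_region(example_obs) is Region.UNIQUE

    @pytest.mark.parametrize(
        "a,b,region",
        [
            (0.3, 1.2, Region.REJECT_RL_GE_1),
            (0.3, 1.0, Region.REJECT_RL_GE_1),
            (0.6, 0.4, Region.REJECT_B_LE_A),
            (0.5, 0.5, Region.REJECT_B_LE_A),
            (0.2, 0.35, Region.FALLBACK),  # between diagonal and 1/(2-a)=0.556
        ],
    )
    def test_partition(self, a, b, region):
        assert classify_region(ObservableRatios(a, b)) is region

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            classify_region(ObservableRatios(math.nan, 0.5))


class TestReducedEquation:
    def test_forward_generated_observables_are_roots(self, example_obs):
        assert reduced_equation(0.5, example_obs) == pytest.approx(0.0, abs=1e-10)

    def test_sign_change_brackets_true_k(self, example_obs):
        assert reduced_equation(0.45, example_obs) * reduced_equation(
            0.55, example_obs
        ) < 0

    def test_continuous_across_k_equals_one(self):
        obs = obs_from(1.0, 1.0)  # domain contains k=1
        vals = [reduced_equation(k, obs) for k in (1 - 5e-5, 1.0, 1 + 5e-5)]
        assert vals[0] == pytest.approx(vals[1], abs=1e-3)
        assert vals[2] == pytest.approx(vals[1], abs=1e-3)
        assert reduced_equation(1.0, obs) == pytest.approx(0.0, abs=1e-8)

    def test_outside_domain_raises(self, example_obs):
        with pytest.raises(ValueError):
            reduced_equation(0.3, example_obs)
        with pytest.raises(ValueError):
            reduced_equation(0.8, example_obs)


class TestSolveK:
    def test_worked_inversion(self, example_obs):
        roots = solve_k(example_obs)
        assert len(roots) == 1
        assert roots[0] == pytest.approx(0.5, abs=1e-6)

    def test_two_root_case_is_genuine(self):
        """Below the separating curve both roots reproduce the observables."""
        obs = obs_from(2.0, 1.5)
        assert classify_region(obs) is Region.FALLBACK
        roots = solve_k(obs)
        assert len(roots) == 2
        assert roots[0] == pytest.approx(1.36446, abs=1e-4)
        assert any(abs(r - 2.0) < 1e-6 for r in roots)
        for k in roots:
            x = gamma_from_k(k, obs, 1.0)
            assert math.log(ratio_unlabeled((k, x)) / obs.a) == pytest.approx(
                0.0, abs=1e-8
            )
            assert math.log(ratio_labeled((k, x)) / obs.b) == pytest.approx(
                0.0, abs=1e-8
            )

    @pytest.mark.parametrize("k,x", [(0.3, 0.5), (0.7, 2.0), (1.8, 0.3), (3.0, 0.8)])
    def test_unique_region_has_exactly_one_root(self, k, x):
        obs = obs_from(k, x)
        if classify_region(obs) is Region.UNIQUE:
            roots = solve_k(obs)
            assert len(roots) == 1
            assert roots[0] == pytest.approx(k, rel=1e-6)

    def test_empty_domain_returns_no_roots(self):
        assert solve_k(ObservableRatios(0.5, 0.5)) == []


class TestRateReconstruction:
    def test_gamma_from_worked_example(self, example_obs):
        assert gamma_from_k(0.5, example_obs, 1.0) == pytest.approx(1.0, rel=1e-9)

    def test_gamma_scales_inversely_with_pulse(self, example_obs):
        assert gamma_from_k(0.5, example_obs, 10.0) == pytest.approx(0.1, rel=1e-9)

    def test_alpha_from_unlabeled_recovers_synthesis(self, example_record):
        m_u = example_record.chi_u - example_record.iota_u
        alpha = alpha_from_unlabeled(0.5, 1.0, 1.0, example_record.chi_u,
                                     example_record.iota_u)
        assert m_u == pytest.approx(1.690364, abs=1e-6)
        assert alpha == pytest.approx(2.0, rel=1e-9)

    def test_alpha_linear_in_abundance(self, example_record):
        a1 = alpha_from_unlabeled(0.5, 1.0, 1.0, example_record.chi_u,
                                  example_record.iota_u)
        a3 = alpha_from_unlabeled(0.5, 1.0, 1.0, 3 * example_record.chi_u,
                                  3 * example_record.iota_u)
        assert a3 == pytest.approx(3 * a1, rel=1e-12)

    def test_alpha_sources_agree_on_exact_input(self, example_record):
        au = alpha_from_unlabeled(0.5, 1.0, 1.0, example_record.chi_u,
                                  example_record.iota_u)
        al = alpha_from_labeled(0.5, 1.0, 1.0, example_record.chi_l,
                                example_record.iota_l)
        assert al == pytest.approx(au, rel=1e-9)

    def test_alpha_from_labeled_steady_state_limit(self):
        """For long pulses m_l -> alpha/gamma, so alpha -> gamma * (chi_l - iota_l)."""
        rates = RateTriplet(3.0, 0.5, 1.0)
        rec = forward_observe(rates, 40.0)
        m_l = rec.chi_l - rec.iota_l
        assert alpha_from_labeled(0.5, 1.0, 40.0, rec.chi_l, rec.iota_l) == (
            pytest.approx(1.0 * m_l, rel=1e-6)
        )

    def test_alpha_degenerate_processing_rate(self):
        """beta == gamma uses the analytic limit and still round-trips."""
        rates = RateTriplet(2.0, 1.0, 1.0)
        rec = forward_observe(rates, 1.0)
        assert alpha_from_unlabeled(1.0, 1.0, 1.0, rec.chi_u, rec.iota_u) == (
            pytest.approx(2.0, rel=1e-9)
        )

    def test_inverted_abundances_raise(self):
        with pytest.raises(ValueError):
            alpha_from_unlabeled(0.5, 1.0, 1.0, 1.0, 2.0)


class TestObjective:
    def test_zero_at_truth(self, example_obs):
        assert objective_f(0.5, 1.0, example_obs.a, example_obs.b) == pytest.approx(
            0.0, abs=1e-16
        )

    def test_single_log_perturbation(self, example_obs):
        val = objective_f(0.5, 1.0, example_obs.a * math.exp(0.1), example_obs.b)
        assert val == pytest.approx(0.01, rel=1e-9)

    def test_nonnegative_everywhere(self, example_obs):
        for k in (0.45, 0.5, 0.6):
            for x in (0.5, 1.0, 2.0):
                assert objective_f(k, x, example_obs.a, example_obs.b) >= 0.0

    def test_reduced_objective_minimum_at_true_k(self, example_obs):
        assert objective_reduced(0.5, example_obs.a, example_obs.b) == pytest.approx(
            0.0, abs=1e-14
        )
        assert objective_reduced(0.6, example_obs.a, example_obs.b) > 1e-4


def _result(k, beta, gamma, status=Status.UNIQUE_ROOT, objective=math.nan):
    return EstimationResult(status=status, k=k, alpha=1.0, beta=beta, gamma=gamma,
                            objective_value=objective)


class TestResolveAmbiguity:
    def test_small_population_picks_nearest_candidate(self):
        """With few unambiguous transcripts, nearest to the population median wins."""
        cands = [_result(0.3, 0.3, 1.0), _result(3.0, 3.0, 1.0)]
        pop = [_result(0.4, 0.4, 1.0)]
        chosen = resolve_ambiguity(cands, pop)
        assert chosen.k == 0.3
        assert chosen.status is Status.AMBIGUOUS_RESOLVED

    def test_dense_population_uses_density(self):
        rng = np.random.default_rng(0)
        pop = [
            _result(k, b, g)
            for b, g in zip(np.exp(rng.normal(-1, 0.3, 200)),
                            np.exp(rng.normal(0.5, 0.3, 200)))
            for k in [b / g]
        ]
        cands = [_result(0.22, 0.37, 1.65), _result(40.0, 200.0, 5.0)]
        assert resolve_ambiguity(cands, pop).k == 0.22

    def test_identical_candidates_pick_first(self):
        cands = [_result(1.2, 1.2, 1.0), _result(1.2, 1.2, 1.0)]
        pop = [_result(0.5, 0.5, 1.0)] * 20
        assert resolve_ambiguity(cands, pop) is cands[0]

    def test_empty_population_uses_objective(self):
        cands = [
            _result(0.3, 0.3, 1.0, objective=2.0),
            _result(3.0, 3.0, 1.0, objective=0.5),
        ]
        assert resolve_ambiguity(cands, []).k == 3.0

    def test_wrong_candidate_count_raises(self):
        with pytest.raises(ValueError):
            resolve_ambiguity([_result(1.0, 1.0, 1.0)], [])


class TestEstimateTranscript:
    def test_full_pipeline_on_exact_record(self, example_record):
        res = estimate_transcript(example_record, 1.0)
        assert res.status is Status.UNIQUE_ROOT
        assert res.n_roots == 1
        assert res.k == pytest.approx(0.5, rel=1e-7)
        assert res.beta == pytest.approx(0.5, rel=1e-6)
        assert res.gamma == pytest.approx(1.0, rel=1e-6)
        assert res.alpha == pytest.approx(2.0, rel=1e-6)

    def test_labeled_alpha_source(self, example_record):
        res = estimate_transcript(example_record, 1.0, alpha_source="labeled")
        assert res.alpha == pytest.approx(2.0, rel=1e-6)

    def test_rejections_are_data_not_errors(self):
        rec = TranscriptRecord("t", "g", chi_u=10, iota_u=5, chi_l=8, iota_l=9)
        res = estimate_transcript(rec, 1.0)  # r_l = 1.125
        assert res.status is Status.REJECTED_RATIO_GE_1
        assert math.isnan(res.alpha) and math.isnan(res.gamma)
        assert res.r_l == pytest.approx(1.125)

        rec = TranscriptRecord("t", "g", chi_u=10, iota_u=6, chi_l=10, iota_l=4)
        assert estimate_transcript(rec, 1.0).status is Status.REJECTED_B_LE_A

        rec = TranscriptRecord("t", "g", chi_u=0.0, iota_u=0, chi_l=10, iota_l=4)
        assert estimate_transcript(rec, 1.0).status.rejected

    def test_invalid_arguments(self, example_record):
        with pytest.raises(ValueError):
            estimate_transcript(example_record, 0.0)
        with pytest.raises(ValueError):
            estimate_transcript(example_record, 1.0, alpha_source="total")


class TestEstimateAll:
    def test_ambiguous_resolved_against_population(self):
        """Two-root transcripts are resolved toward the population's rates."""
        rng = np.random.default_rng(1)
        records = []
        # population: k in the unique region, clustered around k=0.5, x=1
        for i, (k, x) in enumerate(zip(rng.uniform(0.4, 0.7, 40),
                                       rng.uniform(0.6, 1.5, 40))):
            records.append(forward_observe(RateTriplet(1.0, k * x, x), 1.0,
                                           transcript_id=f"u{i}"))
        amb = forward_observe(RateTriplet(1.0, 2.0 * 1.5, 1.5), 1.0,
                              transcript_id="amb")
        records.append(amb)
        results = estimate_all(records, 1.0)
        res = {r.transcript_id: r for r in results}["amb"]
        assert res.status is Status.AMBIGUOUS_RESOLVED
        assert res.n_roots == 2
        assert len(res.k_candidates) == 2
        # both candidates are genuine solutions; one matches the truth
        assert min(abs(c - 2.0) for c in res.k_candidates) < 1e-6

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        lk=st.floats(-3.0, 3.0).filter(lambda v: abs(v) > 1e-3),
        lx=st.floats(math.log(0.05), math.log(5.0)),
    )
    def test_forward_inverse_identity_in_unique_region(self, lk, lx):
        """Noise-free round trip recovers all three rates to 1e-6."""
        k, x = math.exp(lk), math.exp(lx)
        obs = obs_from(k, x)
        if classify_region(obs) is not Region.UNIQUE:
            return
        rates = RateTriplet(alpha=1.7, beta=k * x, gamma=x)  # T = 1
        res = estimate_transcript(forward_observe(rates, 1.0), 1.0)
        assert res.status is Status.UNIQUE_ROOT
        assert res.beta == pytest.approx(rates.beta, rel=1e-6)
        assert res.gamma == pytest.approx(rates.gamma, rel=1e-6)
        assert res.alpha == pytest.approx(rates.alpha, rel=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        lk=st.floats(-2.0, 2.0).filter(lambda v: abs(v) > 1e-3),
        lx=st.floats(math.log(0.05), math.log(5.0)),
        c=st.floats(0.2, 5.0),
    )
    def test_pulse_length_invariance_of_k(self, lk, lx, c):
        """Scaling T by c and rates by 1/c leaves k and the observables unchanged."""
        k, x = math.exp(lk), math.exp(lx)
        r1 = forward_observe(RateTriplet(1.0, k * x, x), 1.0)
        r2 = forward_observe(RateTriplet(1.0 / c, k * x / c, x / c), c)
        assert r1.iota_u / r1.chi_u == pytest.approx(r2.iota_u / r2.chi_u, rel=1e-9)
        assert r1.iota_l / r1.chi_l == pytest.approx(r2.iota_l / r2.chi_l, rel=1e-9)
        res1 = estimate_transcript(r1, 1.0)
        res2 = estimate_transcript(r2, c)
        if not res1.status.rejected and not res2.status.rejected:
            assert res2.k == pytest.approx(res1.k, rel=1e-6)
            assert res2.gamma == pytest.approx(res1.gamma / c, rel=1e-6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        lk=st.floats(-3.0, 3.0).filter(lambda v: abs(v) > 1e-3),
        lx=st.floats(math.log(0.05), math.log(5.0)),
    )
    def test_returned_k_respects_domain(self, lk, lx):
        """Every returned root satisfies the domain inequalities strictly."""
        obs = obs_from(math.exp(lk), math.exp(lx))
        dom = admissible_domain(obs)
        for k in solve_k(obs):
            assert dom.lower < k < dom.upper
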