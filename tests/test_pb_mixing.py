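"""Three-end-member Pb-isotope mixing: forward model, inversion, properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilrisk.constants import SOURCE_FRACTION_TABLE
from soilrisk.pb_mixing import (EndMemberSet, SingularMixingError,
                                default_r_prime, forward_mix, solve_mix,
                                solve_mix_overdetermined,
                                summarize_contributions, sensitivity_sweep)


class TestForward:
    def test_pure_end_member(self):
        obs = forward_mix((1.0, 0.0, 0.0))
        assert obs["r206_207"] == pytest.approx(1.2252)
        assert obs["c_pb"] == pytest.approx(6681.0)

    def test_hand_evaluated_mixture(self):
        # 0.3·1.2252 + 0.5·1.1497 + 0.2·1.097 and the harmonic concentration
        obs = forward_mix((0.3, 0.5, 0.2))
        assert obs["r206_207"] == pytest.approx(1.16181, abs=1e-5)
        assert obs["c_pb"] == pytest.approx(2967.9, abs=0.1)

    def test_symmetric_mixture_is_mean(self):
        ems = EndMemberSet()
        obs = forward_mix((1 / 3, 1 / 3, 1 / 3), ems)
        assert obs["r206_207"] == pytest.approx(np.mean(ems.r))

    def test_rejects_non_simplex(self):
        with pytest.raises(ValueError, match="sum to 1"):
            forward_mix((0.5, 0.5, 0.5))

    def test_linear_rule_differs(self):
        h = forward_mix((0.3, 0.5, 0.2))["c_pb"]
        lin = forward_mix((0.3, 0.5, 0.2), concentration_rule="linear")["c_pb"]
        assert lin == pytest.approx(0.3 * 6681 + 0.7 * 2397)
        assert lin != pytest.approx(h)

    def test_mixing_envelope(self):
        ems = EndMemberSet()
        rng = np.random.default_rng(5)
        for f in rng.dirichlet((1, 1, 1), size=50):
            obs = forward_mix(f, ems)
            assert min(ems.r) - 1e-12 <= obs["r206_207"] <= max(ems.r) + 1e-12
            assert min(ems.c) - 1e-9 <= obs["c_pb"] <= max(ems.c) + 1e-9


class TestSolve:
    def test_round_trip_recovers_fractions(self):
        truth = (0.3, 0.5, 0.2)
        res = solve_mix(forward_mix(truth))
        assert np.allclose(res.fractions, truth, atol=1e-9)
        assert res.feasible

    def test_pure_end_member_observation(self):
        res = solve_mix({"r206_207": 1.2252, "c_pb": 6681.0})
        assert np.allclose(res.fractions, (1.0, 0.0, 0.0), atol=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_over_random_mixes_and_end_members(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet((1.0, 1.0, 1.0))
        r = np.sort(rng.uniform(1.05, 1.30, size=3))[::-1]
        c = rng.uniform(500, 10000, size=3)
        ems = EndMemberSet(r=tuple(r), c=tuple(c))
        res = solve_mix(forward_mix(f, ems), ems)
        assert np.allclose(res.fractions, f, atol=1e-8)
        assert sum(res.fractions) == pytest.approx(1.0, abs=1e-9)
        # forward∘solve reproduces the observation
        back = forward_mix(np.clip(res.fractions, 0, 1)
                           / np.sum(np.clip(res.fractions, 0, 1)), ems)
        assert back["r206_207"] == pytest.approx(
            forward_mix(f, ems)["r206_207"], rel=1e-9)

    def test_sum_to_one_even_when_infeasible(self):
        res = solve_mix({"r206_207": 1.5, "c_pb": 100.0})  # outside envelope
        assert sum(res.fractions) == pytest.approx(1.0, abs=1e-9)
        assert not res.feasible
        assert "envelope" in res.diagnostics

    def test_degenerate_end_members_rejected(self):
        with pytest.raises(SingularMixingError, match="industrial"):
            EndMemberSet(r=(1.2252, 1.097, 1.097))

    def test_simplex_projection_opt_in(self):
        res = solve_mix({"r206_207": 1.5, "c_pb": 100.0},
                        project_to_simplex=True)
        f = np.array(res.fractions)
        assert np.all(f >= 0) and f.sum() == pytest.approx(1.0)
        assert "projected" in res.diagnostics

    def test_continuity_under_small_perturbation(self):
        obs = forward_mix((0.3, 0.5, 0.2))
        base = solve_mix(obs)
        bumped = solve_mix({"r206_207": obs["r206_207"] + 1e-6,
                            "c_pb": obs["c_pb"]})
        delta = np.abs(np.array(bumped.fractions) - np.array(base.fractions))
        assert delta.max() < base.condition_number * 1e-4
        assert np.isfinite(base.condition_number)


class TestOverdetermined:
    def test_consistent_observation_matches_exact_solver(self):
        ems = EndMemberSet(r_prime=default_r_prime())
        truth = (0.25, 0.45, 0.30)
        obs = forward_mix(truth, ems)
        res = solve_mix_overdetermined(obs, ems)
        assert np.allclose(res.fractions, truth, atol=1e-6)
        assert res.residual_norm < 1e-8

    def test_noisy_ratio_keeps_sum_constraint(self):
        ems = EndMemberSet(r_prime=default_r_prime())
        obs = forward_mix((0.25, 0.45, 0.30), ems)
        obs["r208_207"] *= 1.002
        res = solve_mix_overdetermined(obs, ems)
        assert sum(res.fractions) == pytest.approx(1.0, abs=1e-9)
        assert res.residual_norm > 0

    def test_conflicting_observation_flagged(self):
        ems = EndMemberSet(r_prime=default_r_prime())
        res = solve_mix_overdetermined(
            {"r206_207": 1.4, "r208_207": 2.0, "c_pb": 50.0}, ems)
        assert not res.feasible


class TestSummaries:
    def test_published_table_column_means(self):
        rows = [solve_mix(forward_mix(f), sample_id=sid)
                for sid, f in SOURCE_FRACTION_TABLE.items()]
        # overwrite with the printed fractions themselves
        for r, (sid, f) in zip(rows, SOURCE_FRACTION_TABLE.items()):
            r.fractions = f
        summary = summarize_contributions(rows)
        assert summary["geogenic"]["mean"] == pytest.approx(0.2583, abs=5e-5)
        assert summary["industrial"]["mean"] == pytest.approx(0.5125, abs=5e-5)
        assert summary["traffic"]["mean"] == pytest.approx(0.2292, abs=5e-5)

    def test_every_published_row_sums_to_one(self):
        for f in SOURCE_FRACTION_TABLE.values():
            assert sum(f) == pytest.approx(1.0, abs=1e-12)

    def test_single_result(self):
        res = solve_mix(forward_mix((0.2, 0.5, 0.3)))
        s = summarize_contributions([res])
        assert s["geogenic"]["mean"] == pytest.approx(res.f1)

    def test_permutation_invariance(self):
        results = [solve_mix(forward_mix(f)) for f in
                   ((0.2, 0.5, 0.3), (0.4, 0.4, 0.2), (0.1, 0.6, 0.3))]
        a = summarize_contributions(results)
        b = summarize_contributions(list(reversed(results)))
        assert a == b


def test_sensitivity_sweep_spans_industrial_range():
    obs = forward_mix((0.3, 0.5, 0.2))
    sweep = sensitivity_sweep(obs)
    r2s = [r2 for r2, _ in sweep]
    assert r2s[0] == pytest.approx(1.1427) and r2s[-1] == pytest.approx(1.1567)
    for _, res in sweep:
        assert sum(res.fractions) == pytest.approx(1.0, abs=1e-9)
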