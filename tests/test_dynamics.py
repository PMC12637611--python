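"""Transition maps, Cochran-Armitage trend test, group comparisons."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import lesiontrack as lt
from lesiontrack.synthetic import BehaviorConfig, generate_behavior_sequences


def seq_df(states_by_lesion, mouse="m0"):
    rows = []
    for lesion, states in states_by_lesion.items():
        for i, s in enumerate(states):
            rows.append(
                {"lesion_id": lesion, "mouse_id": mouse, "session": i,
                 "lesion_age": 2.0 * i, "state": s}
            )
    return pd.DataFrame(rows)


class TestTransitionMap:
    def test_constant_sequences(self):
        tm = lt.transition_map(seq_df({"L0": ["scattered"] * 5, "L1": ["scattered"] * 4}))
        assert tm.maintenance.loc["scattered", "mean"] == 1.0
        assert tm.maintenance.loc["scattered", "sem"] == 0.0

    def test_hand_enumerated_sequence(self):
        """B,S,S,B: maintenance(S) = 1/2 and change(B->S) = 1."""
        tm = lt.transition_map(
            seq_df({"L0": ["basally_confined", "scattered", "scattered", "basally_confined"]})
        )
        assert tm.maintenance.loc["scattered", "mean"] == 0.5
        assert tm.change.loc[("basally_confined", "scattered"), "mean"] == 1.0

    def test_rows_sum_to_one_per_mouse(self):
        seqs, _ = generate_behavior_sequences(BehaviorConfig(n_lesions=60, seed=5))
        tm = lt.transition_map(seqs)
        dest_cols = [c for c in tm.per_mouse.columns if c.startswith("to:")]
        totals = tm.per_mouse["maintain"] + tm.per_mouse[dest_cols].sum(axis=1)
        assert np.allclose(totals, 1.0)

    def test_recovers_generator_change_probability(self):
        """Scattered change probability within sampling error of the 32% default."""
        cfg = BehaviorConfig(n_lesions=800, sequence_length=10, seed=6)
        seqs, _ = generate_behavior_sequences(cfg)
        est = lt.TransitionMapEstimator(pooled=True).fit(seqs)
        n = int(est.map_.n_transitions["scattered"])
        p = cfg.change_prob_by_state["scattered"]
        assert abs(est.change_probability("scattered") - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_no_transitions_error(self):
        with pytest.raises(ValueError, match="transition"):
            lt.transition_map(seq_df({"L0": ["scattered"]}))

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            lt.transition_map(seq_df({"L0": ["scattered", "swirling"]}))


def brute_force_exact_p(table, scores):
    """Independent enumeration oracle over all tables with the observed margins."""
    table = np.asarray(table, dtype=int)
    scores = np.asarray(scores, dtype=float)
    successes, totals = table[0], table.sum(axis=0)
    R1, N = successes.sum(), totals.sum()
    t_obs = float(scores @ successes)
    e_t = R1 / N * float(scores @ totals)
    p = 0.0
    ranges = [range(t + 1) for t in totals]
    import itertools

    for xs in itertools.product(*ranges):
        if sum(xs) != R1:
            continue
        w = np.prod([comb(int(t), x) for t, x in zip(totals, xs)]) / comb(int(N), int(R1))
        if abs(float(scores @ np.array(xs)) - e_t) >= abs(t_obs - e_t) - 1e-9:
            p += w
    return p


class TestCochranArmitage:
    def test_equal_proportions_zero_statistic(self):
        res = lt.cochran_armitage([[4, 8, 12], [2, 4, 6]], scores=[0, 1, 2])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_brute_force_oracle(self):
        for table in ([[5, 0, 2], [0, 1, 4]], [[3, 1, 1], [0, 2, 5]], [[6, 3, 1], [1, 4, 5]]):
            res = lt.cochran_armitage(table, scores=[0.0, 1.0, 2.0], method="exact")
            assert res.p_exact == pytest.approx(brute_force_exact_p(table, [0, 1, 2]), abs=1e-12)

    def test_asymptotic_near_exact_on_example_table(self):
        """n=12 example table: asymptotic p within 0.02 of the permutation oracle."""
        res = lt.cochran_armitage([[5, 0, 2], [0, 1, 4]], scores=[0.0, 1.0, 2.0], method="exact")
        assert res.n == 12
        assert abs(res.p_value - res.p_exact) < 0.02

    def test_k2_reduces_to_two_by_two_chi_square(self):
        """K=2: Z^2 equals the score-free 2x2 trend chi-square (N-1)/N * Pearson."""
        table = [[8, 3], [2, 9]]
        res = lt.cochran_armitage(table, scores=[0, 1])
        chi2 = stats.chi2_contingency(np.array(table), correction=False).statistic
        N = np.sum(table)
        assert res.statistic**2 == pytest.approx(chi2 * (N - 1) / N, abs=1e-10)

    def test_matches_statsmodels_linear_by_linear(self):
        from statsmodels.stats.contingency_tables import Table

        table = [[3, 5, 7], [5, 4, 1]]
        res = lt.cochran_armitage(table, scores=[0.0, 1.0, 2.0])
        sm = Table(np.array(table).T).test_ordinal_association(
            row_scores=np.array([0.0, 1.0, 2.0]), col_scores=np.array([1.0, 0.0])
        )
        assert res.statistic == pytest.approx(float(sm.zscore), abs=1e-10)
        assert res.p_value == pytest.approx(float(sm.pvalue), abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin|degenerate"):
            lt.cochran_armitage([[0, 0, 0], [3, 4, 5]], scores=[0, 1, 2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 50), b=st.floats(-100, 100),
        seed=st.integers(0, 1000),
    )
    def test_affine_score_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 10, size=(2, 4))
        scores = np.array([0.0, 1.0, 3.0, 7.0])
        z1 = lt.cochran_armitage(table, scores).statistic
        z2 = lt.cochran_armitage(table, a * scores + b).statistic
        assert z2 == pytest.approx(z1, abs=1e-9)


class TestMaintenanceByAge:
    def test_identical_bins_zero_trend(self):
        # two lesions, identical maintenance behaviour at every age
        states = ["scattered", "scattered", "scattered", "basally_confined"] * 2
        df = seq_df({"L0": states, "L1": states})
        out, res = lt.maintenance_by_age(df, "scattered", age_bin_edges=[0, 6, 20])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_planted_monotone_trend_detected(self):
        """Maintenance rising with age gives a positive, significant trend."""
        rng = np.random.default_rng(0)
        rows = []
        for lesion in range(120):
            p_by_age = {0: 0.3, 2: 0.45, 4: 0.6, 6: 0.75, 8: 0.9}
            states = ["scattered"]
            for age in [0, 2, 4, 6, 8]:
                nxt = "scattered" if rng.random() < p_by_age[age] else "multifocal"
                states.append(nxt)
                if nxt != "scattered":
                    break
            for i, s in enumerate(states):
                rows.append({"lesion_id": f"L{lesion}", "mouse_id": "m0",
                             "session": i, "lesion_age": 2.0 * i, "state": s})
        df = pd.DataFrame(rows)
        out, res = lt.maintenance_by_age(df, "scattered", age_bin_edges=[0, 2, 4, 6, 8, 10])
        assert res.statistic > 0
        assert res.p_value < 0.01
        assert out["maintenance"].is_monotonic_increasing

    def test_single_bin_rejected(self):
        df = seq_df({"L0": ["scattered"] * 4})
        with pytest.raises(ValueError):
            lt.maintenance_by_age(df, "scattered", age_bin_edges=[0, 10])


class TestCompareGroups:
    def test_identical_values_unit_p(self):
        res = lt.compare_groups({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_omnibus_matches_rank_formula_oracle(self):
        groups = {"g1": [1.0, 3.0, 5.0], "g2": [2.0, 4.0, 8.0], "g3": [9.0, 10.0, 11.0]}
        values = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(values)
        n = len(values)
        start, H = 0, 0.0
        for g in groups.values():
            r = ranks[start : start + len(g)]
            H += r.sum() ** 2 / len(g)
            start += len(g)
        H = 12 / (n * (n + 1)) * H - 3 * (n + 1)  # no ties -> no correction
        res = lt.compare_groups(groups)
        assert res.statistic == pytest.approx(H, abs=1e-10)

    def test_pairwise_adjustment_and_shape(self):
        rng = np.random.default_rng(1)
        groups = {s: rng.normal(i, 1, size=12) for i, s in enumerate(lt.MYELOID_STATES)}
        res = lt.compare_groups(groups)
        assert len(res.pairwise) == len(list(combinations(lt.MYELOID_STATES, 2)))
        assert (res.pairwise["p_adj"] >= res.pairwise["p"] - 1e-12).all()

    def test_displacement_by_state_separates_phantom_states(self, state_phantoms):
        """Omnibus test applied to displacement stratified by the four states."""
        rng = np.random.default_rng(2)
        from test_state import segment_features

        groups = {}
        for s in lt.MYELOID_STATES:
            base = segment_features(*state_phantoms[s]).displacement
            groups[s] = base * rng.uniform(0.9, 1.1, size=8)  # session-level jitter
        res = lt.compare_groups(groups)
        assert res.p_value < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="zero observations"):
            lt.compare_groups({"a": [1.0], "b": []})
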