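import numpy as np
import pytest
from scipy import stats

from dyadlang.features import PER_SPEAKER_FEATURES, UtteranceSeries
from dyadlang.design import (
    between_pair_count,
    candidate_link_count,
    design_summary,
    retained_session_count,
)
from dyadlang.responsiveness import (
    DyadGraph,
    LaggedLink,
    ResponsivenessConfig,
    adf_stationary,
    aggregate_graphs,
    dyad_graph,
    first_difference,
    mci_test,
    partial_corr_test,
    pc1_parents,
    screen_session,
)

from oracles import partial_corr_residual_oracle

CFG = ResponsivenessConfig()
WPS = PER_SPEAKER_FEATURES.index("Words per Second")


def make_series(rng, T=120, sid="S000", patient=None, therapist=None):
    """Numeric UtteranceSeries: independent noise except planted columns."""
    pat = rng.normal(size=(T, 16))
    ther = rng.normal(size=(T, 16))
    if patient is not None:
        for j, col in patient.items():
            pat[:, j] = col
    if therapist is not None:
        for j, col in therapist.items():
            ther[:, j] = col
    return UtteranceSeries(session_id=sid, patient=pat, therapist=ther)


class TestFirstDifference:
    def test_examples(self):
        assert list(first_difference([1, 3, 6, 10])) == [2, 3, 4]
        assert np.allclose(first_difference([5.0] * 6), 0.0)
        assert np.allclose(first_difference(np.arange(10) * 2.5), 2.5)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            first_difference([1.0])


class TestAdf:
    def test_white_noise_is_stationary(self, rng):
        hits = sum(
            adf_stationary(rng.normal(size=500)).stationary for _ in range(40)
        )
        assert hits >= 36  # ≥90% at high power

    def test_random_walk_rejection_near_alpha(self, rng):
        hits = sum(
            adf_stationary(np.cumsum(rng.normal(size=500))).stationary
            for _ in range(200)
        )
        assert abs(hits / 200 - 0.05) < 0.04

    def test_constant_series_flagged_not_tested(self):
        with pytest.raises(ValueError, match="zero-variance"):
            adf_stationary(np.ones(50))


class TestScreening:
    def test_zero_variance_feature_excluded_with_name(self, rng):
        s = make_series(rng, patient={3: np.zeros(120)})
        rep = screen_session(s, CFG)
        assert not rep.included
        assert rep.reason == "zero_variance_feature"
        assert f"patient:{PER_SPEAKER_FEATURES[3]}" in rep.offending

    def test_integrated_of_order_two_column_nonstationary(self, rng):
        i2 = np.cumsum(np.cumsum(rng.normal(size=120)))
        rep = screen_session(make_series(rng, therapist={5: i2}), CFG)
        assert not rep.included
        assert rep.reason == "nonstationary_after_differencing"
        assert f"therapist:{PER_SPEAKER_FEATURES[5]}" in rep.offending

    def test_well_behaved_series_included(self, rng):
        rep = screen_session(make_series(rng), CFG)
        assert rep.included and rep.reason == "ok"

    def test_short_series_flagged(self, rng):
        rep = screen_session(make_series(rng, T=5), CFG)
        assert rep.reason == "too_short"


class TestPartialCorr:
    def test_plain_correlation_when_no_conditioners(self):
        rho, _ = partial_corr_test([1, 2, 3], [6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_conditioning_removes_confounder(self):
        x = np.array([1.0, 2, 3, 4, 5])
        z = np.array([1.0, 0, 1, 0, 1])
        y = x + 2 * z
        rho, _ = partial_corr_test(x, y, [z])
        assert rho == pytest.approx(1.0)

    def test_matches_residual_regression_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(size=60)
            Z = [rng.normal(size=60) for _ in range(3)]
            y = rng.normal(size=60) + 0.5 * Z[0]
            rho, _ = partial_corr_test(x, y, Z)
            assert rho == pytest.approx(
                partial_corr_residual_oracle(x, y, Z), abs=1e-9)

    def test_null_pvalues_uniform(self, rng):
        ps = []
        for _ in range(400):
            x, y, z = rng.normal(size=(3, 200))
            ps.append(partial_corr_test(x, y, [z])[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_residual_returns_zero(self):
        z = np.arange(10.0)
        rho, p = partial_corr_test(2 * z, np.arange(10.0) ** 2, [z])
        assert rho == 0.0 and p == 1.0


def _var2(rng, T, coeff=0.7, ar=0.4):
    """Bivariate VAR with X(t-1) -> Y(t)."""
    x = np.zeros(T)
    y = np.zeros(T)
    for t in range(1, T):
        x[t] = ar * x[t - 1] + rng.normal()
        y[t] = ar * y[t - 1] + coeff * x[t - 1] + rng.normal()
    return np.column_stack([x, y])


class TestPc1:
    def test_planted_lagged_parent_recovered(self, rng):
        hits = 0
        for _ in range(40):
            parents = pc1_parents(_var2(rng, 500), tau_max=2, alpha_pc=0.2)
            hits += (0, 1) in parents[1]
        assert hits >= 38

    def test_null_system_selects_few_parents(self, rng):
        sizes = []
        for _ in range(50):
            data = rng.normal(size=(150, 4))
            parents = pc1_parents(data, tau_max=2, alpha_pc=0.2)
            sizes.extend(len(v) for v in parents.values())
        assert np.mean(sizes) <= 0.2 * 8  # alpha_pc x candidate count

    def test_chain_parent_screened_off_by_mediator(self, rng):
        # X -> M -> Y: (X, -2) is d-separated from Y given M(t-1), so it
        # should be pruned; spurious parents survive at ~alpha_pc rate, so
        # the check runs at alpha_pc = 0.1 to test the property with margin
        hits = 0
        for _ in range(20):
            T = 800
            x = rng.normal(size=T)
            m = np.zeros(T)
            y = np.zeros(T)
            for t in range(1, T):
                m[t] = 0.8 * x[t - 1] + 0.3 * rng.normal()
                y[t] = 0.8 * m[t - 1] + 0.3 * rng.normal()
            parents = pc1_parents(np.column_stack([x, m, y]), 2, alpha_pc=0.1)
            hits += (0, 2) not in parents[2]
        assert hits >= 16


class TestMci:
    def test_reduces_to_lagged_partial_correlation_without_parents(self, rng):
        data = rng.normal(size=(80, 3))
        rho_mci, p_mci = mci_test(data, 0, 1, 2, {}, tau_max=1)
        # the MCI sample starts at tau_max + tau so all lags share one window
        x = data[1:-1, 0]
        y = data[2:, 2]
        rho_ref, p_ref = partial_corr_test(x, y)
        assert rho_mci == pytest.approx(rho_ref, abs=1e-12)
        assert p_mci == pytest.approx(p_ref, abs=1e-12)

    def test_pure_lag1_link_scores_better_at_lag1(self, rng):
        wins = 0
        for _ in range(20):
            data = _var2(rng, 400)
            parents = pc1_parents(data, 2, 0.2)
            _, p1 = mci_test(data, 0, 1, 1, parents, 2)
            _, p0 = mci_test(data, 0, 0, 1, parents, 2)
            wins += p1 < p0
        assert wins >= 16

    def test_planted_negative_link_sign_recovered(self, rng):
        data = _var2(rng, 400, coeff=-0.6)
        parents = pc1_parents(data, 2, 0.2)
        rho, p = mci_test(data, 0, 1, 1, parents, 2)
        assert rho < 0 and p < 1e-6


class TestDyadGraph:
    def test_planted_cross_link_found_with_sign(self, rng):
        T = 300
        x = np.zeros(T)
        y = np.zeros(T)
        for t in range(1, T):
            x[t] = 0.3 * x[t - 1] + rng.normal()
            y[t] = 0.3 * y[t - 1] - 0.5 * x[t] + rng.normal()
        s = make_series(rng, T=T, patient={WPS: x}, therapist={WPS: y})
        g = dyad_graph(s, CFG)
        found = [l for l in g.links
                 if l.source == "Words per Second" and l.target == "Words per Second"]
        assert len(found) == 1
        assert found[0].rho < 0 and found[0].lag == 0
        assert g.n_tested == 256

    def test_zero_link_graph_is_valid(self, rng):
        g = dyad_graph(make_series(rng, T=60), CFG)
        assert isinstance(g.links, list)  # may legitimately be empty
        assert g.n_tested == 256


class TestAggregate:
    def _graph(self, sid, rho):
        link = LaggedLink("Words per Second", "Words per Second", 0, rho,
                          0.001, 0.01, True)
        return DyadGraph(session_id=sid, links=[link], n_tested=256)

    def test_shared_link_counted_and_averaged(self):
        agg = aggregate_graphs([self._graph("a", -0.2), self._graph("b", -0.4)])
        row = agg.iloc[0]
        assert row["count"] == 2
        assert row["mean_rho"] == pytest.approx(-0.3)
        assert row["n_negative"] == 2

    def test_min_count_filter(self):
        graphs = [self._graph(str(i), -0.2) for i in range(5)]
        other = DyadGraph("x", [LaggedLink("Positive", "Hedging", 1, 0.3,
                                           0.001, 0.01, True)], 256)
        agg = aggregate_graphs(graphs + [other], min_count=4)
        assert len(agg) == 1 and agg.iloc[0]["count"] == 5

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate_graphs([])


class TestDesignArithmetic:
    def test_candidate_links_for_retained_dyads(self):
        assert retained_session_count(78, 2, 3) == 73
        assert candidate_link_count(73) == 18_688

    def test_between_pairs(self):
        assert between_pair_count(78) == 3003
        assert between_pair_count(2) == 1

    def test_full_summary_rounds(self):
        s = design_summary(78, 2, 3, 303)
        assert round(s["significant_link_rate_percent"], 1) == 1.6
        assert round(s["links_per_dyad"], 1) == 4.2
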