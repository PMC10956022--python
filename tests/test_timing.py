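import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadlang.timing import (
    bh_fdr,
    mann_whitney_u,
    natural_cubic_spline,
    quintile_curves,
    timing_contrasts,
)
from dyadlang.transcripts import Corpus

from conftest import make_session
from oracles import bh_reject_enumeration, mann_whitney_enumeration


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 extreme labelings / C(6,3)=20

    def test_identical_multisets_give_central_u(self):
        a = [1.0, 2.0, 2.0, 5.0]
        u, p = mann_whitney_u(a, list(a))
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p == pytest.approx(1.0)

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=6),
        st.lists(st.integers(0, 5), min_size=2, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_p_matches_full_enumeration_with_ties(self, a, b):
        u, p = mann_whitney_u(a, b)
        u_ref, p_ref = mann_whitney_enumeration(a, b)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_exact_and_asymptotic_agree_for_moderate_n(self, rng):
        # property: approximation error below 0.02 in p around n=10..12
        for _ in range(30):
            a = rng.normal(size=6)
            b = rng.normal(size=6) + rng.normal(0, 0.5)
            _, p_exact = mann_whitney_u(list(a), list(b))
            from scipy.stats import mannwhitneyu
            p_asym = mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_power_against_one_sd_shift(self, rng):
        # two groups of 78, shift of 1 sd: rejections should dominate
        rejected = 0
        n_sim = 120
        for _ in range(n_sim):
            a = rng.normal(size=78)
            b = rng.normal(loc=1.0, size=78)
            _, p = mann_whitney_u(a, b)
            rejected += p < 0.05
        assert rejected / n_sim > 0.9

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBhFdr:
    def test_worked_example(self):
        reject, q = bh_fdr([0.01, 0.02, 0.04, 0.5], alpha=0.05)
        # thresholds i*alpha/m = .0125, .025, .0375, .05
        assert list(reject) == [True, True, False, False]

    def test_all_zero_pvalues_all_rejected(self):
        reject, _ = bh_fdr([0.0] * 7, alpha=0.05)
        assert reject.all()

    def test_adjusted_values_monotone_and_geq_p(self):
        ps = [0.001, 0.02, 0.015, 0.8, 0.3]
        _, q = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.array(ps) - 1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_matches_threshold_enumeration_oracle(self, ps):
        reject, _ = bh_fdr(ps, alpha=0.05)
        assert list(reject) == list(bh_reject_enumeration(ps, 0.05))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_rejections_superset_of_bonferroni(self, ps):
        reject, _ = bh_fdr(ps, alpha=0.05)
        bonf = np.asarray(ps) <= 0.05 / len(ps)
        assert np.all(reject[bonf])

    def test_null_uniform_pvalues_rarely_rejected(self, rng):
        total = 0
        for _ in range(300):
            ps = rng.uniform(size=100)
            reject, _ = bh_fdr(ps, alpha=0.05)
            total += reject.sum()
        # under the global null the expected number of false discoveries
        # per family is far below alpha*m
        assert total / 300 <= 0.05 * 100

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.2, 1.4])


class TestNaturalCubicSpline:
    def test_reproduces_linear_data(self):
        cs = natural_cubic_spline([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
        assert cs(2.5) == pytest.approx(1.5)

    def test_interpolates_knots_exactly(self):
        ys = [0.3, 1.2, -0.5, 2.0, 0.0]
        cs = natural_cubic_spline([1, 2, 3, 4, 5], ys)
        assert np.allclose(cs([1, 2, 3, 4, 5]), ys, atol=1e-12)

    def test_symmetric_input_gives_symmetric_curve(self):
        cs = natural_cubic_spline([1, 2, 3, 4, 5], [0, 1, 2, 1, 0])
        xs = np.linspace(1, 3, 41)
        assert np.allclose(cs(xs), cs(6 - xs), atol=1e-9)

    def test_natural_boundary_second_derivative_zero(self):
        cs = natural_cubic_spline([1, 2, 3, 4, 5], [0.3, 1.2, -0.5, 2.0, 0.0])
        assert abs(cs(1, 2)) < 1e-9 and abs(cs(5, 2)) < 1e-9

    def test_duplicate_x_raises(self):
        with pytest.raises(ValueError):
            natural_cubic_spline([1, 2, 2, 4, 5], [0, 1, 2, 3, 4])


def _flat_corpus(n_sessions=6):
    """Sessions whose feature distributions are identical across quintiles
    and speakers."""
    sessions = []
    for i in range(n_sessions):
        texts = ["i never feel calm now maybe you see"] * 20
        sessions.append(
            make_session(texts, session_id=f"S{i:03d}", therapist_id=f"T{i:03d}",
                         patient_id=f"P{i:03d}")
        )
    return Corpus(sessions=sessions)


class TestQuintileCurves:
    def test_identical_sessions_give_single_session_values(self, counter):
        corpus = _flat_corpus(2)
        curves = quintile_curves(corpus, counter)
        c = curves[("Absolutist", "therapist")]
        assert np.allclose(c.means, c.per_session[0][0])

    def test_constant_feature_yields_flat_curve(self, counter):
        curves = quintile_curves(_flat_corpus(4), counter)
        c = curves[("Absolutist", "patient")]
        assert np.allclose(c.means, c.means[0])
        assert np.allclose(c.normalized(), 0.5)


class TestPlotting:
    def test_plot_files_written_per_group(self, counter, tmp_path):
        from dyadlang.timing import plot_quintile_curves

        curves = quintile_curves(_flat_corpus(3), counter)
        paths = plot_quintile_curves(curves, tmp_path)
        assert paths and all(p.exists() and p.stat().st_size > 0 for p in paths)
        names = {p.name for p in paths}
        assert "curves_paralinguistic_style.png" in names


class TestTimingContrasts:
    def test_identical_distributions_label_indistinct(self, counter):
        results, labels = timing_contrasts(_flat_corpus(8), counter)
        by_feature = {l.feature: l.label for l in labels}
        assert by_feature["Absolutist"] == "indistinct"
        assert not any(r.significant for r in results)

    def test_single_combined_fdr_family(self, counter):
        results, _ = timing_contrasts(_flat_corpus(6), counter)
        # q-values computed over the one declared family: all share its size
        ps = [r.p for r in results]
        _, q = bh_fdr(ps)
        assert np.allclose(sorted(q), sorted(r.q for r in results))
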