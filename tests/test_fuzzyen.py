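"""Unit and property tests for the fuzzy-entropy core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegfatigue.fuzzyen import (
    FuzzyEnParams,
    chebyshev_distance,
    embed_windows,
    fuzzy_entropy,
    fuzzy_entropy_oracle,
    phi,
    similarity,
)


class TestEmbedWindows:
    def test_linear_ramp_windows_identical(self):
        w = embed_windows([1, 2, 3, 4, 5], m=2)
        assert w.shape == (3, 2)
        assert np.allclose(w, [[-0.5, 0.5]] * 3)

    def test_hand_computed_windows(self):
        # x=[0,1,0,2], m=2: first N-m windows, each minus its own mean
        w = embed_windows([0, 1, 0, 2], m=2)
        assert np.allclose(w, [[-0.5, 0.5], [0.5, -0.5]])

    def test_constant_series_gives_zero_vectors(self):
        w = embed_windows([3.0] * 8, m=3)
        assert np.all(w == 0)

    def test_rows_sum_to_zero(self, rng):
        w = embed_windows(rng.standard_normal(40), m=5)
        assert np.allclose(w.sum(axis=1), 0, atol=1e-12)
        assert w.shape == (35, 5)

    def test_count_override_for_higher_dimension(self, rng):
        x = rng.standard_normal(30)
        assert embed_windows(x, 3, n_vectors=28).shape == (28, 3)

    @pytest.mark.parametrize("x, m", [([1, 2, 3], 2), ([1], 1), ([1, 2, 3, 4], 3)])
    def test_too_short_series_raises_with_sizes_named(self, x, m):
        with pytest.raises(ValueError, match=rf"N={len(x)}.*{m + 2}"):
            embed_windows(x, m)

    def test_non_finite_samples_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            embed_windows([1.0, np.nan, 2.0, 3.0], 1)


class TestDistanceAndSimilarity:
    def test_hand_computed_chebyshev(self):
        assert chebyshev_distance([-0.5, 0.5], [0.5, -0.5]) == 1.0

    def test_identity_and_symmetry(self, rng):
        v = rng.standard_normal(4)
        u = rng.standard_normal(4)
        assert chebyshev_distance(v, v) == 0.0
        assert chebyshev_distance(u, v) == chebyshev_distance(v, u)
        a = 0.7
        assert chebyshev_distance([0, 0], [a, -a]) == pytest.approx(a)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            chebyshev_distance([1, 2], [1, 2, 3])

    @pytest.mark.parametrize("form", ["as_printed", "normalized"])
    def test_zero_distance_is_full_similarity(self, form):
        assert similarity(0.0, n=4, r=0.2, form=form) == 1.0

    def test_as_printed_arithmetic(self):
        # d=1, n=4, r=0.2 -> exp(-1/0.2) = exp(-5)
        assert similarity(1.0, 4, 0.2, "as_printed") == pytest.approx(np.exp(-5), rel=1e-14)

    def test_normalized_arithmetic(self):
        assert similarity(0.4, 4, 0.2, "normalized") == pytest.approx(np.exp(-16), rel=1e-12)

    @pytest.mark.parametrize("form", ["as_printed", "normalized"])
    def test_strictly_decreasing_and_bounded(self, form):
        # range kept small enough that the steep normalized kernel does not
        # underflow to exactly zero in float64
        d = np.linspace(0, 0.4, 50)
        s = similarity(d, 4, 0.2, form)
        assert np.all(np.diff(s) < 0)
        assert np.all((s > 0) & (s <= 1))

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            similarity(1.0, 4, 0.0)


class TestPhi:
    @pytest.mark.parametrize("x", [np.full(20, 2.5), np.arange(20.0)])
    def test_regular_series_phi_is_one(self, x):
        # identical centred windows -> all similarities 1
        for m in (2, 3):
            assert phi(x, m, FuzzyEnParams(), r=0.1) == pytest.approx(1.0, abs=1e-14)

    def test_matches_naive_definition(self, rng):
        x = rng.standard_normal(50)
        p = FuzzyEnParams()
        r = 0.2 * np.std(x)
        vecs = embed_windows(x, 2, n_vectors=48)
        expected = np.mean([
            np.mean([
                similarity(chebyshev_distance(vecs[i], vecs[j]), p.n, r)
                for j in range(48) if j != i
            ])
            for i in range(48)
        ])
        assert phi(x, 2, p, r=r, n_vectors=48) == pytest.approx(expected, abs=1e-12)

    def test_too_few_vectors_raises(self):
        with pytest.raises(ValueError):
            phi([1.0, 2.0, 5.0], 3, FuzzyEnParams(m=1))


class TestFuzzyEntropy:
    def test_constant_series_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero SD"):
            assert fuzzy_entropy(np.full(50, 7.0)) == 0.0

    def test_linear_ramp_is_zero(self):
        assert fuzzy_entropy(np.arange(1.0, 11.0)) == pytest.approx(0.0, abs=1e-14)

    def test_shift_invariance(self, rng):
        x = rng.standard_normal(200)
        # offsets up to the hundreds-of-microvolts scale of real baselines;
        # far larger offsets degrade the input samples themselves in float64
        for c in (1.0, -3.7, 250.0):
            assert abs(fuzzy_entropy(x + c) - fuzzy_entropy(x)) < 1e-12

    def test_scale_invariance_normalized_form_only(self, rng):
        x = rng.standard_normal(150)
        p_norm = FuzzyEnParams(similarity_form="normalized")
        base = fuzzy_entropy(x, p_norm)
        for a in (0.1, 10.0, 1000.0):
            assert abs(fuzzy_entropy(a * x, p_norm) - base) < 1e-10
        # the as-printed form scales d^n/r by a^(n-1): not invariant
        p_print = FuzzyEnParams()
        assert abs(fuzzy_entropy(10.0 * x, p_print) - fuzzy_entropy(x, p_print)) > 1e-3

    def test_deterministic(self, rng):
        x = rng.standard_normal(300)
        assert fuzzy_entropy(x) == fuzzy_entropy(x.copy())

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            fuzzy_entropy([1.0, 2.0, 3.0])

    def test_empirical_nonnegativity(self):
        # regression guard: near-zero negatives can only come from rounding
        rng = np.random.default_rng(0)
        vals = [fuzzy_entropy(rng.standard_normal(500)) for _ in range(300)]
        assert min(vals) >= -1e-9

    def test_monotone_in_disorder(self):
        # noisier sinusoids are less regular -> entropy strictly increases
        fs, n = 1000.0, 1000
        t = np.arange(n) / fs
        medians = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            vals = []
            for seed in range(10):
                r = np.random.default_rng(seed)
                x = np.sin(2 * np.pi * 10 * t + r.uniform(0, 2 * np.pi))
                x = x + sigma * r.standard_normal(n)
                vals.append(fuzzy_entropy(x))
            medians.append(np.median(vals))
        assert np.all(np.diff(medians) > 0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("N", [20, 50, 200])
    @pytest.mark.parametrize("form", ["as_printed", "normalized"])
    def test_fast_path_matches_oracle(self, N, form, rng):
        p = FuzzyEnParams(similarity_form=form)
        for _ in range(5):
            x = rng.standard_normal(N)
            assert abs(fuzzy_entropy(x, p) - fuzzy_entropy_oracle(x, p)) < 1e-10

    def test_oracle_constant_is_zero(self):
        with pytest.warns(UserWarning):
            assert fuzzy_entropy_oracle(np.full(20, 1.0)) == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        N=st.sampled_from([20, 50]),
        m=st.integers(1, 4),
    )
    def test_oracle_equivalence_property(self, seed, N, m):
        x = np.random.default_rng(seed).standard_normal(N)
        p = FuzzyEnParams(m=m)
        assert abs(fuzzy_entropy(x, p) - fuzzy_entropy_oracle(x, p)) < 1e-10


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(m=0), dict(n=0), dict(r_factor=-0.1), dict(similarity_form="other")],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FuzzyEnParams(**kwargs)

    def test_defaults(self):
        p = FuzzyEnParams()
        assert (p.m, p.n, p.r_factor, p.similarity_form) == (2, 4.0, 0.2, "as_printed")
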