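"""Approximate entropy and Higuchi fractal dimension against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegpipe.complexity import (
    ApEnParams,
    HiguchiParams,
    apen,
    higuchi_fd,
)
from eegpipe.exceptions import (
    DegenerateInputError,
    NoMatchError,
    ValidationError,
)
from oracles import apen_bruteforce, higuchi_naive

INCLUDE = ApEnParams(self_match="include")
EXCLUDE = ApEnParams(self_match="exclude")


class TestApEn:
    @pytest.mark.parametrize("convention", ["include", "exclude"])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_sequences(self, convention, seed):
        """Optimised template counting equals explicit pair enumeration.

        Equivalence includes error behaviour: when a template has no
        neighbour under the exclude convention, both routes must refuse.
        """
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 201))
        x = rng.standard_normal(n)
        r = float(rng.uniform(0.5, 1.5))
        params = ApEnParams(self_match=convention)
        try:
            expected = apen_bruteforce(x, params.m, r, convention == "exclude")
        except ArithmeticError:
            with pytest.raises(NoMatchError):
                apen(x, params, r_absolute=r)
        else:
            got = apen(x, params, r_absolute=r)
            assert got.value == pytest.approx(expected, abs=1e-12)

    def test_periodic_sequence_exclude_equals_bruteforce(self):
        """The 2,4,6-periodic pattern under the exclude convention."""
        x = np.tile([2.0, 4.0, 6.0], 17)  # N = 51 periodic sequence
        expected = apen_bruteforce(x, 2, 1.0, True)
        got = apen(x, EXCLUDE, r_absolute=1.0)
        assert got.value == pytest.approx(expected, abs=1e-12)
        # perfectly periodic: extending a match never breaks it, so the value
        # is only the O(1/N) denominator imbalance of the exclude convention
        assert abs(got.value) < 0.01

    def test_constant_sequence_include_is_zero(self):
        """Every template matches every other, so both phi terms vanish."""
        x = np.full(100, 3.5)
        result = apen(x, INCLUDE, r_absolute=0.5)
        assert result.value == 0.0
        assert np.all(result.c_m == 1.0)

    def test_constant_sequence_without_tolerance_raises(self):
        with pytest.raises(DegenerateInputError):
            apen(np.zeros(100))

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValidationError):
            apen(np.arange(49.0))

    def test_zero_match_template_raises_with_index(self):
        """Exclude convention on white noise at the default tight tolerance."""
        x = np.random.default_rng(0).standard_normal(400)
        with pytest.raises(NoMatchError) as err:
            apen(x, EXCLUDE)
        assert err.value.template_index >= 0

    @given(seed=st.integers(0, 2**16), scale=st.sampled_from([2.0, 0.5, 3.7, 250.0]))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, seed, scale):
        """r tied to the SD makes ApEn exactly scale-free."""
        x = np.random.default_rng(seed).standard_normal(80)
        assert apen(scale * x, INCLUDE).value == apen(x, INCLUDE).value

    @given(seed=st.integers(0, 2**16), shift=st.sampled_from([1.0, -4.25, 100.0]))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_translation_invariance(self, seed, shift):
        x = np.random.default_rng(seed).standard_normal(80)
        assert apen(x + shift, INCLUDE).value == apen(x, INCLUDE).value

    def test_value_is_phi_difference(self):
        x = np.random.default_rng(5).standard_normal(120)
        res = apen(x, INCLUDE)
        assert res.value == res.phi_m - res.phi_m1
        assert np.all(res.c_m > 0) and np.all(res.c_m <= 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_conventions_differ_by_small_amount(self, seed):
        """Include vs exclude is an O(1/N) effect where both are defined."""
        rng = np.random.default_rng(seed)
        t = np.arange(400) / 200.0
        x = np.sin(2 * np.pi * 10 * t) + 0.01 * rng.standard_normal(400)
        diff = abs(apen(x, INCLUDE).value - apen(x, EXCLUDE).value)
        assert diff < 0.05

    def test_sine_more_regular_than_noise(self):
        """A nearly pure tone scores far below white noise, every seed."""
        t = np.arange(400) / 200.0
        gaps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sine = np.sin(2 * np.pi * 10 * t) + 0.01 * rng.standard_normal(400)
            noise = rng.standard_normal(400)
            gaps.append(apen(noise, INCLUDE).value - apen(sine, INCLUDE).value)
        assert min(gaps) > 0.3


class TestHiguchi:
    def test_linear_ramp_dimension_one(self):
        res = higuchi_fd(np.arange(400.0), HiguchiParams(k_max=8))
        assert res.dimension == pytest.approx(1.0, abs=0.01)
        assert np.all(res.lengths > 0)

    def test_white_noise_dimension_near_two(self):
        dims = [
            higuchi_fd(np.random.default_rng(s).standard_normal(400)).dimension
            for s in range(100)
        ]
        assert 1.9 <= np.mean(dims) <= 2.05

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_transcription(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(int(rng.integers(60, 300)))
        k_max = int(rng.integers(2, 12))
        res = higuchi_fd(x, HiguchiParams(k_max=k_max))
        lengths, slope = higuchi_naive(x, k_max)
        np.testing.assert_allclose(res.lengths, lengths, atol=1e-12)
        assert res.dimension == pytest.approx(slope, abs=1e-12)

    def test_kmax_one_rejected(self):
        with pytest.raises(ValidationError):
            HiguchiParams(k_max=1)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateInputError):
            higuchi_fd(np.ones(100))

    def test_short_input_raises(self):
        with pytest.raises(ValidationError):
            higuchi_fd(np.random.default_rng(0).standard_normal(16), HiguchiParams(k_max=8))
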