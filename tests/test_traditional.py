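"""Comparison metrics: HR, SDNN, spectral band powers, sample and
permutation entropy.  Entropy oracles are naive per-template loops."""

import itertools
import math

import numpy as np
import pytest

from classa.preprocess import UniformHRV, resample_uniform
from classa.traditional import (
    EntropyParams,
    band_powers,
    heart_rate,
    periodogram,
    permutation_entropy,
    sample_entropy,
    sdnn,
    total_power,
)


def oracle_sampen(v, m, r):
    """O(N^2) pure-python template counting (Chebyshev, no self-matches)."""
    n = len(v)

    def count(mm):
        c = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                if max(abs(v[i + k] - v[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def oracle_pe(v, m):
    """Brute-force ordinal pattern tally with stable tie-breaking."""
    tally = {}
    for i in range(len(v) - m + 1):
        w = v[i : i + m]
        pat = tuple(sorted(range(m), key=lambda k: (w[k], k)))
        tally[pat] = tally.get(pat, 0) + 1
    n = sum(tally.values())
    h = -sum(c / n * math.log(c / n) for c in tally.values())
    return h / math.log(math.factorial(m))


class TestTemporal:
    @pytest.mark.parametrize(
        "values,expected",
        [([0.8] * 8, 75.0), ([1.0] * 8, 60.0), ([0.5, 1.0], 90.0)],
    )
    def test_heart_rate_is_mean_instantaneous_rate(self, make_hrv, values, expected):
        assert heart_rate(make_hrv(values)) == pytest.approx(expected)

    def test_heart_rate_rejects_nonpositive(self, make_hrv):
        with pytest.raises(ValueError):
            heart_rate(make_hrv([0.8, 0.0, 0.8]))

    def test_sdnn_closed_form(self, make_hrv):
        assert sdnn(make_hrv([0.8, 0.9, 1.0])) == pytest.approx(100.0)

    def test_sdnn_constant_zero_and_shift_invariant(self, make_hrv, rng):
        assert sdnn(make_hrv([0.8] * 10)) == 0.0
        v = rng.normal(0.8, 0.05, 30)
        assert sdnn(make_hrv(v)) == pytest.approx(sdnn(make_hrv(v + 0.1)))

    def test_order_permutation_invariance(self, rng, make_hrv):
        v = rng.normal(0.8, 0.05, 40)
        p = rng.permutation(v)
        assert heart_rate(make_hrv(v)) == pytest.approx(heart_rate(make_hrv(p)))
        assert sdnn(make_hrv(v)) == pytest.approx(sdnn(make_hrv(p)))


class TestSpectral:
    def _sine(self, freq, amp=0.05, dur=300.0, rate=4.0, rr0=0.8):
        t = np.arange(int(dur * rate)) / rate
        return UniformHRV(rr0 + amp * np.sin(2 * np.pi * freq * t), rate)

    def test_sinusoid_total_power_parseval(self):
        spec = periodogram(self._sine(0.1))
        assert total_power(spec) == pytest.approx(0.05**2 / 2, rel=0.02)

    def test_constant_signal_zero_power(self, make_hrv):
        spec = periodogram(make_hrv([0.8] * 64))
        assert total_power(spec) == pytest.approx(0.0, abs=1e-20)

    def test_white_noise_mean_power_tracks_variance(self, rng):
        # periodogram expectation: integrated power == variance
        tots = []
        for _ in range(100):
            v = rng.normal(0.0, 0.05, 256)
            tots.append(total_power(periodogram(UniformHRV(v, 4.0))))
        assert np.mean(tots) == pytest.approx(0.05**2, rel=0.05)

    def test_lf_sinusoid_lands_in_lf_band(self):
        bp = band_powers(periodogram(self._sine(0.1)))
        assert bp.nLF > 98.0 and bp.nHF < 2.0
        assert bp.aLF == pytest.approx(0.05**2 / 2, rel=0.02)

    def test_hf_sinusoid_lands_in_hf_band(self):
        bp = band_powers(periodogram(self._sine(0.3)))
        assert bp.nHF > 98.0 and bp.nLF < 2.0

    def test_equal_mix_splits_evenly(self):
        t = np.arange(1200) / 4.0
        v = 0.8 + 0.05 * np.sin(2 * np.pi * 0.1 * t) + 0.05 * np.sin(2 * np.pi * 0.3 * t)
        bp = band_powers(periodogram(UniformHRV(v, 4.0)))
        assert bp.nLF == pytest.approx(50.0, abs=2.0)
        assert bp.nHF == pytest.approx(50.0, abs=2.0)

    def test_band_powers_nonnegative_additive(self, rng):
        bp = band_powers(periodogram(UniformHRV(rng.normal(0.8, 0.05, 1200), 4.0)))
        assert bp.aLF >= 0 and bp.aHF >= 0
        assert bp.aLF + bp.aHF <= bp.Np * (1 + 1e-9)
        assert bp.nLF + bp.nHF <= 100.0 + 1e-6


class TestSampleEntropy:
    def test_periodic_sequence_zero(self, make_hrv):
        v = [1.0, 2.0] * 20
        assert sample_entropy(make_hrv(v)) == pytest.approx(0.0)

    def test_constant_flagged_undefined(self, make_hrv):
        with pytest.warns(UserWarning, match="tolerance"):
            assert math.isnan(sample_entropy(make_hrv([0.8] * 30)))

    def test_noise_more_entropic_than_sorted(self, rng, make_hrv):
        v = rng.uniform(0, 1, 200)
        se_noise = sample_entropy(make_hrv(v))
        se_sorted = sample_entropy(make_hrv(np.sort(v)))
        assert se_noise > se_sorted

    def test_matches_bruteforce_oracle(self, rng, make_hrv):
        for n in (60, 150, 300):
            t = np.arange(n) / 4.0
            v = 0.8 + 0.05 * np.sin(2 * np.pi * 0.1 * t) + rng.normal(0, 0.01, n)
            r = 0.15 * float(np.std(v))
            assert sample_entropy(make_hrv(v)) == pytest.approx(
                oracle_sampen(list(v), 2, r), abs=1e-12
            )

    def test_shift_invariance(self, rng, make_hrv):
        v = rng.normal(0.8, 0.05, 120)
        assert sample_entropy(make_hrv(v)) == pytest.approx(
            sample_entropy(make_hrv(v + 1.0))
        )


class TestPermutationEntropy:
    def test_monotone_sequence_zero(self, make_hrv):
        p = EntropyParams(m_pe=4)
        assert permutation_entropy(make_hrv(np.linspace(0, 1, 50)), p) == 0.0

    def test_all_patterns_equal_gives_one(self, make_hrv):
        # six sliding length-3 windows realizing all 3! ordinal patterns once
        v = [0, 1, 5, 4, 3, 7, 2, 6]
        p = EntropyParams(m_pe=3)
        assert permutation_entropy(make_hrv(v), p) == pytest.approx(1.0)

    def test_affine_invariance(self, rng, make_hrv):
        v = rng.normal(0.8, 0.05, 100)
        p = EntropyParams(m_pe=4)
        assert permutation_entropy(make_hrv(v), p) == permutation_entropy(
            make_hrv(2 * v + 5), p
        )

    def test_matches_bruteforce_oracle(self, rng, make_hrv):
        for m in (3, 4, 6):
            v = rng.normal(0.8, 0.05, 200)
            p = EntropyParams(m_pe=m)
            assert permutation_entropy(make_hrv(v), p) == pytest.approx(
                oracle_pe(list(v), m), abs=1e-12
            )

    def test_tie_handling_stable(self, make_hrv):
        # repeated values: stable ranking keeps first occurrence first
        v = [1.0, 1.0, 2.0, 1.0, 1.0, 2.0, 1.0, 1.0]
        p = EntropyParams(m_pe=3)
        assert permutation_entropy(make_hrv(v), p) == pytest.approx(
            oracle_pe(v, 3), abs=1e-12
        )

    def test_undersampled_warns(self, make_hrv, rng):
        with pytest.warns(UserWarning, match="exceeds window length"):
            permutation_entropy(
                make_hrv(rng.normal(0.8, 0.05, 50)), EntropyParams(m_pe=6)
            )
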