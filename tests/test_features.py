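"""Feature families: periodogram, relative power, fuzzy entropy, PLI, table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gadpipe as gp
from gadpipe.features import (
    FuzzyParams,
    Spectrum,
    build_feature_table,
    feature_columns,
    fuzzy_entropy,
    fuzzy_entropy_many,
    hilbert_phase,
    periodogram,
    pli,
    relative_power,
    wrap_phase,
)
from gadpipe.montage import BANDS, CHANNELS


def _tone(freq, fs=100.0, duration=4.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


class TestPeriodogram:
    def test_pure_tone_mass_and_total_power(self):
        spec = periodogram(_tone(10.0), 100.0)
        i = int(np.argmin(np.abs(spec.freqs - 10.0)))
        assert spec.power[i] / spec.power.sum() > 0.999
        assert abs(spec.power.sum() - 0.5) < 0.005

    def test_zero_window(self):
        spec = periodogram(np.zeros(128), 100.0)
        assert np.allclose(spec.power, 0.0)

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(400)
        spec = periodogram(x, 100.0)
        ms = np.mean(x**2)
        assert abs(spec.power.sum() - ms) / ms < 1e-10

    @given(st.integers(min_value=2, max_value=501))
    @settings(max_examples=25, deadline=None)
    def test_parseval_any_length(self, n):
        rng = np.random.default_rng(n)
        x = rng.standard_normal(n)
        spec = periodogram(x, 100.0)
        assert abs(spec.power.sum() - np.mean(x**2)) <= 1e-10 * max(np.mean(x**2), 1)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            periodogram(np.array([]), 100.0)


class TestRelativePower:
    def _flat(self, n=400, fs=100.0):
        f = np.fft.rfftfreq(n, 1 / fs)
        return Spectrum(freqs=f, power=np.ones_like(f), n=n)

    @pytest.mark.parametrize("band", list(BANDS.values()))
    def test_flat_spectrum_identity(self, band):
        assert abs(relative_power(self._flat(), band) - 1.0) < 1e-6

    def test_raw_band_fractions_partition_unity(self):
        spec = periodogram(np.random.default_rng(4).standard_normal(400), 100.0)
        fracs = [
            relative_power(spec, b) * (b[1] - b[0]) / 26.0 for b in BANDS.values()
        ]
        assert abs(sum(fracs) - 1.0) < 1e-6

    def test_tone_in_band(self):
        spec = periodogram(_tone(5.0), 100.0)
        # all spectral mass in theta: value = bandwidth ratio 26/4
        assert abs(relative_power(spec, BANDS["theta"]) - 6.5) < 0.01

    def test_tone_out_of_band(self):
        spec = periodogram(_tone(20.0), 100.0)
        assert relative_power(spec, BANDS["theta"]) < 0.01

    def test_degenerate_window_rejected(self):
        spec = periodogram(np.zeros(400), 100.0)
        with pytest.raises(ValueError):
            relative_power(spec, BANDS["theta"])


def fe_reference(x, m=2, k=0.2):
    """Brute-force double-loop fuzzy entropy, kept independent of the
    vectorised implementation."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sd = (sum((v - mean) ** 2 for v in x) / n) ** 0.5
    if sd == 0:
        return 0.0
    r = k * sd

    def mean_similarity(p):
        n_vec = n - m
        vecs = []
        for i in range(n_vec):
            w = x[i : i + p]
            mu = sum(w) / p
            vecs.append([v - mu for v in w])
        total = 0.0
        for i in range(n_vec):
            s = 0.0
            for j in range(n_vec):
                if j == i:
                    continue
                d = max(abs(a - b) for a, b in zip(vecs[i], vecs[j]))
                s += math.exp(-math.log(2.0) * (d / r) ** 2)
            total += s / (n_vec - 1)
        return total / n_vec

    return math.log(mean_similarity(m)) - math.log(mean_similarity(m + 1))


class TestFuzzyEntropy:
    def test_constant_window_is_zero(self):
        assert fuzzy_entropy(np.full(100, 3.7)) == 0.0

    def test_matches_reference_small(self):
        rng = np.random.default_rng(5)
        for n in (20, 60, 150):
            x = rng.standard_normal(n)
            assert abs(fuzzy_entropy(x) - fe_reference(x)) < 1e-12

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(300)
        assert abs(fuzzy_entropy(x) - fuzzy_entropy(7.3 * x)) < 1e-12

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance_property(self, a):
        x = np.random.default_rng(7).standard_normal(120)
        assert abs(fuzzy_entropy(x) - fuzzy_entropy(a * x)) < 1e-10

    def test_decreases_with_sinusoid_share(self):
        rng = np.random.default_rng(8)
        noise = rng.standard_normal(400)
        tone = _tone(10.0)
        fes = [
            fuzzy_entropy((1 - w) * noise + w * 5 * tone) for w in (0.0, 0.5, 0.9)
        ]
        assert fes[0] > fes[1] > fes[2]

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_entropy(np.array([1.0, 2.0, 3.0]), FuzzyParams(m=2))

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(9)
        w = rng.standard_normal((5, 80))
        batch = fuzzy_entropy_many(w)
        single = [fuzzy_entropy(row) for row in w]
        assert np.allclose(batch, single, atol=0)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            FuzzyParams(m=0)
        with pytest.raises(ValueError):
            FuzzyParams(k=0.0)


class TestHilbertPhase:
    def test_tone_phase_velocity(self):
        fs, f = 100.0, 10.0
        phase = np.unwrap(hilbert_phase(_tone(f, fs=fs)))
        interior = slice(40, -40)
        dphi = np.diff(phase[interior])
        expected = 2 * np.pi * f / fs
        assert np.abs(dphi - expected).max() / expected < 0.01

    def test_cos_sin_quadrature(self):
        fs = 100.0
        t = np.arange(400) / fs
        pc = hilbert_phase(np.cos(2 * np.pi * 10 * t))
        ps = hilbert_phase(np.sin(2 * np.pi * 10 * t))
        d = wrap_phase(pc - ps)[40:-40]
        assert np.allclose(d, np.pi / 2, atol=0.02)

    def test_range_contract(self):
        rng = np.random.default_rng(10)
        ph = hilbert_phase(rng.standard_normal(1000))
        assert np.all(ph > -np.pi) and np.all(ph <= np.pi)

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            hilbert_phase(np.zeros(100))


class TestPli:
    def test_identical_phases_zero(self):
        ph = hilbert_phase(_tone(10.0))
        assert pli(ph, ph.copy()) == 0.0

    def test_constant_lag_one(self):
        ph = hilbert_phase(_tone(10.0))
        assert pli(ph[20:-20], (ph + np.pi / 4)[20:-20]) == 1.0

    def test_random_phases_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(-np.pi, np.pi, 10_000)
        b = rng.uniform(-np.pi, np.pi, 10_000)
        assert pli(a, b) < 0.05

    def test_symmetry_and_amplitude_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        pa, pb = hilbert_phase(x), hilbert_phase(y)
        assert pli(pa, pb) == pytest.approx(pli(pb, pa), abs=0)
        # amplitude scaling leaves analytic phase unchanged
        assert np.allclose(hilbert_phase(4.2 * x), pa)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pli(np.zeros(10), np.zeros(11))


class TestFeatureTable:
    def test_all_families_cardinality(self, tone_epochs):
        table = build_feature_table(tone_epochs)
        assert table.values.shape == (tone_epochs.n_epochs, 608)
        kinds = [c.kind for c in table.columns]
        assert kinds.count("PSD") == 64
        assert kinds.count("FE") == 64
        assert kinds.count("PLI") == 480

    def test_pli_only_cardinality(self, tone_epochs):
        table = build_feature_table(tone_epochs, families=["PLI"])
        assert table.values.shape[1] == 480
        assert np.all(table.values >= 0) and np.all(table.values <= 1)

    def test_identical_epochs_identical_rows(self, tone_epochs):
        from dataclasses import replace

        dup = replace(
            tone_epochs,
            broadband=tone_epochs.broadband[[1, 1]],
            bands={b: a[[1, 1]] for b, a in tone_epochs.bands.items()},
            subject_ids=tone_epochs.subject_ids[:2],
            groups=tone_epochs.groups[:2],
            offsets=tone_epochs.offsets[:2],
        )
        table = build_feature_table(dup)
        assert np.array_equal(table.values[0], table.values[1])

    def test_column_order_deterministic(self):
        cols = feature_columns(CHANNELS)
        assert cols[0].name == "PSD:theta:Fp1"
        assert cols[64].name == "FE:theta:Fp1"
        assert cols[128].name == "PLI:theta:Fp1-Fp2"

    def test_csv_roundtrip(self, tone_epochs, tmp_path):
        table = build_feature_table(tone_epochs, families=["PSD"])
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = gp.FeatureTable.from_csv(path)
        assert np.allclose(back.values, table.values)
        assert [c.name for c in back.columns] == [c.name for c in table.columns]

    def test_unknown_family_rejected(self, tone_epochs):
        with pytest.raises(ValueError):
            build_feature_table(tone_epochs, families=["PSD", "COH"])
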