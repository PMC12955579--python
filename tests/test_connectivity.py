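"""Analytic signal and wPLI: oracles, invariances, contrast recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmodal_eeg.connectivity import (
    AnalyticEpochSet,
    analytic_signal,
    connectivity_contrast,
    connectivity_matrix,
    wpli,
)
from crossmodal_eeg.montage import ChannelLayout

SMALL_LAYOUT = ChannelLayout(
    labels=("Fp1", "Fp2", "C3", "C4", "Cz"),
    pairs=(("Fp1", "Fp2"), ("C3", "C4")),
)


def hilbert_oracle(x):
    """Frequency-domain analytic-signal construction, independent of scipy."""
    n = len(x)
    spec = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.fft.ifft(spec * h)


def wpli_bruteforce(z_i, z_j, sample_slice):
    """Trial-loop evaluation of the stated wPLI definition."""
    vals = []
    for t in range(sample_slice.start, sample_slice.stop):
        num = 0.0
        den = 0.0
        for k in range(z_i.shape[0]):
            im = np.imag(z_i[k, t] * np.conj(z_j[k, t]))
            num += im
            den += abs(im)
        vals.append(abs(num) / den if den > 0 else 0.0)
    return float(np.mean(vals))


def make_analytic(z, layout=SMALL_LAYOUT, sfreq=500.0):
    n = z.shape[0]
    events = pd.DataFrame({"trial_index": np.arange(n), "condition": "A_att"})
    return AnalyticEpochSet(
        data=np.asarray(z, dtype=complex),
        times_ms=np.arange(z.shape[2]) / sfreq * 1000.0,
        events=events,
        layout=layout,
        sfreq=sfreq,
        retained=np.ones(n, dtype=bool),
        edge_mask=np.zeros(z.shape[2], dtype=bool),
    )


class TestAnalyticSignal:
    def test_phase_advances_at_carrier_frequency(self, layout, make_epochs):
        t = np.arange(500) / 500.0
        wave = np.cos(2 * np.pi * 10.0 * t)
        ep = make_epochs(np.tile(wave, (2, 32, 1)), layout)
        an = analytic_signal(ep)
        phase = np.unwrap(np.angle(an.data[0, 0, ~an.edge_mask]))
        freq = np.diff(phase) / (2 * np.pi) * 500.0
        assert np.median(freq) == pytest.approx(10.0, rel=0.01)

    def test_unit_envelope_away_from_edges(self, layout, make_epochs):
        t = np.arange(500) / 500.0
        wave = np.sin(2 * np.pi * 10.0 * t)
        ep = make_epochs(np.tile(wave, (2, 32, 1)), layout)
        an = analytic_signal(ep)
        env = np.abs(an.data[0, 0, 50:450])
        assert np.allclose(env, 1.0, atol=0.05)

    def test_matches_fft_oracle_on_arbitrary_trial(self, layout, make_epochs):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((1, 32, 128))
        ep = make_epochs(data, layout)
        an = analytic_signal(ep)
        x = data[0, 7] - data[0, 7].mean()
        expected = hilbert_oracle(x)
        assert np.allclose(an.data[0, 7], expected, atol=1e-10)
        assert np.allclose(an.data.real, ep.data - ep.data.mean(axis=2, keepdims=True))


class TestWpli:
    def test_zero_lag_gives_zero(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((20, 1, 50)) + 1j * rng.standard_normal((20, 1, 50))
        z = np.concatenate([base] * 5, axis=1)
        an = make_analytic(z)
        assert wpli(an, "C3", "C4", (0.0, 100.0)) == 0.0

    def test_constant_quarter_lag_gives_one(self):
        rng = np.random.default_rng(7)
        phases = rng.uniform(0, 2 * np.pi, size=(20, 1, 50))
        z = np.exp(1j * np.stack([phases[:, 0]] * 5, axis=1))
        z[:, 3] = z[:, 3] * np.exp(1j * np.pi / 2)
        an = make_analytic(z)
        assert wpli(an, "C3", "C4", (0.0, 100.0)) == pytest.approx(1.0)

    def test_hand_computed_imaginary_parts(self):
        """Im X = {+1, +1, -1, +3} at one sample -> |4|/6 = 0.6667."""
        v = np.array([1.0, 1.0, -1.0, 3.0])
        z = np.ones((4, 5, 1), dtype=complex)
        z[:, 3, 0] = -1j * v  # Im(z_i conj z_j) = v with z_i = 1
        an = make_analytic(z)
        assert wpli(an, "C3", "C4", (0.0, 2.0)) == pytest.approx(4.0 / 6.0, abs=1e-12)

    def test_sign_consistent_lags_saturate_regardless_of_magnitude(self):
        rng = np.random.default_rng(8)
        for lag in (0.1, 1.0, np.pi - 0.1):
            phases = rng.uniform(0, 2 * np.pi, size=(15, 50))
            z = np.ones((15, 5, 50), dtype=complex)
            z[:, 2] = np.exp(1j * phases)
            z[:, 3] = np.exp(1j * (phases + lag))
            an = make_analytic(z)
            assert wpli(an, "C3", "C4", (0.0, 100.0)) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equivalence_with_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_trials = int(rng.integers(2, 11))
        z = rng.standard_normal((n_trials, 5, 12)) + 1j * rng.standard_normal(
            (n_trials, 5, 12)
        )
        an = make_analytic(z)
        sl = an.window_slice((0.0, 24.0))
        for i, j in ((2, 3), (0, 4), (1, 2)):
            assert wpli(an, i, j, (0.0, 24.0)) == pytest.approx(
                wpli_bruteforce(z[:, i], z[:, j], sl), abs=1e-12
            )

    def test_invariant_to_positive_amplitude_rescaling(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal((10, 5, 20)) + 1j * rng.standard_normal((10, 5, 20))
        an1 = make_analytic(z)
        z2 = z.copy()
        z2[:, 2] *= 37.5
        an2 = make_analytic(z2)
        assert wpli(an1, 2, 3, (0.0, 40.0)) == pytest.approx(
            wpli(an2, 2, 3, (0.0, 40.0)), abs=1e-12
        )

    def test_requires_two_trials(self):
        z = np.ones((1, 5, 10), dtype=complex)
        with pytest.raises(ValueError, match="at least 2"):
            wpli(make_analytic(z), 0, 1, (0.0, 20.0))


class TestConnectivityMatrix:
    def test_symmetric_zero_diagonal_and_small_under_independence(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal((200, 5, 25)) + 1j * rng.standard_normal((200, 5, 25))
        cm = connectivity_matrix(make_analytic(z), (0.0, 50.0))
        assert cm.values.shape == (3, 3)  # non-EOG channels only
        assert np.allclose(cm.values, cm.values.T)
        assert np.all(np.diag(cm.values) == 0)
        off = cm.values[np.triu_indices(3, k=1)]
        assert np.all(off < 0.2)

    def test_injected_coupling_dominates_its_row(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal((60, 5, 30)) + 1j * rng.standard_normal((60, 5, 30))
        phases = rng.uniform(0, 2 * np.pi, size=(60, 30))
        z[:, 2] += 5 * np.exp(1j * phases)
        z[:, 4] += 5 * np.exp(1j * (phases + np.pi / 4))
        cm = connectivity_matrix(make_analytic(z), (0.0, 60.0))
        i = cm.channels.index("C3")
        j = cm.channels.index("Cz")
        assert cm.values[i, j] > 0.8
        assert cm.values[i, j] == cm.values.max()

    def test_matrix_agrees_with_pairwise_wpli(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal((8, 5, 10)) + 1j * rng.standard_normal((8, 5, 10))
        an = make_analytic(z)
        cm = connectivity_matrix(an, (0.0, 20.0))
        for a in range(3):
            for b in range(a + 1, 3):
                pair = wpli(an, cm.channels[a], cm.channels[b], (0.0, 20.0))
                assert cm.values[a, b] == pytest.approx(pair, abs=1e-12)


class TestContrast:
    def _matrices(self, d_a, d_av, n_subj=8):
        """Per-participant condition matrices with given A/AV attended boosts."""
        rng = np.random.default_rng(13)
        out = []
        for _ in range(n_subj):
            conds = {}
            for label, boost in (
                ("A_att", d_a), ("A_unatt", 0.0), ("AV_att", d_av), ("AV_unatt", 0.0),
            ):
                base = np.abs(rng.normal(0.1, 0.02, size=(3, 3)))
                base = 0.5 * (base + base.T)
                base[0, 1] = base[1, 0] = min(base[0, 1] + boost, 1.0)
                np.fill_diagonal(base, 0.0)
                from crossmodal_eeg.connectivity import ConnectivityMatrix

                conds[label] = ConnectivityMatrix(
                    values=np.clip(base, 0, 1),
                    channels=("C3", "C4", "Cz"),
                    condition=label,
                    participant=0,
                    window_ms=(0.0, 100.0),
                )
            out.append(conds)
        return out

    def test_exact_null_yields_no_significant_pairs(self):
        mats = self._matrices(d_a=0.3, d_av=0.3)
        # identical D_A and D_AV per participant: force equality
        for conds in mats:
            conds["AV_att"] = conds["A_att"]
            conds["AV_unatt"] = conds["A_unatt"]
        table = connectivity_contrast(mats)
        assert not table["significant"].any()
        assert np.allclose(table["t"], 0.0)

    def test_t_statistics_match_paired_oracle(self):
        from scipy import stats as sps

        mats = self._matrices(d_a=0.25, d_av=0.05)
        table = connectivity_contrast(mats)
        d_a = np.array(
            [c["A_att"].upper_triangle() - c["A_unatt"].upper_triangle() for c in mats]
        )
        d_av = np.array(
            [c["AV_att"].upper_triangle() - c["AV_unatt"].upper_triangle() for c in mats]
        )
        t_oracle, p_oracle = sps.ttest_rel(d_a, d_av, axis=0)
        assert np.allclose(table["t"], t_oracle, atol=1e-10)
        assert np.allclose(table["p"], p_oracle, atol=1e-10)


def test_matrix_frame_has_channel_label_axes():
    rng = np.random.default_rng(14)
    z = rng.standard_normal((6, 5, 10)) + 1j * rng.standard_normal((6, 5, 10))
    cm = connectivity_matrix(make_analytic(z), (0.0, 20.0))
    frame = cm.to_frame()
    assert list(frame.index) == list(cm.channels)
    assert frame.loc["C3", "C4"] == cm.values[0, 1]
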