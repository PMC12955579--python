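"""Phenomenological forward model for the synthetic EEG cohort.

Each trial contributes a sum of component templates (scalp gain map x
smooth temporal envelope x signed amplitude), optionally modulated by
modality, attention state and stimulus laterality.  On top of the evoked
components the generator injects amplitude-modulated 10 Hz oscillatory
bursts whose across-trial phase-lag concentration differs by condition
(the substrate of the wPLI contrasts), spatially independent pink + white
background noise, and occasional blink artifacts large enough to trip the
+/-80 uV rejection threshold.  Topographies are gain maps, not lead-field
solutions.

Every template envelope is flat (gain exactly 1) over its nominal
measurement window with raised-cosine ramps outside it, so ROI x window
means recover injected amplitudes exactly in noiseless runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import BehaviorConfig
from .montage import (
    CENTRO_PARIETAL_ROI,
    OCCIPITAL_ROI,
    SN_ROI,
    SN_ROI_RIGHT,
    ChannelLayout,
)
from .preprocess import ContinuousEEG

#: Event marker codes: modality base + side offset (+5 when target).
_MODALITY_CODE = {"V": 10, "A": 20, "AV": 30}
_SIDE_CODE = {"center": 0, "left": 1, "right": 2}


def event_code(modality: str, stimulus_side: str, is_target: bool) -> int:
    return _MODALITY_CODE[modality] + _SIDE_CODE[stimulus_side] + (5 if is_target else 0)


@dataclass(frozen=True)
class ComponentTemplate:
    """One evoked component: gain map, envelope, amplitude, modulators.

    ``topography`` maps channel label -> unitless gain.  For a lateralized
    component the map is written for LEFT-side stimuli and mirrored through
    the homologous pairs for right-side stimuli (so e.g. a gain on P4
    denotes the hemisphere contralateral to the stimulus).  The envelope is
    1 over ``flat_ms`` with raised-cosine ramps out to ``support_ms``.
    Modulators default to 1.
    """

    name: str
    topography: dict[str, float]
    support_ms: tuple[float, float]
    flat_ms: tuple[float, float]
    amplitude_uv: float
    modalities: tuple[str, ...] = ("A", "AV")
    attention_gain: dict[str, float] = field(
        default_factory=lambda: {"attended": 1.0, "unattended": 1.0, "none": 1.0}
    )
    modality_gain: dict[str, float] = field(default_factory=dict)
    lateralized: bool = False

    def __post_init__(self) -> None:
        s0, s1 = self.support_ms
        f0, f1 = self.flat_ms
        if not s0 <= f0 < f1 <= s1:
            raise ValueError(f"{self.name}: flat window must lie inside the support")
        if not all(np.isfinite(list(self.topography.values()))):
            raise ValueError(f"{self.name}: gains must be finite")

    def envelope(self, sfreq: float) -> tuple[np.ndarray, int]:
        """(envelope samples, onset-relative start sample)."""
        s0, s1 = self.support_ms
        f0, f1 = self.flat_ms
        start = int(round(s0 / 1000.0 * sfreq))
        n = int(round((s1 - s0) / 1000.0 * sfreq))
        t = (np.arange(n) + start) / sfreq * 1000.0
        env = np.ones(n)
        rise = t < f0
        if rise.any() and f0 > s0:
            env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - s0) / (f0 - s0)))
        fall = t >= f1
        if fall.any() and s1 > f1:
            env[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - f1) / (s1 - f1)))
        return env, start

    def gain(self, modality: str, attention: str) -> float:
        if modality not in self.modalities:
            return 0.0
        g = self.amplitude_uv * self.attention_gain.get(attention, 1.0)
        return g * self.modality_gain.get(modality, 1.0)


def default_components() -> tuple[ComponentTemplate, ...]:
    """The study-condition component set (amplitudes in uV).

    Injected effects: a -0.7 uV selection-negativity attention effect in
    both A and AV; a -0.5 uV contralateral fronto-central sensory bias in A
    only; a contralateral parietal positivity (ACOP) of 1.2 uV in A and
    0.6 uV in AV; and an attended-only crossmodal spreading negativity of
    -0.8 uV (occipital 300-600 ms, centro-parietal 500-600 ms) carried by
    the AV trials exclusively so that [(AV-A)-V] isolates it.
    """
    fc = {ch: 1.0 for ch in SN_ROI}
    occ = {ch: 1.0 for ch in OCCIPITAL_ROI}
    cp = {ch: 1.0 for ch in CENTRO_PARIETAL_ROI}
    return (
        ComponentTemplate(
            "AEP_N1", fc, (60.0, 180.0), (90.0, 150.0), -2.0, ("A", "AV")
        ),
        ComponentTemplate(
            "AEP_P2", fc, (190.0, 350.0), (220.0, 320.0), 3.0, ("A", "AV")
        ),
        ComponentTemplate(
            "SN",
            fc,
            (210.0, 330.0),
            (220.0, 320.0),
            -0.7,
            ("A", "AV"),
            attention_gain={"attended": 1.0, "unattended": 0.0, "none": 0.0},
        ),
        ComponentTemplate(
            "SN_CONTRA_BIAS",
            {ch: 1.0 for ch in SN_ROI_RIGHT},  # contralateral to a left stimulus
            (210.0, 330.0),
            (220.0, 320.0),
            -0.5,
            ("A",),
            lateralized=True,
        ),
        ComponentTemplate(
            "ACOP",
            {"P4": 1.0, "P8": 1.0},  # contralateral to a left stimulus
            (290.0, 510.0),
            (300.0, 500.0),
            1.2,
            ("A", "AV"),
            modality_gain={"A": 1.0, "AV": 0.5},
            lateralized=True,
        ),
        ComponentTemplate(
            "V_EVOKED", occ, (90.0, 280.0), (120.0, 250.0), 2.5, ("V", "AV")
        ),
        ComponentTemplate(
            "SPREAD_OCC",
            occ,
            (290.0, 610.0),
            (300.0, 600.0),
            -0.8,
            ("AV",),
            attention_gain={"attended": 1.0, "unattended": 0.0, "none": 0.0},
        ),
        ComponentTemplate(
            "SPREAD_CP",
            cp,
            (490.0, 610.0),
            (500.0, 600.0),
            -0.8,
            ("AV",),
            attention_gain={"attended": 1.0, "unattended": 0.0, "none": 0.0},
        ),
    )


@dataclass(frozen=True)
class BlinkConfig:
    """Biphasic blink artifact: one full sine cycle over ``duration_ms``."""

    probability: float = 0.08
    amplitude_uv: float = 120.0
    duration_ms: float = 300.0
    #: scalp spread relative to the EOG channels
    frontal_gains: dict[str, float] = field(
        default_factory=lambda: {
            "Fp1": 1.0, "Fp2": 1.0,
            "F7": 0.35, "F3": 0.35, "Fz": 0.35, "F4": 0.35, "F8": 0.35,
            "FC5": 0.15, "FC1": 0.15, "FC2": 0.15, "FC6": 0.15,
        }
    )


@dataclass(frozen=True)
class CouplingConfig:
    """Phase-coupled oscillatory bursts for the connectivity contrasts.

    Each auditory-bearing trial carries a 10 Hz burst at the seed channel
    (second member of each pair) with a uniformly random base phase; the
    partner channel receives a copy lagged by ``lag_rad`` plus von Mises
    jitter with concentration ``kappa[attention]`` (kappa=0 means a uniform
    lag, i.e. no coupling).  The burst amplitude is scaled per modality.
    """

    freq_hz: float = 10.0
    lag_rad: float = math.pi / 4
    window_ms: tuple[float, float] = (150.0, 450.0)
    amplitude_uv: float = 12.0
    modality_gain: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "AV": 0.5}
    )
    kappa: dict[str, float] = field(
        default_factory=lambda: {"attended": 20.0, "unattended": 0.0}
    )
    pairs: tuple[tuple[str, str], ...] = (("FC1", "T8"), ("Cz", "T8"))

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.kappa.values()):
            raise ValueError("phase concentration must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one synthetic participant recording."""

    sampling_rate_hz: float = 500.0
    pink_noise_uv: float = 10.0
    white_noise_uv: float = 2.0
    components: tuple[ComponentTemplate, ...] = field(default_factory=default_components)
    blink: BlinkConfig = field(default_factory=BlinkConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    #: SD of the multiplicative per-participant random effect on amplitudes
    subject_sd: float = 0.1

    def null_effects(self) -> "SimulationConfig":
        """Copy with every attention-dependent term switched off.

        Attention gains become equal across states (the attended-only
        components keep their 'off' state everywhere), and the coupling
        concentration is equalized, so every attended-vs-unattended
        contrast has expectation zero.
        """
        comps = []
        for c in self.components:
            g = c.attention_gain
            if g["attended"] != g["unattended"]:
                comps.append(
                    replace(c, attention_gain={k: 0.0 for k in g})
                )
            else:
                comps.append(c)
        kap = self.coupling.kappa
        coupling = replace(
            self.coupling,
            kappa={k: min(kap.values()) for k in kap},
        )
        return replace(self, components=tuple(comps), coupling=coupling)


def pink_noise(n_channels: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise, independent across channels."""
    from scipy import fft as sfft

    n_fast = sfft.next_fast_len(n_samples, real=True)
    white = rng.standard_normal((n_channels, n_fast))
    spec = sfft.rfft(white, axis=-1)
    freqs = sfft.rfftfreq(n_fast)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    out = sfft.irfft(spec, n=n_fast, axis=-1)[:, :n_samples]
    out /= out.std(axis=-1, keepdims=True)
    return out


def _mirrored_topography(topo: dict[str, float], layout: ChannelLayout) -> dict[str, float]:
    mirrored: dict[str, float] = {}
    for ch, g in topo.items():
        mirrored[layout.mirror(ch)] = mirrored.get(layout.mirror(ch), 0.0) + g
    return mirrored


def simulate_recording(
    design: pd.DataFrame,
    layout: ChannelLayout,
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
) -> tuple[ContinuousEEG, dict]:
    """Render the continuous recording for one participant.

    Returns the recording plus a ground-truth dictionary with the blink
    trial indices, the per-participant amplitude random effects and the
    per-trial burst phase lags (for oracle tests).
    """
    fs = config.sampling_rate_hz
    rng = np.random.default_rng(seed)
    n_ch = layout.n_channels
    n_samples = int(math.ceil((design["onset_s"].max() + 1.5) * fs))

    data = np.zeros((n_ch, n_samples))
    if config.pink_noise_uv > 0:
        data += config.pink_noise_uv * pink_noise(n_ch, n_samples, rng)
    if config.white_noise_uv > 0:
        data += config.white_noise_uv * rng.standard_normal((n_ch, n_samples))

    # Per-participant multiplicative random effect per component.
    subject_gain = {
        c.name: 1.0 + config.subject_sd * rng.standard_normal()
        for c in config.components
    }

    # Precompute envelopes and channel-index/gain vectors per component.
    prepared = []
    for comp in config.components:
        env, start = comp.envelope(fs)
        topo_left = comp.topography
        topo_right = (
            _mirrored_topography(comp.topography, layout) if comp.lateralized else comp.topography
        )
        prepared.append(
            (
                comp,
                env,
                start,
                {
                    side: (
                        np.array(layout.indices(list(topo.keys()))),
                        np.array(list(topo.values())),
                    )
                    for side, topo in (("left", topo_left), ("right", topo_right))
                },
            )
        )

    onset_samples = np.round(design["onset_s"].to_numpy() * fs).astype(int)
    attention = np.where(
        design["stimulus_side"].to_numpy() == "center",
        "none",
        np.where(
            design["stimulus_side"].to_numpy() == design["attended_side"].to_numpy(),
            "attended",
            "unattended",
        ),
    )

    for comp, env, start, topos in prepared:
        for i, row in enumerate(design.itertuples(index=False)):
            amp = comp.gain(row.modality, attention[i])
            if amp == 0.0:
                continue
            side = "right" if (comp.lateralized and row.stimulus_side == "right") else "left"
            idx, gains = topos[side]
            s0 = onset_samples[i] + start
            data[idx, s0 : s0 + env.size] += (
                amp * subject_gain[comp.name] * gains[:, None] * env[None, :]
            )

    # Oscillatory coupling bursts.
    cp = config.coupling
    lag_truth = []
    if cp.amplitude_uv > 0 and cp.pairs:
        env_c0 = int(round(cp.window_ms[0] / 1000.0 * fs))
        n_env = int(round((cp.window_ms[1] - cp.window_ms[0]) / 1000.0 * fs))
        t_env = np.arange(n_env) / fs
        burst_env = np.hanning(n_env)
        seeds = {s for _, s in cp.pairs}
        for i, row in enumerate(design.itertuples(index=False)):
            if row.modality not in ("A", "AV") or attention[i] == "none":
                continue
            a = cp.amplitude_uv * cp.modality_gain.get(row.modality, 1.0)
            if a == 0.0:
                continue
            kappa = cp.kappa.get(attention[i], 0.0)
            phi = rng.uniform(0.0, 2 * math.pi)
            s0 = onset_samples[i] + env_c0
            carrier = 2 * math.pi * cp.freq_hz * t_env
            for seed_ch in seeds:
                data[layout.index(seed_ch), s0 : s0 + n_env] += (
                    a * burst_env * np.cos(carrier + phi)
                )
            # One lag draw per trial, shared by all partner channels: the
            # partners are then mutually zero-lag, so no spurious coupling
            # arises between them (only partner-seed pairs are coupled).
            if kappa > 0:
                lag = rng.vonmises(cp.lag_rad, kappa)
            else:
                lag = rng.uniform(-math.pi, math.pi)
            for partner, seed_ch in cp.pairs:
                lag_truth.append((int(row.trial_index), partner, seed_ch, lag))
                data[layout.index(partner), s0 : s0 + n_env] += (
                    a * burst_env * np.cos(carrier + phi + lag)
                )

    # Blink artifacts.
    bl = config.blink
    blink_trials = []
    if bl.probability > 0 and bl.amplitude_uv != 0:
        n_blink = int(round(bl.duration_ms / 1000.0 * fs))
        blink_wave = np.sin(2 * np.pi * np.arange(n_blink) / n_blink)
        gains_idx = np.array(layout.indices(list(bl.frontal_gains.keys())))
        gains = np.array(list(bl.frontal_gains.values()))
        for i, onset in enumerate(onset_samples):
            if rng.uniform() < bl.probability:
                blink_trials.append(int(design["trial_index"].iloc[i]))
                s0 = onset + int(round(rng.uniform(0.0, 0.4) * fs))
                data[gains_idx, s0 : s0 + n_blink] += (
                    bl.amplitude_uv * gains[:, None] * blink_wave[None, :]
                )

    events = pd.DataFrame(
        {
            "sample": onset_samples,
            "code": [
                event_code(r.modality, r.stimulus_side, r.is_target)
                for r in design.itertuples(index=False)
            ],
            "trial_index": design["trial_index"].to_numpy(),
        }
    )
    rec = ContinuousEEG(data=data, sfreq=fs, layout=layout, events=events)
    truth = {
        "blink_trials": blink_trials,
        "subject_gain": subject_gain,
        "phase_lags": pd.DataFrame(
            lag_truth, columns=["trial_index", "channel", "seed_channel", "lag_rad"]
        ),
    }
    return rec, truth
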