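"""Condition-averaged waveforms and component measures: SN, ACOP, spreading.

All measures are ROI x time-window means of condition-averaged waveforms
(linear in the data), with half-open [start, end) windows so that
consecutive 100-ms windows tile without double counting.

Lateralized components are isolated by contralateral/ipsilateral
collapsing: lateral electrodes are relabelled relative to stimulus side and
averaged across left/right stimuli and homologous electrode pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import (
    ACOP_PAIRS,
    CENTRO_PARIETAL_ROI,
    OCCIPITAL_ROI,
    SN_ROI_LEFT,
    SN_ROI_RIGHT,
)
from .preprocess import EpochSet

SPREADING_WINDOWS_MS = tuple((w, w + 100.0) for w in (200.0, 300.0, 400.0, 500.0, 600.0))
ACOP_WINDOWS_MS = ((300.0, 400.0), (400.0, 500.0), (300.0, 500.0))


@dataclass
class Evoked:
    """Per-condition average waveform (channels x time, uV)."""

    data: np.ndarray
    times_ms: np.ndarray
    n_trials: int
    condition: dict
    layout: object
    sfreq: float

    def window_slice(self, window_ms: tuple[float, float]) -> slice:
        start_ms, end_ms = window_ms
        t0 = self.times_ms[0]
        i0 = int(round((start_ms - t0) / 1000.0 * self.sfreq))
        i1 = int(round((end_ms - t0) / 1000.0 * self.sfreq))
        if i0 < 0 or i1 > self.data.shape[1] or i0 >= i1:
            raise ValueError(f"window {window_ms} outside the epoch")
        return slice(i0, i1)

    def roi_window_mean(self, roi, window_ms) -> float:
        """Time-and-channel mean amplitude over an ROI and window."""
        idx = self.layout.indices(roi)
        return float(self.data[idx, self.window_slice(window_ms)].mean())


def average_evoked(
    ep: EpochSet, extra_mask: np.ndarray | None = None, **criteria
) -> Evoked:
    """Pointwise mean over retained trials matching the given event criteria.

    ``criteria`` are equality filters on columns of ``ep.events`` (e.g.
    ``modality="A", attention="attended", is_target=False``).  An optional
    boolean ``extra_mask`` (e.g. correct-response compatibility) is ANDed in.
    """
    mask = ep.retained.copy()
    if extra_mask is not None:
        mask &= np.asarray(extra_mask, dtype=bool)
    for col, val in criteria.items():
        mask &= (ep.events[col] == val).to_numpy()
    if not mask.any():
        raise ValueError(f"no retained trials in cell {criteria}")
    return Evoked(
        data=ep.data[mask].mean(axis=0),
        times_ms=ep.times_ms,
        n_trials=int(mask.sum()),
        condition=dict(criteria),
        layout=ep.layout,
        sfreq=ep.sfreq,
    )


def to_long_frame(
    evokeds: dict[str, Evoked], participant: str | int = ""
) -> pd.DataFrame:
    """Long-format export of (difference) waveforms.

    One row per condition x channel x time sample with columns
    (participant, condition, channel, time_ms, amplitude_uv).
    """
    frames = []
    for condition, ev in evokeds.items():
        n_ch, n_t = ev.data.shape
        frames.append(
            pd.DataFrame(
                {
                    "participant": participant,
                    "condition": condition,
                    "channel": np.repeat(list(ev.layout.labels), n_t),
                    "time_ms": np.tile(ev.times_ms, n_ch),
                    "amplitude_uv": ev.data.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def measure_sn(
    evokeds: dict[tuple[str, str], Evoked],
    window_ms: tuple[float, float] = (220.0, 320.0),
) -> pd.DataFrame:
    """Selection-negativity cell means for one modality.

    ``evokeds`` is keyed by (attention_side, stimulus_side) over
    left/right x left/right; each cell is summarized by its mean amplitude
    over the left (FC1/FC5/F3/C3) and right (FC2/FC6/F4/C4) fronto-central
    hemisphere ROIs in the given window (default 220-320 ms).
    """
    rows = []
    for att in ("left", "right"):
        for stim in ("left", "right"):
            if (att, stim) not in evokeds:
                raise ValueError(f"missing SN cell (attention={att}, stimulus={stim})")
            ev = evokeds[(att, stim)]
            for hemi, roi in (("left", SN_ROI_LEFT), ("right", SN_ROI_RIGHT)):
                rows.append(
                    {
                        "attention_side": att,
                        "stimulus_side": stim,
                        "hemisphere": hemi,
                        "amplitude_uv": ev.roi_window_mean(roi, window_ms),
                        "n_trials": ev.n_trials,
                    }
                )
    return pd.DataFrame(rows)


def sn_attention_effect(cells: pd.DataFrame) -> float:
    """Attended-minus-unattended mean amplitude from an SN cell table."""
    att = cells["attention_side"] == cells["stimulus_side"]
    return float(
        cells.loc[att, "amplitude_uv"].mean() - cells.loc[~att, "amplitude_uv"].mean()
    )


@dataclass
class LateralizedEvoked:
    """Waveforms relabelled contralateral/ipsilateral to the stimulus."""

    contralateral: np.ndarray  # 1-D time course, uV
    ipsilateral: np.ndarray
    times_ms: np.ndarray
    sfreq: float
    derivation: str

    def window_slice(self, window_ms: tuple[float, float]) -> slice:
        start_ms, end_ms = window_ms
        t0 = self.times_ms[0]
        i0 = int(round((start_ms - t0) / 1000.0 * self.sfreq))
        i1 = int(round((end_ms - t0) / 1000.0 * self.sfreq))
        if i0 < 0 or i1 > self.contralateral.size or i0 >= i1:
            raise ValueError(f"window {window_ms} outside the epoch")
        return slice(i0, i1)


def collapse_laterality(
    evokeds_by_side: dict[str, Evoked],
    pairs: tuple[tuple[str, str], ...] = ACOP_PAIRS,
) -> LateralizedEvoked:
    """Collapse across stimulus side and electrode side.

    Contralateral = mean of {right electrode | left stimuli} and
    {left electrode | right stimuli}, over all pairs; ipsilateral is the
    complement.  Both averages span the same number of
    (stimulus side x electrode pair) cells.
    """
    for side in ("left", "right"):
        if side not in evokeds_by_side:
            raise ValueError(f"missing {side}-stimulus evoked for laterality collapsing")
    ev_l, ev_r = evokeds_by_side["left"], evokeds_by_side["right"]
    if not np.array_equal(ev_l.times_ms, ev_r.times_ms):
        raise ValueError("left/right evokeds have mismatched time axes")
    layout = ev_l.layout
    contra, ipsi = [], []
    for left_el, right_el in pairs:
        contra.append(ev_l.data[layout.index(right_el)])
        contra.append(ev_r.data[layout.index(left_el)])
        ipsi.append(ev_l.data[layout.index(left_el)])
        ipsi.append(ev_r.data[layout.index(right_el)])
    return LateralizedEvoked(
        contralateral=np.mean(contra, axis=0),
        ipsilateral=np.mean(ipsi, axis=0),
        times_ms=ev_l.times_ms,
        sfreq=ev_l.sfreq,
        derivation=f"pairs={pairs}, collapsed over stimulus side",
    )


def measure_acop(
    lat: LateralizedEvoked,
    windows_ms: tuple[tuple[float, float], ...] = ACOP_WINDOWS_MS,
) -> pd.DataFrame:
    """Contralateral/ipsilateral means and their difference per window."""
    rows = []
    for win in windows_ms:
        sl = lat.window_slice(win)
        c = float(lat.contralateral[sl].mean())
        i = float(lat.ipsilateral[sl].mean())
        rows.append(
            {
                "window_start_ms": win[0],
                "window_end_ms": win[1],
                "contralateral_uv": c,
                "ipsilateral_uv": i,
                "difference_uv": c - i,
            }
        )
    return pd.DataFrame(rows)


def spreading_measure(
    evokeds: dict[str, Evoked],
    rois: dict[str, tuple[str, ...]] | None = None,
    windows_ms: tuple[tuple[float, float], ...] = SPREADING_WINDOWS_MS,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Crossmodal spreading difference waves [(AV - A) - V] per attention state.

    ``evokeds`` must contain 'AV_att', 'A_att', 'AV_unatt', 'A_unatt' and a
    single attention-unspecific 'V'.  Returns the full difference waveforms
    (channels x time) and the ROI x window mean table (default: occipital
    and centro-parietal ROIs in five 100-ms windows, 200-700 ms).
    """
    required = ("AV_att", "A_att", "AV_unatt", "A_unatt", "V")
    for key in required:
        if key not in evokeds:
            raise ValueError(f"missing evoked {key!r} for the spreading measure")
    times = evokeds["V"].times_ms
    for key in required:
        if not np.array_equal(evokeds[key].times_ms, times):
            raise ValueError("evokeds have mismatched time axes")
    if rois is None:
        rois = {"centro_parietal": CENTRO_PARIETAL_ROI, "occipital": OCCIPITAL_ROI}

    waves = {
        "attended": evokeds["AV_att"].data - evokeds["A_att"].data - evokeds["V"].data,
        "unattended": evokeds["AV_unatt"].data - evokeds["A_unatt"].data - evokeds["V"].data,
    }
    ref = evokeds["V"]
    rows = []
    for attention, wave in waves.items():
        for roi_name, roi in rois.items():
            idx = ref.layout.indices(roi)
            for win in windows_ms:
                sl = ref.window_slice(win)
                rows.append(
                    {
                        "attention": attention,
                        "roi": roi_name,
                        "window_start_ms": win[0],
                        "window_end_ms": win[1],
                        "amplitude_uv": float(wave[idx, sl].mean()),
                    }
                )
    return waves, pd.DataFrame(rows)
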