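"""Trial-locked time-domain wPLI connectivity and condition contrasts.

The weighted phase lag index is computed across trials at each time sample
from the analytic (Hilbert) signal: with cross-terms
``X_k(t) = z_i,k(t) * conj(z_j,k(t))`` over trials k,

    wpli(t) = | sum_k Im X_k(t) |  /  sum_k | Im X_k(t) |

(defined as 0 when the denominator vanishes), then averaged over the
analysis window.  Because only the imaginary part of the cross-term enters,
zero-lag (volume-conduction) coupling does not contribute, and the measure
is invariant to positive amplitude rescaling of either channel.  The
broadband 0.1-30 Hz signal is used as-is; this is deliberately a
time-domain, stimulus-locked measure, not a band-specific spectral one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .inference import bh_fdr
from .preprocess import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class AnalyticEpochSet:
    """Complex analytic signal per trial/channel; real part is the input."""

    data: np.ndarray  # complex, trials x channels x time
    times_ms: np.ndarray
    events: pd.DataFrame
    layout: object
    sfreq: float
    retained: np.ndarray
    edge_mask: np.ndarray  # True where edge-affected

    def window_slice(self, window_ms: tuple[float, float]) -> slice:
        start_ms, end_ms = window_ms
        t0 = self.times_ms[0]
        i0 = int(round((start_ms - t0) / 1000.0 * self.sfreq))
        i1 = int(round((end_ms - t0) / 1000.0 * self.sfreq))
        if i0 < 0 or i1 > self.data.shape[2] or i0 >= i1:
            raise ValueError(f"window {window_ms} outside the epoch")
        return slice(i0, i1)


def analytic_signal(
    ep: EpochSet, edge_ms: float = 50.0, min_cycles_hz: float = 10.0
) -> AnalyticEpochSet:
    """Hilbert analytic signal per trial and channel (no padding).

    The per-trial, per-channel mean is removed before the transform.
    Samples within ``edge_ms`` of either epoch edge are flagged as
    edge-affected.  A warning is logged if the epoch is shorter than three
    cycles of ``min_cycles_hz``.
    """
    n_t = ep.data.shape[2]
    if n_t / ep.sfreq < 3.0 / min_cycles_hz:
        logger.warning(
            "epoch of %.0f ms is shorter than 3 cycles at %.1f Hz",
            1000.0 * n_t / ep.sfreq,
            min_cycles_hz,
        )
    demeaned = ep.data - ep.data.mean(axis=2, keepdims=True)
    z = hilbert(demeaned, axis=2)
    n_edge = int(round(edge_ms / 1000.0 * ep.sfreq))
    edge = np.zeros(n_t, dtype=bool)
    if n_edge > 0:
        edge[:n_edge] = True
        edge[-n_edge:] = True
    return AnalyticEpochSet(
        data=z,
        times_ms=ep.times_ms,
        events=ep.events,
        layout=ep.layout,
        sfreq=ep.sfreq,
        retained=ep.retained.copy(),
        edge_mask=edge,
    )


_DEN_RTOL = 1e-12  # relative floor below which the denominator counts as zero


def _wpli_timecourse(zi: np.ndarray, zj: np.ndarray) -> np.ndarray:
    """wpli(t) across trials for one channel pair (trials x time inputs).

    The denominator is compared against a relative floor (1e-12 of the
    summed cross-term magnitude) so that numerically zero imaginary parts
    (e.g. identical signals) yield wpli = 0, per the zero-denominator
    convention.
    """
    prod = zi * np.conj(zj)
    im = prod.imag
    num = np.abs(im.sum(axis=0))
    den = np.abs(im).sum(axis=0)
    floor = _DEN_RTOL * np.abs(prod).sum(axis=0)
    out = np.zeros_like(num)
    nz = den > floor
    out[nz] = num[nz] / den[nz]
    return out


def wpli(
    an: AnalyticEpochSet,
    ch_i: str | int,
    ch_j: str | int,
    window_ms: tuple[float, float],
    trial_mask: np.ndarray | None = None,
) -> float:
    """Window-mean across-trial wPLI between two channels, in [0, 1]."""
    i = an.layout.index(ch_i) if isinstance(ch_i, str) else ch_i
    j = an.layout.index(ch_j) if isinstance(ch_j, str) else ch_j
    mask = an.retained.copy()
    if trial_mask is not None:
        mask &= np.asarray(trial_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("wPLI requires at least 2 retained trials")
    sl = an.window_slice(window_ms)
    tc = _wpli_timecourse(an.data[mask, i, sl], an.data[mask, j, sl])
    return float(tc.mean())


@dataclass
class ConnectivityMatrix:
    """Symmetric non-EOG channel x channel wPLI matrix, zero diagonal."""

    values: np.ndarray
    channels: tuple[str, ...]
    condition: str
    participant: str | int
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.channels),) * 2:
            raise ValueError("matrix shape must match the channel list")
        if not np.allclose(v, v.T):
            raise ValueError("wPLI matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("wPLI values must lie in [0, 1]")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.channels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        """Square matrix as a DataFrame with channel-label axes (TSV-ready)."""
        return pd.DataFrame(
            self.values, index=list(self.channels), columns=list(self.channels)
        )


def pair_labels(channels: tuple[str, ...]) -> list[tuple[str, str]]:
    iu = np.triu_indices(len(channels), k=1)
    return [(channels[a], channels[b]) for a, b in zip(*iu)]


def connectivity_matrix(
    an: AnalyticEpochSet,
    window_ms: tuple[float, float],
    trial_mask: np.ndarray | None = None,
    condition: str = "",
    participant: str | int = "",
) -> ConnectivityMatrix:
    """wPLI over all unordered non-EOG channel pairs (diagonal 0)."""
    channels = an.layout.non_eog_labels
    idx = an.layout.indices(channels)
    mask = an.retained.copy()
    if trial_mask is not None:
        mask &= np.asarray(trial_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("wPLI requires at least 2 retained trials")
    sl = an.window_slice(window_ms)
    z = an.data[np.ix_(np.flatnonzero(mask), idx)][:, :, sl]  # K x C x T
    # Cross-terms for all pairs at once; K*C*C*T stays modest for the
    # condition-wise trial counts used here.
    prod = z[:, :, None, :] * np.conj(z[:, None, :, :])
    im = prod.imag
    num = np.abs(im.sum(axis=0))
    den = np.abs(im).sum(axis=0)
    floor = _DEN_RTOL * np.abs(prod).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(den > floor, num / np.where(den > 0, den, 1.0), 0.0)
    values = tc.mean(axis=-1)
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        values=values,
        channels=channels,
        condition=condition,
        participant=participant,
        window_ms=window_ms,
    )


CONTRAST_CONDITIONS = ("A_att", "A_unatt", "AV_att", "AV_unatt")


def connectivity_contrast(
    matrices: list[dict[str, ConnectivityMatrix]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired test of attention contrasts (A vs AV) per channel pair.

    For each participant, D_A = wPLI(A attended) - wPLI(A unattended) and
    D_AV likewise; D_A vs D_AV is compared per pair with a paired t-test
    across participants and BH-FDR corrected over all pairs.  Participants
    missing a condition are dropped (logged).
    """
    d_a, d_av = [], []
    channels = None
    for k, conds in enumerate(matrices):
        if any(c not in conds for c in CONTRAST_CONDITIONS):
            logger.warning("participant %d dropped: missing conditions", k)
            continue
        if channels is None:
            channels = conds["A_att"].channels
        d_a.append(
            conds["A_att"].upper_triangle() - conds["A_unatt"].upper_triangle()
        )
        d_av.append(
            conds["AV_att"].upper_triangle() - conds["AV_unatt"].upper_triangle()
        )
    if len(d_a) < 2:
        raise ValueError("need at least 2 complete participants for the contrast")
    diff = np.asarray(d_a) - np.asarray(d_av)  # subjects x pairs
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    t[~nz & (mean > 0)] = np.inf
    t[~nz & (mean < 0)] = -np.inf
    from scipy import stats

    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p_fdr = bh_fdr(p)
    pairs = pair_labels(channels)
    return pd.DataFrame(
        {
            "channel_i": [a for a, _ in pairs],
            "channel_j": [b for _, b in pairs],
            "mean_contrast": mean,
            "t": t,
            "df": n - 1,
            "p": p,
            "p_fdr": p_fdr,
            "significant": p_fdr < alpha,
        }
    )
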