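"""Shared test helpers: tiny layouts, analytic-set builders, wPLI oracle."""

import numpy as np
import pandas as pd

from crossmodal_eeg.connectivity import AnalyticEpochSet
from crossmodal_eeg.montage import ChannelLayout

TINY_LAYOUT = ChannelLayout(
    labels=("Fp1", "Fp2", "C3", "C4", "Cz"),
    pairs=(("Fp1", "Fp2"), ("C3", "C4")),
)


def make_analytic_set(z, layout=TINY_LAYOUT, sfreq=500.0) -> AnalyticEpochSet:
    n = z.shape[0]
    return AnalyticEpochSet(
        data=np.asarray(z, dtype=complex),
        times_ms=np.arange(z.shape[2]) / sfreq * 1000.0,
        events=pd.DataFrame({"trial_index": np.arange(n), "condition": "A_att"}),
        layout=layout,
        sfreq=sfreq,
        retained=np.ones(n, dtype=bool),
        edge_mask=np.zeros(z.shape[2], dtype=bool),
    )


def wpli_bruteforce(z_i, z_j, sample_slice) -> float:
    """Direct trial-loop evaluation of the wPLI definition."""
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
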