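"""File I/O: BrainVision triplets, EDF, design TSVs, HDF5 epoch containers.

Continuous synthetic recordings are written as a BrainVision triplet
(.vhdr/.eeg/.vmrk; multiplexed little-endian 32-bit float, microvolts) with
stimulus markers encoding the trial codes, plus a JSON sidecar with the full
simulation configuration.  Reading goes through MNE, which also serves as a
round-trip check of the writer.  Epoch sets are stored as HDF5 containers
(data + JSON-encoded event table + rejection log).
"""

from __future__ import annotations

import dataclasses
import json
from io import StringIO
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import ChannelLayout
from .preprocess import ContinuousEEG, EpochSet

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by crossmodal_eeg

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us:.0f}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Each entry: Ch<n>=<Name>,<Reference>,<Resolution in "Unit">,<Unit>
{channel_lines}
"""


def write_brainvision(rec: ContinuousEEG, basepath: str | Path) -> Path:
    """Write a BrainVision triplet; returns the .vhdr path."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    channel_lines = "\n".join(
        f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(rec.layout.labels)
    )
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem,
        n_channels=rec.layout.n_channels,
        sampling_interval_us=1e6 / rec.sfreq,
        channel_lines=channel_lines,
    )
    (base.with_suffix(".vhdr")).write_text(vhdr, encoding="utf-8")

    lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "; Each entry: Mk<n>=<Type>,<Description>,<Position in data points>,",
        "; <Size in data points>, <Channel number (0 = marker is related to all channels)>",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    for k, row in enumerate(rec.events.itertuples(index=False), start=2):
        lines.append(f"Mk{k}=Stimulus,S{row.code:>3d},{row.sample + 1},1,0")
    (base.with_suffix(".vmrk")).write_text("\n".join(lines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(base.with_suffix(".eeg"))
    return base.with_suffix(".vhdr")


def _events_from_mne(raw, sfreq: float) -> pd.DataFrame:
    import mne

    events, event_id = mne.events_from_annotations(raw, verbose="error")
    rows = []
    code_by_id = {}
    for desc, ev_id in event_id.items():
        token = desc.split("/")[-1].replace("Stimulus", "").replace("S", "").strip()
        try:
            code_by_id[ev_id] = int(token)
        except ValueError:
            continue  # non-stimulus annotation (e.g. new segment)
    for sample, _, ev_id in events:
        if ev_id in code_by_id:
            rows.append((int(sample), code_by_id[ev_id]))
    df = pd.DataFrame(rows, columns=["sample", "code"]).sort_values("sample")
    df["trial_index"] = np.arange(len(df))
    return df.reset_index(drop=True)


def read_brainvision(vhdr_path: str | Path, layout: ChannelLayout | None = None) -> ContinuousEEG:
    """Read a BrainVision recording into a :class:`ContinuousEEG` (uV)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    return _raw_to_continuous(raw, layout)


def read_edf(edf_path: str | Path, layout: ChannelLayout | None = None) -> ContinuousEEG:
    """Read an EDF recording into a :class:`ContinuousEEG` (uV)."""
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    return _raw_to_continuous(raw, layout)


def _raw_to_continuous(raw, layout: ChannelLayout | None) -> ContinuousEEG:
    if layout is None:
        layout = ChannelLayout(labels=tuple(raw.ch_names))
    data_uv = raw.get_data(picks=list(layout.labels)) * 1e6
    events = _events_from_mne(raw, raw.info["sfreq"])
    return ContinuousEEG(
        data=data_uv, sfreq=float(raw.info["sfreq"]), layout=layout, events=events
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if not f.name.startswith("_")
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_config_json(config, path: str | Path) -> None:
    """JSON sidecar with the full (nested dataclass) configuration."""
    Path(path).write_text(
        json.dumps(_jsonable(config), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_target"] = df["is_target"].astype(bool)
    return df


def save_epochs(ep: EpochSet, path: str | Path) -> None:
    """Store an epoch set (data, events, rejection log) as HDF5."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=ep.data, compression="gzip", compression_opts=1)
        h5.create_dataset("times_ms", data=ep.times_ms)
        h5.create_dataset("rejected", data=ep.rejected)
        h5.create_dataset(
            "reject_reason",
            data=np.array([s.encode() for s in ep.reject_reason]),
        )
        h5.attrs["sfreq"] = ep.sfreq
        h5.attrs["labels"] = json.dumps(list(ep.layout.labels))
        h5.attrs["eog"] = json.dumps(list(ep.layout.eog))
        h5.attrs["events"] = ep.events.to_json(orient="split")


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as h5:
        layout = ChannelLayout(
            labels=tuple(json.loads(h5.attrs["labels"])),
            eog=tuple(json.loads(h5.attrs["eog"])),
        )
        events = pd.read_json(StringIO(h5.attrs["events"]), orient="split")
        return EpochSet(
            data=h5["data"][()],
            times_ms=h5["times_ms"][()],
            events=events,
            layout=layout,
            sfreq=float(h5.attrs["sfreq"]),
            rejected=h5["rejected"][()].astype(bool),
            reject_reason=np.array(
                [b.decode() for b in h5["reject_reason"][()]], dtype=object
            ),
        )
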