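"""32-channel 10-20 montage bookkeeping: hemispheres, homologous pairs, ROIs.

The recording layout is a standard 32-electrode cap referenced to the left
earlobe; Fp1/Fp2 double as the EOG derivation.  All region-of-interest
definitions used by the component analyses live here so that every analysis
module draws channel subsets from a single source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Default 32-channel labels (10-20 system).
DEFAULT_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CPz", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "POz", "PO8",
    "O1", "Oz", "O2",
)

#: Homologous left/right electrode pairs (left, right).
HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"),
    ("FC5", "FC6"), ("FC1", "FC2"),
    ("T7", "T8"), ("C3", "C4"),
    ("CP5", "CP6"), ("CP1", "CP2"),
    ("P7", "P8"), ("P3", "P4"),
    ("PO7", "PO8"), ("O1", "O2"),
)

# ROIs used by the component analyses.
SN_ROI = ("FC1", "FC2", "FC5", "FC6", "F3", "F4", "C3", "C4")
SN_ROI_LEFT = ("FC1", "FC5", "F3", "C3")
SN_ROI_RIGHT = ("FC2", "FC6", "F4", "C4")
ACOP_PAIRS = (("P3", "P4"), ("P7", "P8"))
CENTRO_PARIETAL_ROI = ("Pz", "P3", "P4", "CP1", "CP2")
OCCIPITAL_ROI = ("PO7", "PO8", "Oz", "O1", "O2")


@dataclass(frozen=True)
class ChannelLayout:
    """Channel labels with hemisphere assignment and EOG flags."""

    labels: tuple[str, ...] = DEFAULT_LABELS
    eog: tuple[str, ...] = ("Fp1", "Fp2")
    pairs: tuple[tuple[str, str], ...] = HOMOLOGOUS_PAIRS
    reference: str = "left earlobe"
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if len(self.eog) != 2:
            raise ValueError("exactly two EOG-flagged channels are expected")
        missing = [c for c in self.eog if c not in self.labels]
        if missing:
            raise ValueError(f"EOG channels {missing} not in layout")
        for left, right in self.pairs:
            if left not in self.labels or right not in self.labels:
                raise ValueError(f"pair ({left},{right}) not in layout")
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"channel {label!r} not in layout") from None

    def indices(self, labels) -> list[int]:
        return [self.index(lab) for lab in labels]

    def hemisphere(self, label: str) -> str:
        """Return 'left', 'right' or 'midline' for a channel."""
        for l, r in self.pairs:
            if label == l:
                return "left"
            if label == r:
                return "right"
        return "midline"

    def mirror(self, label: str) -> str:
        """Homologous channel in the opposite hemisphere (midline maps to itself)."""
        for l, r in self.pairs:
            if label == l:
                return r
            if label == r:
                return l
        return label

    @property
    def non_eog_labels(self) -> tuple[str, ...]:
        return tuple(lab for lab in self.labels if lab not in self.eog)

    def is_eog(self, label: str) -> bool:
        return label in self.eog
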