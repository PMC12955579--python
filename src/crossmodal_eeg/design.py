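"""Experimental design generation and behavioral simulation/scoring.

The task is an auditory spatial attention experiment: participants attend to
sounds on one side (constant within a block) and press a key for occasional
auditory targets on that side.  Stimuli are visual-only (V, central),
auditory-only (A, lateralized) or synchronous audiovisual (AV, lateralized
sound + central visual).  The design generator reproduces the protocol's
counts exactly by counting, not sampling: 12 blocks, 16% V / 42% A / 42% AV,
10% targets, targets only on auditory-bearing trials at the attended side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_BLOCKS = 12
MODALITY_PROPORTIONS = {"V": 0.16, "A": 0.42, "AV": 0.42}
TARGET_PROPORTION = 0.10
STIMULUS_DURATION_S = 0.100
ITI_RANGE_S = (0.950, 1.050)

DESIGN_COLUMNS = [
    "trial_index", "block", "attended_side", "modality",
    "stimulus_side", "is_target", "onset_s",
]


def _alternating_split(total_per_block: int, n_blocks: int) -> list[int]:
    """Per-block 'left' (or 'A') counts whose sum is exactly half the total.

    When the per-block count is odd the remainder alternates between blocks
    so the design-level split is exact.
    """
    base, rem = divmod(total_per_block, 2)
    return [base + (rem if b % 2 == 0 else 0) for b in range(n_blocks)]


def generate_design(n_trials_per_block: int = 100, seed: int = 0) -> pd.DataFrame:
    """Generate the full trial table for one participant.

    Allocation is exact: modality counts, target counts and left/right
    balance are computed by counting, then the order is shuffled within each
    block.  Onsets accumulate stimulus duration plus a uniform inter-trial
    interval.

    Raises
    ------
    ValueError
        If ``n_trials_per_block`` does not yield integer allocations for the
        16/42/42% modality split and the 10% target rate.
    """
    n = n_trials_per_block
    counts = {}
    for mod, prop in MODALITY_PROPORTIONS.items():
        c = prop * n
        if abs(c - round(c)) > 1e-9:
            raise ValueError(
                f"n_trials_per_block={n} gives a non-integer count "
                f"({c:.2f}) for modality {mod} at {prop:.0%}; use a "
                "multiple of 50"
            )
        counts[mod] = round(c)
    t = TARGET_PROPORTION * n
    if abs(t - round(t)) > 1e-9:
        raise ValueError(
            f"n_trials_per_block={n} gives a non-integer target count "
            f"({t:.2f}) at {TARGET_PROPORTION:.0%}; use a multiple of 50"
        )
    n_targets_block = round(t)
    if n_targets_block > counts["A"] // 2 + counts["AV"] // 2:
        raise ValueError("more targets than attended-side auditory trials")

    rng = np.random.default_rng(seed)

    # Half the blocks attend left, half right, in seeded random order.
    sides = np.array(["left"] * (N_BLOCKS // 2) + ["right"] * (N_BLOCKS // 2))
    rng.shuffle(sides)

    # Design-level-exact odd splits alternate across blocks.
    left_counts = {m: _alternating_split(counts[m], N_BLOCKS) for m in ("A", "AV")}
    target_a_counts = _alternating_split(n_targets_block, N_BLOCKS)

    rows: list[tuple] = []
    onset = 1.0
    idx = 0
    for b in range(N_BLOCKS):
        attended = sides[b]
        block_rows: list[list] = []
        block_rows.extend(
            ["V", "center", False] for _ in range(counts["V"])
        )
        for mod in ("A", "AV"):
            n_left = left_counts[mod][b]
            n_tgt = target_a_counts[b] if mod == "A" else n_targets_block - target_a_counts[b]
            lateral = ["left"] * n_left + ["right"] * (counts[mod] - n_left)
            # Targets occupy the first attended-side slots; the subsequent
            # shuffle randomizes their serial position.
            n_assigned = 0
            for side in lateral:
                is_tgt = side == attended and n_assigned < n_tgt
                if is_tgt:
                    n_assigned += 1
                block_rows.append([mod, side, is_tgt])
            if n_assigned < n_tgt:
                raise ValueError(
                    f"block {b + 1}: cannot place {n_tgt} targets on "
                    f"{mod} attended-side trials"
                )
        order = rng.permutation(len(block_rows))
        for k in order:
            mod, side, is_tgt = block_rows[k]
            rows.append((idx, b + 1, attended, mod, side, is_tgt, onset))
            idx += 1
            onset += STIMULUS_DURATION_S + rng.uniform(*ITI_RANGE_S)
        onset += 2.0  # inter-block pause

    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    design["is_target"] = design["is_target"].astype(bool)
    return design


def validate_design(design: pd.DataFrame) -> None:
    """Assert every design invariant; raise ``ValueError`` on violation."""
    n = len(design)
    if design["block"].nunique() != N_BLOCKS:
        raise ValueError("design must contain exactly 12 blocks")
    by_block = design.groupby("block")["attended_side"].nunique()
    if (by_block != 1).any():
        raise ValueError("attended side must be constant within a block")
    block_sides = design.groupby("block")["attended_side"].first()
    if (block_sides == "left").sum() != N_BLOCKS // 2:
        raise ValueError("half of the blocks must be left-attended")
    for mod, prop in MODALITY_PROPORTIONS.items():
        if (design["modality"] == mod).sum() != round(prop * n):
            raise ValueError(f"modality {mod} count violates the {prop:.0%} split")
    if design["is_target"].sum() != round(TARGET_PROPORTION * n):
        raise ValueError("target count violates the 10% rate")
    tgt = design[design["is_target"]]
    if (tgt["modality"] == "V").any():
        raise ValueError("targets must be auditory-bearing (A or AV)")
    if (tgt["stimulus_side"] != tgt["attended_side"]).any():
        raise ValueError("targets must occur at the attended side")
    if (design.loc[design["modality"] == "V", "stimulus_side"] != "center").any():
        raise ValueError("V trials must be central")
    for mod in ("A", "AV"):
        sides = design.loc[design["modality"] == mod, "stimulus_side"]
        if (sides == "left").sum() != (sides == "right").sum():
            raise ValueError(f"{mod} trials must be left/right balanced")
    d = design["onset_s"].diff().dropna()
    lo = STIMULUS_DURATION_S + ITI_RANGE_S[0] - 1e-9
    if (d < lo).any():
        raise ValueError("onsets violate the minimum inter-trial interval")


@dataclass(frozen=True)
class BehaviorConfig:
    """Response model for target detection.

    RTs are drawn from a shifted gamma (positively skewed); the defaults put
    the mean at ``shift + shape*scale`` = 520 ms.  ``lapse`` is the miss
    probability on attended targets, ``fa_rate`` the false-alarm probability
    on any non-target trial.
    """

    lapse: float = 0.02
    fa_rate: float = 0.01
    rt_shift_ms: float = 300.0
    rt_shape: float = 4.0
    rt_scale_ms: float = 55.0

    def __post_init__(self) -> None:
        for name in ("lapse", "fa_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


def simulate_behavior(
    design: pd.DataFrame,
    config: BehaviorConfig = BehaviorConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate key presses: hits on attended targets, sparse false alarms.

    The random stream is consumed strictly in trial order (one response draw
    per trial, one RT draw per emitted response), so a fixed seed fully
    determines the record.
    """
    rng = np.random.default_rng(seed)
    responded = np.zeros(len(design), dtype=bool)
    rt_ms = np.full(len(design), np.nan)
    for i, row in enumerate(design.itertuples(index=False)):
        if row.is_target:
            if rng.uniform() >= config.lapse:
                responded[i] = True
                rt_ms[i] = config.rt_shift_ms + rng.gamma(
                    config.rt_shape, config.rt_scale_ms
                ) if config.rt_scale_ms > 0 else config.rt_shift_ms
        else:
            if rng.uniform() < config.fa_rate:
                responded[i] = True
                rt_ms[i] = rng.uniform(150.0, 900.0)
    return pd.DataFrame(
        {
            "trial_index": design["trial_index"].to_numpy(),
            "is_target": design["is_target"].to_numpy(),
            "responded": responded,
            "rt_ms": rt_ms,
        }
    )


def score_behavior(
    behavior: pd.DataFrame,
    design: pd.DataFrame,
    window_ms: tuple[float, float] = (100.0, 1000.0),
) -> pd.DataFrame:
    """Accuracy (%) and mean RT (ms) per target modality (A vs AV).

    Responses outside ``window_ms`` count as misses; RT averages in-window
    hits only.  A modality without targets is reported as missing (NaN).
    """
    merged = design.merge(
        behavior[["trial_index", "responded", "rt_ms"]], on="trial_index"
    )
    lo, hi = window_ms
    out = []
    for mod in ("A", "AV"):
        tgt = merged[(merged["modality"] == mod) & merged["is_target"]]
        n = len(tgt)
        if n == 0:
            out.append((mod, np.nan, np.nan, 0))
            continue
        in_win = tgt["responded"] & tgt["rt_ms"].between(lo, hi)
        acc = 100.0 * in_win.sum() / n
        rt = tgt.loc[in_win, "rt_ms"].mean() if in_win.any() else np.nan
        out.append((mod, acc, rt, n))
    scores = pd.DataFrame(out, columns=["modality", "acc_pct", "mean_rt_ms", "n_targets"])
    return scores.set_index("modality")


def false_alarm_rate(behavior: pd.DataFrame) -> float:
    """Fraction of non-target trials with a response."""
    nt = behavior[~behavior["is_target"]]
    return float(nt["responded"].mean()) if len(nt) else np.nan
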