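"""Cohort orchestration: simulate -> preprocess -> components -> stats.

A run is a pure function of a :class:`RunConfig`: per participant the
design is generated, the continuous recording simulated, filtered, epoched
and cleaned, condition-averaged measures extracted, and wPLI matrices
computed; group-level inference then assembles the cohort report
(behavioral tests, SN ANOVAs, ACOP ANOVAs, spreading window tests,
connectivity contrast, and the per-condition valid-epoch accounting).
Two runs with the same configuration produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .connectivity import (
    analytic_signal,
    connectivity_contrast,
    connectivity_matrix,
)
from .design import (
    false_alarm_rate,
    generate_design,
    score_behavior,
    simulate_behavior,
)
from .evoked import (
    average_evoked,
    collapse_laterality,
    measure_acop,
    measure_sn,
    sn_attention_effect,
    spreading_measure,
)
from .inference import (
    StatResult,
    apply_fdr,
    paired_t,
    results_table,
    rm_anova,
)
from .montage import ChannelLayout
from .preprocess import bandpass_filter, epoch, reject_artifacts, retained_counts
from .simulate import SimulationConfig, simulate_recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible cohort run depends on."""

    seed: int = 0
    n_participants: int = 25
    n_trials_per_block: int = 100
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    filter_hp_hz: float = 0.1
    filter_lp_hz: float = 30.0
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    reject_threshold_uv: float = 80.0
    sn_window_ms: tuple[float, float] = (220.0, 320.0)
    connectivity_window_ms: tuple[float, float] = (220.0, 320.0)
    run_connectivity: bool = True
    alpha: float = 0.05

    def hash(self) -> str:
        payload = json.dumps(cio._jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def make_fixtures(scale: str = "tiny") -> RunConfig:
    """Preset cohort configurations.

    ``"paper"`` is the full study geometry (25 participants, 12 blocks of
    100 trials).  ``"tiny"`` keeps the design invariants at the smallest
    block size with integer allocation (12 blocks of 50) and 3 participants,
    for fast end-to-end checks.
    """
    if scale == "tiny":
        return RunConfig(n_participants=3, n_trials_per_block=50)
    if scale == "paper":
        return RunConfig(n_participants=25, n_trials_per_block=100)
    raise ValueError(f"unknown fixture scale {scale!r}")


def participant_seeds(config: RunConfig) -> list[dict[str, int]]:
    """Derive independent (design, simulation, behavior) seeds per participant."""
    ss = np.random.SeedSequence(config.seed)
    out = []
    for child in ss.spawn(config.n_participants):
        d, s, b = (int(x) for x in child.generate_state(3, dtype=np.uint32))
        out.append({"design": d, "sim": s, "behavior": b})
    return out


@dataclass
class ParticipantResult:
    """All per-participant quantities entering group-level inference."""

    participant: int
    behavior_scores: pd.DataFrame
    fa_rate: float
    sn_cells: pd.DataFrame          # modality x attention_side x stimulus_side x hemisphere
    acop_cells: pd.DataFrame        # modality x attention x window contra/ipsi
    spreading_cells: pd.DataFrame   # attention x roi x window
    counts: pd.DataFrame
    connectivity: dict | None = None


def analyze_participant(
    ep,
    behavior: pd.DataFrame,
    config: RunConfig,
    participant: int,
) -> ParticipantResult:
    """Component measures and connectivity for one cleaned epoch set.

    Trials with incorrect responses (false alarms on non-targets) are
    excluded from averaging; target trials are scored behaviorally only.
    """
    ev = ep.events
    beh = ev[["trial_index"]].merge(behavior, on="trial_index", validate="1:1")
    correct = ~(beh["responded"].to_numpy() & ~beh["is_target"].to_numpy())

    # SN cells per modality.
    sn_frames = []
    for modality in ("A", "AV"):
        cells = {}
        for att in ("left", "right"):
            for stim in ("left", "right"):
                cells[(att, stim)] = average_evoked(
                    ep,
                    extra_mask=correct,
                    modality=modality,
                    attended_side=att,
                    stimulus_side=stim,
                    is_target=False,
                )
        tbl = measure_sn(cells, window_ms=config.sn_window_ms)
        tbl.insert(0, "modality", modality)
        sn_frames.append(tbl)
    sn_cells = pd.concat(sn_frames, ignore_index=True)

    # ACOP: contra/ipsi collapsing per modality x attention.
    acop_rows = []
    lateral_evokeds = {}
    for modality in ("A", "AV"):
        for attention in ("attended", "unattended"):
            by_side = {
                side: average_evoked(
                    ep,
                    extra_mask=correct,
                    modality=modality,
                    attention=attention,
                    stimulus_side=side,
                    is_target=False,
                )
                for side in ("left", "right")
            }
            lat = collapse_laterality(by_side)
            lateral_evokeds[(modality, attention)] = lat
            tbl = measure_acop(lat)
            tbl.insert(0, "attention", attention)
            tbl.insert(0, "modality", modality)
            acop_rows.append(tbl)
    acop_cells = pd.concat(acop_rows, ignore_index=True)

    # Crossmodal spreading.
    spread_evokeds = {
        "V": average_evoked(ep, extra_mask=correct, modality="V", is_target=False)
    }
    for modality in ("A", "AV"):
        for attention, key in (("attended", "att"), ("unattended", "unatt")):
            spread_evokeds[f"{modality}_{key}"] = average_evoked(
                ep,
                extra_mask=correct,
                modality=modality,
                attention=attention,
                is_target=False,
            )
    _, spreading_cells = spreading_measure(spread_evokeds)

    connectivity = None
    if config.run_connectivity:
        an = analytic_signal(ep)
        connectivity = {}
        cond = ep.events["condition"].to_numpy()
        for label in ("A_att", "A_unatt", "AV_att", "AV_unatt"):
            connectivity[label] = connectivity_matrix(
                an,
                window_ms=config.connectivity_window_ms,
                trial_mask=(cond == label) & correct,
                condition=label,
                participant=participant,
            )

    design_cols = ev[
        ["trial_index", "block", "attended_side", "modality",
         "stimulus_side", "is_target", "onset_s"]
    ]
    scores = score_behavior(behavior, design_cols)
    return ParticipantResult(
        participant=participant,
        behavior_scores=scores,
        fa_rate=false_alarm_rate(behavior),
        sn_cells=sn_cells,
        acop_cells=acop_cells,
        spreading_cells=spreading_cells,
        counts=retained_counts(ep),
        connectivity=connectivity,
    )


def run_participant(
    config: RunConfig, participant: int, seeds: dict[str, int]
) -> ParticipantResult:
    layout = ChannelLayout()
    design = generate_design(config.n_trials_per_block, seed=seeds["design"])
    rec, _ = simulate_recording(design, layout, config.sim, seed=seeds["sim"])
    behavior = simulate_behavior(design, config.sim.behavior, seed=seeds["behavior"])
    rec = bandpass_filter(rec, config.filter_hp_hz, config.filter_lp_hz)
    ep = epoch(rec, design, config.epoch_window_ms, config.baseline_ms)
    ep = reject_artifacts(ep, config.reject_threshold_uv)
    return analyze_participant(ep, behavior, config, participant)


# ---------------------------------------------------------------------------
# group level


def _mean_ci(values: np.ndarray) -> dict[str, float]:
    from scipy import stats

    v = np.asarray(values, dtype=float)
    n = v.size
    m = v.mean()
    se = v.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
    half = stats.t.ppf(0.975, n - 1) * se if n > 1 else np.nan
    return {"mean": float(m), "se": float(se), "ci_lo": float(m - half), "ci_hi": float(m + half), "n": n}


def _behavior_tests(results: list[ParticipantResult]) -> pd.DataFrame:
    rows = []
    acc = {m: [] for m in ("A", "AV")}
    rt = {m: [] for m in ("A", "AV")}
    for r in results:
        for m in ("A", "AV"):
            acc[m].append(r.behavior_scores.loc[m, "acc_pct"])
            rt[m].append(r.behavior_scores.loc[m, "mean_rt_ms"])
    for name, d in (("ACC_pct", acc), ("RT_ms", rt)):
        res = paired_t(np.asarray(d["A"]), np.asarray(d["AV"]))
        rows.append(
            {
                "measure": name,
                "M_A": np.mean(d["A"]), "SE_A": np.std(d["A"], ddof=1) / np.sqrt(len(d["A"])),
                "M_AV": np.mean(d["AV"]), "SE_AV": np.std(d["AV"], ddof=1) / np.sqrt(len(d["AV"])),
                "t": res.statistic, "df": res.df, "p": res.p, "cohen_d": res.effect_size,
            }
        )
    return pd.DataFrame(rows)


def _sn_group(results: list[ParticipantResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    cells = pd.concat(
        [r.sn_cells.assign(participant=r.participant) for r in results],
        ignore_index=True,
    )
    tables = []
    for modality in ("A", "AV"):
        tbl = cells[cells["modality"] == modality].rename(
            columns={"amplitude_uv": "value"}
        )
        res = rm_anova(
            tbl, dv="value", within=["attention_side", "stimulus_side", "hemisphere"]
        )
        apply_fdr(res)  # family: the 7 terms of this analysis
        out = results_table(res)
        out.insert(0, "modality", modality)
        tables.append(out)
    effects = []
    for r in results:
        for modality in ("A", "AV"):
            effects.append(
                {
                    "participant": r.participant,
                    "modality": modality,
                    "attention_effect_uv": sn_attention_effect(
                        r.sn_cells[r.sn_cells["modality"] == modality]
                    ),
                }
            )
    return pd.concat(tables, ignore_index=True), pd.DataFrame(effects)


def _acop_group(
    results: list[ParticipantResult],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    cells = pd.concat(
        [r.acop_cells.assign(participant=r.participant) for r in results],
        ignore_index=True,
    )
    # 3-way ANOVA per analysis window; one FDR family over both windows.
    all_res: list[StatResult] = []
    window_of: list[tuple[float, float]] = []
    for win in ((300.0, 400.0), (400.0, 500.0)):
        sub = cells[
            (cells["window_start_ms"] == win[0]) & (cells["window_end_ms"] == win[1])
        ]
        long = sub.melt(
            id_vars=["participant", "modality", "attention"],
            value_vars=["contralateral_uv", "ipsilateral_uv"],
            var_name="hemisphere",
            value_name="value",
        )
        long["hemisphere"] = long["hemisphere"].str.replace("_uv", "", regex=False)
        res = rm_anova(long, dv="value", within=["modality", "attention", "hemisphere"])
        all_res.extend(res)
        window_of.extend([win] * len(res))
    apply_fdr(all_res)
    anova3 = results_table(all_res)
    anova3.insert(0, "window_ms", [f"{int(a)}-{int(b)}" for a, b in window_of])

    # 2-way ANOVA on the contralateral-ipsilateral difference, 300-500 ms.
    sub = cells[(cells["window_start_ms"] == 300.0) & (cells["window_end_ms"] == 500.0)]
    long = sub.rename(columns={"difference_uv": "value"})[
        ["participant", "modality", "attention", "value"]
    ]
    res2 = apply_fdr(rm_anova(long, dv="value", within=["modality", "attention"]))
    anova2 = results_table(res2)
    anova2.insert(0, "window_ms", "300-500")

    diffs = sub.rename(columns={"difference_uv": "acop_uv"})[
        ["participant", "modality", "attention", "acop_uv"]
    ]
    return anova3, anova2, diffs


def _spreading_group(results: list[ParticipantResult]) -> pd.DataFrame:
    cells = pd.concat(
        [r.spreading_cells.assign(participant=r.participant) for r in results],
        ignore_index=True,
    )
    rows = []
    stats_res = []
    for roi in ("centro_parietal", "occipital"):
        for win_start in (200.0, 300.0, 400.0, 500.0, 600.0):
            sub = cells[
                (cells["roi"] == roi) & (cells["window_start_ms"] == win_start)
            ].pivot(index="participant", columns="attention", values="amplitude_uv")
            res = paired_t(sub["attended"].to_numpy(), sub["unattended"].to_numpy())
            stats_res.append(res)
            rows.append(
                {
                    "roi": roi,
                    "window_ms": f"{int(win_start)}-{int(win_start + 100)}",
                    "M_attended": sub["attended"].mean(),
                    "M_unattended": sub["unattended"].mean(),
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p,
                    "cohen_d": res.effect_size,
                }
            )
    # One FDR family across both ROIs x five windows.
    apply_fdr(stats_res)
    out = pd.DataFrame(rows)
    out["p_fdr"] = [r.p_fdr for r in stats_res]
    return out


def _accounting(results: list[ParticipantResult]) -> pd.DataFrame:
    counts = pd.concat(
        [r.counts.assign(participant=r.participant) for r in results],
        ignore_index=True,
    )
    g = counts.groupby("condition", sort=False)
    out = g.agg(
        designed_mean=("designed", "mean"),
        retained_mean=("retained", "mean"),
        retained_se=("retained", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
        rejected_mean=("rejected", "mean"),
    ).reset_index()
    return out


@dataclass
class CohortReport:
    """Group-level tables plus a scalar summary; regenerable from config."""

    config_hash: str
    behavior: pd.DataFrame
    behavior_tests: pd.DataFrame
    sn_anova: pd.DataFrame
    sn_effects: pd.DataFrame
    acop_anova3: pd.DataFrame
    acop_anova2: pd.DataFrame
    acop_diffs: pd.DataFrame
    spreading_tests: pd.DataFrame
    epoch_accounting: pd.DataFrame
    connectivity: pd.DataFrame | None
    summary: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "behavior": self.behavior,
            "behavior_tests": self.behavior_tests,
            "sn_anova": self.sn_anova,
            "sn_effects": self.sn_effects,
            "acop_anova_3way": self.acop_anova3,
            "acop_anova_2way": self.acop_anova2,
            "acop_differences": self.acop_diffs,
            "spreading_tests": self.spreading_tests,
            "epoch_accounting": self.epoch_accounting,
        }
        if self.connectivity is not None:
            out["connectivity_contrast"] = self.connectivity
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            path = outdir / f"{name}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(f"# config_hash={self.config_hash}\n")
                df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        (outdir / "report.json").write_text(
            json.dumps(
                {"config_hash": self.config_hash, **self.summary},
                indent=2,
                sort_keys=True,
                allow_nan=True,
            )
            + "\n",
            encoding="utf-8",
        )


def group_report(results: list[ParticipantResult], config: RunConfig) -> CohortReport:
    behavior = pd.concat(
        [
            r.behavior_scores.reset_index().assign(participant=r.participant)
            for r in results
        ],
        ignore_index=True,
    )
    behavior_tests = _behavior_tests(results)
    sn_anova, sn_effects = _sn_group(results)
    acop3, acop2, acop_diffs = _acop_group(results)
    spreading = _spreading_group(results)
    accounting = _accounting(results)

    conn = None
    if all(r.connectivity is not None for r in results):
        conn = connectivity_contrast([r.connectivity for r in results])

    summary: dict = {"n_participants": len(results)}
    for m in ("A", "AV"):
        summary[f"acc_pct_{m}"] = _mean_ci(
            behavior.loc[behavior["modality"] == m, "acc_pct"].to_numpy()
        )
        summary[f"rt_ms_{m}"] = _mean_ci(
            behavior.loc[behavior["modality"] == m, "mean_rt_ms"].to_numpy()
        )
        summary[f"sn_attention_effect_uv_{m}"] = _mean_ci(
            sn_effects.loc[sn_effects["modality"] == m, "attention_effect_uv"].to_numpy()
        )
        d = acop_diffs[acop_diffs["modality"] == m]
        summary[f"acop_diff_uv_{m}"] = _mean_ci(
            d.groupby("participant")["acop_uv"].mean().to_numpy()
        )
    spread_eff = []
    for r in results:
        c = r.spreading_cells
        occ = c[(c["roi"] == "occipital") & c["window_start_ms"].isin([300.0, 400.0, 500.0])]
        piv = occ.groupby("attention")["amplitude_uv"].mean()
        spread_eff.append(piv["attended"] - piv["unattended"])
    summary["spreading_effect_uv_occipital_300_600"] = _mean_ci(np.asarray(spread_eff))
    if conn is not None:
        sig = conn[conn["significant"]]
        summary["connectivity_significant_pairs"] = [
            f"{a}-{b}" for a, b in zip(sig["channel_i"], sig["channel_j"])
        ]
    return CohortReport(
        config_hash=config.hash(),
        behavior=behavior,
        behavior_tests=behavior_tests,
        sn_anova=sn_anova,
        sn_effects=sn_effects,
        acop_anova3=acop3,
        acop_anova2=acop2,
        acop_diffs=acop_diffs,
        spreading_tests=spreading,
        epoch_accounting=accounting,
        connectivity=conn,
        summary=summary,
    )


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> CohortReport:
    """Execute the full cohort pipeline; optionally write the report."""
    results = []
    for pid, seeds in enumerate(participant_seeds(config)):
        t0 = time.perf_counter()
        results.append(run_participant(config, pid, seeds))
        logger.info("participant %d analyzed in %.1f s", pid, time.perf_counter() - t0)
    report = group_report(results, config)
    if outdir is not None:
        report.write(outdir)
    return report


# ---------------------------------------------------------------------------
# staged (on-disk) execution used by the CLI


def simulate_to_dir(config: RunConfig, outdir: str | Path) -> list[Path]:
    """Write per-participant BrainVision + design/behavior TSVs + sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = ChannelLayout()
    cio.write_config_json(config, outdir / "run_config.json")
    pdirs = []
    for pid, seeds in enumerate(participant_seeds(config)):
        pdir = outdir / f"sub-{pid:02d}"
        pdir.mkdir(exist_ok=True)
        design = generate_design(config.n_trials_per_block, seed=seeds["design"])
        rec, _ = simulate_recording(design, layout, config.sim, seed=seeds["sim"])
        behavior = simulate_behavior(design, config.sim.behavior, seed=seeds["behavior"])
        cio.write_brainvision(rec, pdir / f"sub-{pid:02d}_eeg")
        cio.write_design_tsv(design, pdir / "design.tsv")
        behavior.to_csv(pdir / "behavior.tsv", sep="\t", index=False, float_format="%.6f")
        pdirs.append(pdir)
    return pdirs


def preprocess_dir(datadir: str | Path, config: RunConfig) -> list[Path]:
    """Filter/epoch/reject every stored participant; write HDF5 + report."""
    datadir = Path(datadir)
    out = []
    for pdir in sorted(datadir.glob("sub-*")):
        vhdr = next(pdir.glob("*_eeg.vhdr"))
        rec = cio.read_brainvision(vhdr)
        design = cio.read_design_tsv(pdir / "design.tsv")
        rec = bandpass_filter(rec, config.filter_hp_hz, config.filter_lp_hz)
        ep = epoch(rec, design, config.epoch_window_ms, config.baseline_ms)
        ep = reject_artifacts(ep, config.reject_threshold_uv)
        cio.save_epochs(ep, pdir / "epochs.h5")
        retained_counts(ep).to_csv(
            pdir / "rejection_report.tsv", sep="\t", index=False
        )
        out.append(pdir / "epochs.h5")
    return out


def analyze_dir(datadir: str | Path, config: RunConfig) -> CohortReport:
    """Run components + connectivity + stats from stored intermediates."""
    datadir = Path(datadir)
    results = []
    for pid, pdir in enumerate(sorted(datadir.glob("sub-*"))):
        ep = cio.load_epochs(pdir / "epochs.h5")
        behavior = pd.read_csv(pdir / "behavior.tsv", sep="\t")
        results.append(analyze_participant(ep, behavior, config, pid))
    report = group_report(results, config)
    report.write(datadir / "group")
    return report
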