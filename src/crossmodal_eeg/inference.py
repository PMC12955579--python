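"""Within-subject statistics: rm-ANOVA, simple effects, paired t, FDR, power.

The repeated-measures ANOVA engine delegates to statsmodels' ``AnovaRM``
for factorial designs and to pingouin's ``rm_anova`` for a single factor
(which supplies the Greenhouse-Geisser correction when a factor has more
than two levels).  Partial eta squared for a term with (df1, df2) is
recovered from F as ``F*df1 / (F*df1 + df2)``, which equals
SS_effect / (SS_effect + SS_error).

All tests are two-tailed at alpha = 0.05 unless stated otherwise.  FDR
families are configured by the caller (the component ANOVA terms, the
spreading windows, or the full set of channel pairs); corrected values are
attached with :func:`apply_fdr`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass
class StatResult:
    """One tested effect (F or t), with raw and FDR-adjusted p."""

    effect: str
    statistic_kind: str  # "F" or "t"
    statistic: float
    df: tuple[float, float] | float
    p: float
    p_fdr: float = np.nan
    effect_size: float = np.nan  # eta_p^2 for F, Cohen's d for t
    cells: pd.DataFrame | None = field(default=None, repr=False)


def cell_summary(
    table: pd.DataFrame, dv: str = "value", factors: list[str] | None = None
) -> pd.DataFrame:
    """M and SE per condition cell (across participants)."""
    if factors is None:
        factors = [
            c for c in table.columns if c not in (dv, "participant")
        ]
    g = table.groupby(factors)[dv]
    return g.agg(M="mean", SE=lambda x: x.std(ddof=1) / np.sqrt(len(x))).reset_index()


def _check_complete(table: pd.DataFrame, dv: str, subject: str, within: list[str]) -> None:
    counts = table.groupby([subject] + within, observed=True)[dv].count()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise ValueError(
            f"incomplete or duplicated within-subject crossing; offending "
            f"cells: {list(bad.index[:5])}"
        )
    n_cells = int(np.prod([table[f].nunique() for f in within]))
    per_subject = table.groupby(subject, observed=True)[dv].count()
    if (per_subject != n_cells).any():
        missing = per_subject[per_subject != n_cells]
        raise ValueError(f"missing cells for subjects {list(missing.index[:5])}")


def rm_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant",
    within: list[str] | None = None,
) -> list[StatResult]:
    """Repeated-measures ANOVA over up to three within-subject factors.

    Returns one :class:`StatResult` per main effect and interaction, in
    statsmodels term order.  Degenerate terms (zero effect and zero error
    variance) are reported as F = 0, p = 1.  For a single factor with more
    than two levels the Greenhouse-Geisser corrected p-value is reported.
    """
    if within is None or not 1 <= len(within) <= 3:
        raise ValueError("between 1 and 3 within-subject factors are required")
    if table[subject].nunique() < 2:
        raise ValueError("at least 2 participants are required")
    _check_complete(table, dv, subject, within)

    results: list[StatResult] = []
    if len(within) == 1 and table[within[0]].nunique() > 2:
        import pingouin as pg

        aov = pg.rm_anova(
            data=table, dv=dv, within=within[0], subject=subject,
            correction=True, effsize="np2", detailed=False,
        )
        row = aov.iloc[0]
        gg_col = next((c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns), None)
        unc_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        p = float(row[gg_col]) if gg_col else float(row[unc_col])
        results.append(
            StatResult(
                effect=within[0],
                statistic_kind="F",
                statistic=float(row["F"]),
                df=(float(row["ddof1"]), float(row["ddof2"])),
                p=p,
                effect_size=float(row["np2"]),
            )
        )
        return results

    # Degenerate input (constant response): every SS is zero, F := 0.
    degenerate = table[dv].std() <= 1e-12 * (1.0 + abs(table[dv].mean()))

    fit = AnovaRM(data=table, depvar=dv, subject=subject, within=within).fit()
    for term, row in fit.anova_table.iterrows():
        f_val = row["F Value"]
        df1, df2 = float(row["Num DF"]), float(row["Den DF"])
        p = row["Pr > F"]
        if degenerate or not np.isfinite(f_val) or f_val < 0:
            # a true F is a ratio of non-negative mean squares; anything
            # else is 0/0 round-off
            f_val, p = 0.0, 1.0
        eta = f_val * df1 / (f_val * df1 + df2) if np.isfinite(f_val) else np.nan
        results.append(
            StatResult(
                effect=term.replace(":", " x "),
                statistic_kind="F",
                statistic=float(f_val),
                df=(df1, df2),
                p=float(p),
                effect_size=float(eta),
            )
        )
    return results


def simple_effects(
    table: pd.DataFrame,
    compare: str,
    at: dict[str, object],
    dv: str = "value",
    subject: str = "participant",
) -> StatResult:
    """Paired comparison of a two-level factor within fixed levels of others.

    ``at`` fixes one (or more) factors at given levels; the two levels of
    ``compare`` are then contrasted with a paired t-test, averaging over any
    remaining factors within participant.
    """
    sub = table.copy()
    for col, level in at.items():
        sub = sub[sub[col] == level]
    levels = sorted(sub[compare].unique())
    if len(levels) != 2:
        raise ValueError(f"factor {compare!r} must have exactly 2 levels, got {levels}")
    wide = (
        sub.groupby([subject, compare], observed=True)[dv].mean().unstack(compare)
    )
    if wide.isna().any().any():
        raise ValueError(f"missing cells for simple effect {compare} at {at}")
    res = paired_t(wide[levels[0]].to_numpy(), wide[levels[1]].to_numpy())
    res.effect = f"{compare} ({levels[0]} vs {levels[1]}) at {at}"
    res.cells = cell_summary(
        sub[[subject, compare, dv]], dv=dv, factors=[compare]
    )
    return res


def paired_t(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Two-tailed paired t-test with Cohen's d = mean(diff)/sd(diff).

    Zero-variance differences are handled deterministically: a nonzero mean
    gives an infinite t (p = 0); an all-zero difference gives t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            t_val, p, eff = 0.0, 1.0, 0.0
        else:
            t_val = np.sign(mean) * np.inf
            p, eff = 0.0, np.sign(mean) * np.inf
    else:
        t_val = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t_val), df=n - 1)
        eff = mean / sd
    return StatResult(
        effect="paired comparison",
        statistic_kind="t",
        statistic=float(t_val),
        df=n - 1,
        p=float(p),
        effect_size=float(eff),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: list[StatResult]) -> list[StatResult]:
    """Attach BH-FDR adjusted p-values over one family of results."""
    adj = bh_fdr([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


def results_table(results: list[StatResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        df1, df2 = (r.df if isinstance(r.df, tuple) else (r.df, np.nan))
        rows.append(
            {
                "effect": r.effect,
                "statistic_kind": r.statistic_kind,
                "statistic": r.statistic,
                "df1": df1,
                "df2": df2,
                "p": r.p,
                "p_fdr": r.p_fdr,
                "effect_size": r.effect_size,
            }
        )
    return pd.DataFrame(rows)


def rm_anova_power(
    f: float,
    alpha: float = 0.05,
    power: float = 0.90,
    m: int = 2,
    rho: float = 0.5,
    epsilon: float = 1.0,
    n_min: int = 2,
    n_max: int = 10_000,
) -> int:
    """Smallest N reaching target power for a within-subject ANOVA effect.

    Uses the noncentral-F formulation with noncentrality
    ``lambda = f^2 * N * m * epsilon / (1 - rho)`` and degrees of freedom
    ``df1 = (m - 1) * epsilon``, ``df2 = (N - 1) * (m - 1) * epsilon``,
    where m is the number of repeated measurements, rho their mean
    correlation and epsilon the nonsphericity correction.
    """
    if f <= 0:
        raise ValueError("effect size f must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if m < 2 or not 0 <= rho < 1 or not 0 < epsilon <= 1:
        raise ValueError("invalid design constants")
    for n in range(max(n_min, 2), n_max + 1):
        lam = f**2 * n * m * epsilon / (1.0 - rho)
        df1 = (m - 1) * epsilon
        df2 = (n - 1) * (m - 1) * epsilon
        fcrit = stats.f.isf(alpha, df1, df2)
        if stats.ncf.sf(fcrit, df1, df2, lam) >= power:
            return n
    raise ValueError(f"target power {power} not attainable with N <= {n_max}")
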