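"""Screen-wide statistics: Welch tests against DMSO controls with
Bonferroni-corrected significance tiers.

Each (compound, behavior) pair is compared against the pooled or
batch-matched DMSO control larvae with Welch's unequal-variance t-test.
The Bonferroni divisor is the number of compounds in the screen (876 in
the screen this pipeline targets), matching the thresholds the assay
reports: 0.05/876 = 5.7e-5, 0.01/876 = 1.1e-5, 0.001/876 = 1.1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import BEHAVIOR_NAMES
from .profiling import GLOBAL_BATCH

TIERS = ("ns", "*", "**", "***")


class UndefinedTestError(ValueError):
    pass


@dataclass
class StatConfig:
    """Multiple-comparison setup: descending alpha levels and the
    Bonferroni divisor m (number of compounds tested)."""

    alpha_levels: tuple[float, ...] = (0.05, 0.01, 0.001)
    m: int = 876

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        a = self.alpha_levels
        if not all(0 < x < 1 for x in a) or list(a) != sorted(a, reverse=True):
            raise ValueError("alphas must lie in (0,1) and descend")


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with t = (mean_a - mean_b) /
    sqrt(s2_a/n_a + s2_b/n_b), Welch-Satterthwaite degrees of freedom
    and a two-sided p-value from the t distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise UndefinedTestError(f"need n >= 2 per sample, got {na} and {nb}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        raise UndefinedTestError("zero variance in both samples with unequal means")
    sa, sb = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _round_2sf(x: float) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    d = 1 - int(floor(log10(abs(x))))
    return round(x, d)


def bonferroni_thresholds(cfg: StatConfig) -> pd.DataFrame:
    """Per-alpha Bonferroni thresholds alpha/m, at full precision and
    rounded to two significant figures for display."""
    rows = [
        {"alpha": a, "threshold": a / cfg.m, "display": _round_2sf(a / cfg.m)}
        for a in cfg.alpha_levels
    ]
    return pd.DataFrame(rows).set_index("alpha")


def assign_tier(p: float, cfg: StatConfig) -> str:
    """Significance tier under the Bonferroni thresholds; monotone in p."""
    tier = "ns"
    for stars, a in zip(("*", "**", "***"), cfg.alpha_levels):
        if p < a / cfg.m:
            tier = stars
    return tier


def screen_test(
    larva_table: pd.DataFrame,
    tmap,
    cfg: StatConfig | None = None,
) -> pd.DataFrame:
    """Welch test of every (compound, behavior) against DMSO larvae.

    DMSO controls are matched by batch when the treatment map carries a
    ``batch`` column, otherwise pooled across the screen.  Compounds
    with fewer than 2 larvae are flagged untestable.  Returns the long
    table (compound, behavior, n, t, df, p, tier, testable).
    """
    cfg = cfg or StatConfig()
    ent = tmap.entries.loc[[w for w in larva_table.index if w in tmap.entries.index]]
    if len(ent) != len(larva_table):
        missing = set(larva_table.index) - set(tmap.entries.index)
        raise KeyError(f"wells absent from treatment map: {sorted(missing)[:5]}")
    batch = ent["batch"] if "batch" in ent.columns else pd.Series(
        GLOBAL_BATCH, index=ent.index
    )
    dmso_wells = ent.index[ent["role"] == "dmso_control"]
    if len(dmso_wells) == 0:
        raise UndefinedTestError("no DMSO control larvae available")
    dmso_by_batch = {
        b: larva_table.loc[ws]
        for b, ws in pd.Series(dmso_wells).groupby(batch.loc[dmso_wells].values)
    }
    pooled = larva_table.loc[dmso_wells]

    rows = []
    treat = ent[ent["role"] == "treatment"]
    for cid, grp in treat.groupby("compound_id"):
        wells = grp.index
        b = batch.loc[wells].iloc[0]
        ctrl = dmso_by_batch.get(b, pooled)
        sub = larva_table.loc[wells]
        for beh in BEHAVIOR_NAMES:
            a = sub[beh].to_numpy(dtype=float)
            c = ctrl[beh].to_numpy(dtype=float)
            a = a[np.isfinite(a)]
            c = c[np.isfinite(c)]
            row = {"compound_id": cid, "behavior": beh,
                   "n_treated": len(a), "n_control": len(c)}
            try:
                t, df, p = welch_t(a, c)
                row.update(t=t, df=df, p=p, tier=assign_tier(p, cfg), testable=True)
            except UndefinedTestError:
                row.update(t=np.nan, df=np.nan, p=np.nan, tier="ns", testable=False)
            rows.append(row)
    return pd.DataFrame(rows)


def fraction_with_significant(
    stat_table: pd.DataFrame,
    compound_set: Iterable[str] | None = None,
    alpha: float = 0.05,
    cfg: StatConfig | None = None,
) -> float:
    """Fraction of compounds with at least one behavior significant at
    the alpha/m Bonferroni tier."""
    cfg = cfg or StatConfig()
    thr = alpha / cfg.m
    df = stat_table
    if compound_set is not None:
        df = df[df["compound_id"].isin(set(compound_set))]
    if df.empty:
        return np.nan
    hit = df.assign(sig=df["p"] < thr).groupby("compound_id")["sig"].any()
    return float(hit.mean())
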