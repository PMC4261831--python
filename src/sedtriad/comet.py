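"""Comet-assay summaries and nonparametric concentration-effect testing.

A *condition* is one site x extract fraction x concentration x FPG
combination; its observations are per-nucleoid %DNA-in-tail values,
scored over duplicate gels in each of (typically) three replicates.
The reported endpoint is the mean %tail pooled over all nucleoids of
the condition.  Net oxidative damage is the difference between the
FPG-treated and buffer-only means of the same condition; negative
differences are reported as such, not clipped.

Concentration effects are tested with the Kruskal-Wallis rank test
(tie-corrected H) followed by Dunn-type pairwise comparisons of each
concentration against the solvent control, Bonferroni-adjusted.  The
default experimental unit is the replicate mean, which avoids treating
the ~100 nucleoids of a condition as independent; nucleoid-level
testing is available for exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import PairingError


@dataclass
class CometCondition:
    """%DNA-in-tail observations for one experimental condition.

    ``nucleoids`` is a DataFrame with columns ``replicate``, ``gel`` and
    ``tail_pct`` (one row per scored nucleoid, values in [0, 100]).
    """

    site: str
    fraction: int
    concentration: float
    fpg: bool
    nucleoids: pd.DataFrame

    def __post_init__(self):
        required = {"replicate", "gel", "tail_pct"}
        missing = required - set(self.nucleoids.columns)
        if missing:
            raise ValueError(f"nucleoids missing columns {sorted(missing)}")
        vals = self.nucleoids["tail_pct"]
        if len(vals) and ((vals < 0) | (vals > 100)).any():
            raise ValueError("%DNA in tail must lie within [0, 100]")

    @property
    def key(self):
        return (self.site, self.fraction, self.concentration, self.fpg)

    def replicate_means(self) -> pd.Series:
        return self.nucleoids.groupby("replicate")["tail_pct"].mean()


def condition_summary(cond: CometCondition) -> dict:
    """Mean and SD of %DNA in tail pooled over all nucleoids of the condition."""
    vals = cond.nucleoids["tail_pct"].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("empty condition: no nucleoids scored")
    return {
        "mean_tail_pct": float(vals.mean()),
        "sd_tail_pct": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "n_nucleoids": int(vals.size),
    }


def net_oxidative_damage(cond_fpg: CometCondition, cond_std: CometCondition) -> float:
    """FPG-minus-buffer difference in mean %tail for one condition (may be negative)."""
    if not cond_fpg.fpg or cond_std.fpg:
        raise PairingError("expected an FPG-treated and a buffer-only condition")
    if (cond_fpg.site, cond_fpg.fraction, cond_fpg.concentration) != \
       (cond_std.site, cond_std.fraction, cond_std.concentration):
        raise PairingError(
            f"conditions do not match: {cond_fpg.key} vs {cond_std.key}")
    return condition_summary(cond_fpg)["mean_tail_pct"] - \
        condition_summary(cond_std)["mean_tail_pct"]


def _dunn_vs_control(groups: list[np.ndarray], alpha: float) -> pd.DataFrame:
    """Dunn rank comparisons of each group against groups[0], Bonferroni-adjusted."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # mean rank per group
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    # tie correction term for the Dunn standard error
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts ** 3 - counts))
    tie_term = tie_sum / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    n_comp = len(groups) - 1
    rows = []
    for j in range(1, len(groups)):
        se = np.sqrt(base_var * (1.0 / sizes[0] + 1.0 / sizes[j]))
        z = (mean_ranks[j] - mean_ranks[0]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * n_comp)
        rows.append({"group": j, "z": float(z), "p_raw": float(p),
                     "p_adjusted": float(p_adj),
                     "significant": bool(p_adj < alpha)})
    return pd.DataFrame(rows)


def kw_concentration_test(conditions: list[CometCondition],
                          unit: str = "replicate",
                          alpha: float = 0.05) -> dict:
    """Kruskal-Wallis test across concentrations plus Dunn comparisons vs control.

    ``conditions`` must be ordered with the 0-concentration control
    first (they are sorted by concentration internally).  ``unit`` picks
    the experimental unit: ``"replicate"`` (default; replicate-mean
    %tail) or ``"nucleoid"`` (every scored nucleoid).
    """
    if len(conditions) < 2:
        raise ValueError("need at least 2 concentration groups")
    conditions = sorted(conditions, key=lambda c: c.concentration)
    if unit == "replicate":
        groups = [c.replicate_means().to_numpy(dtype=float) for c in conditions]
    elif unit == "nucleoid":
        groups = [c.nucleoids["tail_pct"].to_numpy(dtype=float) for c in conditions]
    else:
        raise ValueError(f"unknown experimental unit {unit!r}")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # all tied: no evidence of any effect
        h_stat, p_value = 0.0, 1.0
    else:
        h_stat, p_value = stats.kruskal(*groups)

    pairwise = _dunn_vs_control(groups, alpha)
    pairwise.insert(0, "concentration",
                    [conditions[j].concentration for j in pairwise["group"]])
    return {
        "H": float(h_stat),
        "p": float(p_value),
        "significant": bool(p_value < alpha),
        "pairwise_vs_control": pairwise,
        "unit": unit,
    }


def condition_table(conditions: list[CometCondition]) -> pd.DataFrame:
    """Tidy mean +/- SD summary, one row per condition."""
    rows = []
    for c in sorted(conditions, key=lambda c: (c.site, c.fraction, c.fpg, c.concentration)):
        row = {"site": c.site, "fraction": c.fraction,
               "concentration": c.concentration, "fpg": c.fpg}
        row.update(condition_summary(c))
        rows.append(row)
    return pd.DataFrame(rows)
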