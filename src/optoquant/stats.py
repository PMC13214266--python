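"""Nonparametric group comparisons and their effect sizes.

Mann-Whitney rank-sum tests with rank-biserial correlation r for two-group
comparisons, Kruskal-Wallis with an epsilon-squared-style effect size for
more than two groups, both with bootstrap percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney_effect",
    "kruskal_effect",
    "epsilon_squared_from_h",
    "epsilon_squared_from_p",
]


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    effect_size: float
    effect_name: str
    ci: tuple[float, float]
    n: tuple[int, ...]
    extra: dict


def _rank_biserial(a, b) -> float:
    # r = 1 - 2U_a/(n1 n2): +1 when every value of a lies below every value
    # of b (group b stochastically dominates)
    n1, n2 = len(a), len(b)
    u_a = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
    return 1.0 - 2.0 * float(u_a) / (n1 * n2)


def mann_whitney_effect(a, b, n_boot: int = 2000, seed: int | None = None
                        ) -> GroupComparison:
    """Two-sided Mann-Whitney test with rank-biserial r and bootstrap CI.

    The sign convention is fixed here: r = 1 - 2U_a/(n1 n2) with U_a the U
    statistic of group ``a``, so r = +1 when every value of ``a`` lies below
    every value of ``b`` and r = -1 in the opposite case.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return GroupComparison("mann-whitney", a.size * b.size / 2.0, 1.0, 0.0,
                               "rank_biserial_r", (0.0, 0.0),
                               (a.size, b.size), {})
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    r = 1.0 - 2.0 * float(res.statistic) / (a.size * b.size)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        aa = rng.choice(a, a.size, replace=True)
        bb = rng.choice(b, b.size, replace=True)
        boots[i] = 0.0 if np.ptp(np.concatenate([aa, bb])) == 0 \
            else _rank_biserial(aa, bb)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return GroupComparison("mann-whitney", float(res.statistic),
                           float(res.pvalue), r, "rank_biserial_r", ci,
                           (a.size, b.size), {})


def epsilon_squared_from_h(h: float, k: int, n: int) -> dict:
    """Both epsilon-squared conventions from a Kruskal-Wallis H statistic.

    ``eta_squared_h`` is (H - k + 1)/(n - k), the eta-squared_H form that many
    published reports print under the name epsilon-squared; ``textbook`` is
    the classical H / ((n^2 - 1)/(n + 1)).
    """
    return {
        "eta_squared_h": (h - k + 1.0) / (n - k),
        "textbook": h / ((n * n - 1.0) / (n + 1.0)),
    }


def epsilon_squared_from_p(p: float, k: int, n: int) -> dict:
    """Recompute effect sizes from a printed p-value and group layout.

    Inverts the chi-square approximation (df = k - 1) to recover H, then
    applies :func:`epsilon_squared_from_h`.  Useful when only summary
    statistics are published.
    """
    h = float(sps.chi2.isf(p, k - 1))
    out = epsilon_squared_from_h(h, k, n)
    out["h"] = h
    return out


def kruskal_effect(groups, n_boot: int = 0, seed: int | None = None
                   ) -> GroupComparison:
    """Kruskal-Wallis test (tie-corrected) with epsilon-squared effect sizes.

    Reports the eta-squared_H form (H - k + 1)/(n - k) — the convention most
    published epsilon-squared values follow — as the headline effect size,
    with the textbook epsilon-squared in ``extra``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    k = len(groups)
    n = sum(g.size for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return GroupComparison("kruskal-wallis", 0.0, 1.0, 0.0,
                               "eta_squared_h", (0.0, 0.0),
                               tuple(g.size for g in groups),
                               {"epsilon_squared_textbook": 0.0})
    res = sps.kruskal(*groups)
    eff = epsilon_squared_from_h(float(res.statistic), k, n)
    ci = (np.nan, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            gs = [rng.choice(g, g.size, replace=True) for g in groups]
            try:
                h = float(sps.kruskal(*gs).statistic)
            except ValueError:   # all values identical in the resample
                h = 0.0
            boots[i] = epsilon_squared_from_h(h, k, n)["eta_squared_h"]
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return GroupComparison("kruskal-wallis", float(res.statistic),
                           float(res.pvalue), eff["eta_squared_h"],
                           "eta_squared_h", ci,
                           tuple(g.size for g in groups),
                           {"epsilon_squared_textbook": eff["textbook"]})
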