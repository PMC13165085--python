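"""Stem-water-potential reference statistics.

The physiological reference for the spectral monitoring: per-day
comparison of stem water potential (Ψ, MPa, strictly negative) between
treatment groups.  The workflow screens each day's readings for
normality with a Lilliefors-type Kolmogorov-Smirnov test (parameters
estimated from the data, Monte-Carlo p-values with a fixed seed), applies
the logarithmic transform of |Ψ| when normality is rejected, runs a
classical one-way ANOVA, and follows up with Duncan's multiple range
test.  Output is a per-day summary table (group mean ± sd on the MPa
scale, F, p, ns/* flag, Duncan letters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DayComparison",
    "normality_check",
    "log_transform_psi",
    "oneway_anova",
    "duncan_posthoc",
    "reference_table",
]

# Null distributions of the Lilliefors statistic, cached by (n, reps, seed).
_LILLIEFORS_NULL: dict[tuple[int, int, int], np.ndarray] = {}


def _ks_statistic_fitted(x: np.ndarray) -> float:
    """Sup-distance between the ecdf and a normal fitted to the sample."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max(np.max(i / n - cdf), np.max(cdf - (i - 1) / n)))


def _null_table(n: int, reps: int, seed: int) -> np.ndarray:
    key = (n, reps, seed)
    if key not in _LILLIEFORS_NULL:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((reps, n))
        z = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(
            axis=1, ddof=1, keepdims=True
        )
        z.sort(axis=1)
        cdf = stats.norm.cdf(z)
        i = np.arange(1, n + 1)
        d = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
        _LILLIEFORS_NULL[key] = np.sort(d)
    return _LILLIEFORS_NULL[key]


def normality_check(
    values: np.ndarray, n_reps: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Lilliefors normality test: KS statistic against the fitted normal.

    The p-value is Monte-Carlo: the statistic's null distribution for this
    sample size is simulated once (``n_reps`` standard-normal samples,
    fixed ``seed``) and cached, so repeated calls are cheap and
    deterministic.  Returns (statistic, p_value).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("normality check needs n >= 5")
    if x.std(ddof=1) == 0:
        raise ValueError("constant sample; normality test undefined")
    d = _ks_statistic_fitted(x)
    null = _null_table(x.size, n_reps, seed)
    # add-one correction keeps p in (0, 1]
    n_geq = n_reps - int(np.searchsorted(null, d, side="left"))
    return d, (n_geq + 1) / (n_reps + 1)


def log_transform_psi(psi: np.ndarray) -> np.ndarray:
    """Natural log of |Ψ| for strictly negative potentials (MPa).

    Ψ is a tension, so magnitudes are logged; the order is reversed
    (more negative Ψ maps to larger transformed values).
    """
    x = np.asarray(psi, dtype=float)
    if np.any(x >= 0):
        raise ValueError("stem water potential must be strictly negative")
    return np.log(np.abs(x))


def oneway_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects F test across treatment groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 observations")
    if all(a.std() == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        raise ValueError("zero variance everywhere with equal means; F undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def _anova_decomposition(arrays: list[np.ndarray]) -> tuple[float, int]:
    """Within-group mean square and its degrees of freedom."""
    n_total = sum(a.size for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df = n_total - len(arrays)
    return ssw / df, df


def duncan_posthoc(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> dict[str, str]:
    """Duncan's multiple range test with studentized-range critical values.

    Means are sorted; a span of p adjacent ordered means is homogeneous
    when its extremes differ by no more than the least significant range
    LSR_p = q(1-alpha_p; p, df) * sqrt(MSW / n_h), with the step-dependent
    protection level alpha_p = 1 - (1 - alpha)^(p-1) and n_h the harmonic
    mean group size.  Letters come from the maximal homogeneous spans.
    """
    if len(groups) < 2:
        raise ValueError("post hoc comparison needs >= 2 groups")
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    msw, df = _anova_decomposition(arrays)
    n_h = len(arrays) / sum(1.0 / a.size for a in arrays)
    order = np.argsort([-a.mean() for a in arrays])
    sorted_names = [names[i] for i in order]
    means = np.array([arrays[i].mean() for i in order])
    g = len(means)

    def homogeneous(i: int, j: int) -> bool:
        p = j - i + 1
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        lsr = stats.studentized_range.ppf(1.0 - alpha_p, p, df) * np.sqrt(msw / n_h)
        return abs(means[i] - means[j]) <= lsr

    # maximal homogeneous spans of the ordered means
    spans: list[tuple[int, int]] = []
    for i in range(g):
        j = i
        while j + 1 < g and homogeneous(i, j + 1):
            j += 1
        spans.append((i, j))
    maximal = [s for s in spans if not any(o[0] <= s[0] and s[1] <= o[1] and o != s
                                           for o in spans)]
    letters = {name: "" for name in names}
    for letter_idx, (lo, hi) in enumerate(sorted(set(maximal))):
        letter = chr(ord("a") + letter_idx)
        for pos in range(lo, hi + 1):
            letters[sorted_names[pos]] += letter
    return letters


@dataclass
class DayComparison:
    """Per-day between-group test on stem water potential."""

    day: int
    group_means: dict[str, tuple[float, float]]  # group -> (mean MPa, sd MPa)
    f_statistic: float
    p_value: float
    significant: bool
    duncan_groups: dict[str, str]
    transformed: bool  # whether analysis ran on log|psi|


def reference_table(
    psi: pd.DataFrame,
    alpha: float = 0.01,
    normality_alpha: float = 0.05,
    n_reps: int = 10000,
    seed: int = 0,
) -> list[DayComparison]:
    """Per-day ANOVA + Duncan summary of a Ψ table.

    ``psi`` has columns plant_id, group, day, psi_MPa.  For each day the
    pooled group-centered residuals are screened for normality; if
    rejected at ``normality_alpha`` the analysis runs on log|Ψ|.  Group
    means/sds are always reported on the original MPa scale.
    """
    required = {"group", "day", "psi_MPa"}
    if not required.issubset(psi.columns):
        raise ValueError(f"psi table must have columns {sorted(required)}")
    out = []
    for day, sub in psi.groupby("day", sort=True):
        raw = {g: s["psi_MPa"].to_numpy(dtype=float) for g, s in sub.groupby("group")}
        residuals = np.concatenate([v - v.mean() for v in raw.values()])
        transformed = False
        if residuals.size >= 5 and residuals.std(ddof=1) > 0:
            _, p_norm = normality_check(residuals, n_reps=n_reps, seed=seed)
            transformed = p_norm < normality_alpha
        analysis = (
            {g: log_transform_psi(v) for g, v in raw.items()} if transformed else raw
        )
        f, p = oneway_anova(analysis)
        letters = duncan_posthoc(analysis, alpha=alpha)
        out.append(
            DayComparison(
                day=int(day),
                group_means={
                    g: (float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0)
                    for g, v in raw.items()
                },
                f_statistic=f,
                p_value=p,
                significant=p < alpha,
                duncan_groups=letters,
                transformed=transformed,
            )
        )
    return out


def comparisons_to_frame(comparisons: list[DayComparison]) -> pd.DataFrame:
    """Flatten day comparisons into a printable summary table."""
    rows = []
    for c in comparisons:
        row: dict = {"day": c.day}
        for g, (m, sd) in sorted(c.group_means.items()):
            row[f"{g}_mean_MPa"] = round(m, 2)
            row[f"{g}_sd_MPa"] = round(sd, 2)
        row["F"] = round(c.f_statistic, 3)
        row["p_value"] = c.p_value
        row["flag"] = "*" if c.significant else "ns"
        row["duncan"] = "; ".join(f"{g}:{l}" for g, l in sorted(c.duncan_groups.items()))
        row["log_transformed"] = c.transformed
        rows.append(row)
    return pd.DataFrame(rows)
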