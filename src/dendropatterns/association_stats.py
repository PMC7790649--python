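"""Association and group-difference tests for growth patterns.

Two permutation procedures link the identified growth patterns to canopy
layers, species and tree attributes:

* ``pattern_association_test`` — a Monte-Carlo test of row-column
  independence in a contingency table.  Null tables with the observed
  margins are sampled (Patefield's algorithm) and the chi-square statistic
  compared against the observed one.  This is a documented stand-in for an
  exact r x c Fisher test: it targets the same null but estimates the
  p-value by simulation.

* ``attribute_group_test`` — a stratified permutation F-test comparing a
  numeric attribute between patterns, permuting labels only within strata
  (sites), which plays the role of a site random effect.  Pairwise
  comparisons are Holm-adjusted and summarized as a compact letter display.
  This replaces a mixed-effects ANOVA with Tukey contrasts; it is
  assumption-light but tests the same grouping question.

Permutation p-values use the add-one rule p = (1 + #{perm >= obs}) / (1 + B),
so the smallest attainable p is 1/(B+1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "GroupTestResult",
    "pattern_association_test",
    "attribute_group_test",
]


@dataclass(frozen=True)
class AssociationResult:
    statistic: float  # observed chi-square
    p_value: float
    n_permutations: int
    dof: int


def _chi2_stat(obs: np.ndarray, expected: np.ndarray) -> float:
    return float(((obs - expected) ** 2 / expected).sum())


def pattern_association_test(
    table: pd.DataFrame | np.ndarray,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> AssociationResult:
    """Monte-Carlo chi-square test of independence under fixed margins."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must hold nonnegative integer counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("degenerate margins: empty row or column")
    expected = np.outer(rows, cols) / obs.sum()
    observed_stat = _chi2_stat(obs, expected)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(rows.astype(int), cols.astype(int))
    sims = sampler.rvs(n_permutations, random_state=rng)
    sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    exceed = int(np.sum(sim_stats >= observed_stat - 1e-12))
    p = (1 + exceed) / (1 + n_permutations)
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return AssociationResult(
        statistic=observed_stat, p_value=p, n_permutations=n_permutations, dof=dof
    )


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float  # observed one-way F (nan if undefined)
    p_value: float
    n_permutations: int
    group_means: dict[str, float]
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_raw, p_holm
    letters: dict[str, str]  # compact letter display


def _f_statistic(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = values.size
    grand = values.mean()
    counts = np.bincount(codes, minlength=n_groups)
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    means = sums / counts
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((values - means[codes]) ** 2).sum())
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within == 0:
        return float("nan") if ss_between == 0 else float("inf")
    return (ss_between / df_b) / (ss_within / df_w)


def _permute_within_strata(
    rng: np.random.Generator, codes: np.ndarray, strata_idx: list[np.ndarray]
) -> np.ndarray:
    out = codes.copy()
    for idx in strata_idx:
        out[idx] = out[rng.permutation(idx)]
    return out


def _compact_letters(groups: list[str], means: dict[str, float], sig: set[frozenset]) -> dict[str, str]:
    """Greedy letter assignment: groups sharing a letter are not significantly
    different; ordered by descending mean as in the usual displays."""
    ordered = sorted(groups, key=lambda g: -means[g])
    letter_sets: list[set[str]] = []
    for g in ordered:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in sig for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(out[g])) for g in groups}


def attribute_group_test(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    strata: np.ndarray | pd.Series | None = None,
    n_permutations: int = 9999,
    seed: int | None = None,
    alpha: float = 0.05,
    drop_outliers: bool = False,
) -> GroupTestResult:
    """Stratified permutation F-test of a numeric attribute across patterns.

    Labels are permuted within each stratum (site), holding the stratum
    composition fixed.  ``drop_outliers`` removes values below the 1st or
    above the 99th percentile before testing (off by default).  Groups with
    fewer than two values are excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(str)
    if strata is None:
        strata = np.zeros(values.size, dtype=int)
    strata = np.asarray(strata)
    keep = np.isfinite(values)
    if drop_outliers:
        lo, hi = np.percentile(values[keep], [1, 99])
        keep &= (values >= lo) & (values <= hi)
    values, groups, strata = values[keep], groups[keep], strata[keep]

    names, codes = np.unique(groups, return_inverse=True)
    counts = np.bincount(codes)
    small = names[counts < 2]
    if small.size:
        warnings.warn(f"excluding group(s) with < 2 values: {list(small)}")
        keep = ~np.isin(groups, small)
        values, groups, strata = values[keep], groups[keep], strata[keep]
        names, codes = np.unique(groups, return_inverse=True)
    if names.size < 2:
        raise ValueError("need at least 2 groups with >= 2 values each")

    k = names.size
    obs_f = _f_statistic(values, codes, k)
    means = {
        str(g): float(values[codes == i].mean()) for i, g in enumerate(names)
    }
    rng = np.random.default_rng(seed)
    strata_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]

    if np.isnan(obs_f):  # identical values everywhere: no difference detectable
        pairwise = pd.DataFrame(
            [
                {"group_a": a, "group_b": b, "mean_diff": 0.0, "p_raw": 1.0, "p_holm": 1.0}
                for a, b in itertools.combinations(names, 2)
            ]
        )
        return GroupTestResult(
            statistic=float("nan"),
            p_value=1.0,
            n_permutations=n_permutations,
            group_means=means,
            pairwise=pairwise,
            letters={str(g): "a" for g in names},
        )

    exceed = 0
    for _ in range(n_permutations):
        perm = _permute_within_strata(rng, codes, strata_idx)
        if _f_statistic(values, perm, k) >= obs_f - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)

    # pairwise permutation tests on |mean difference|, Holm-adjusted
    pair_rows = []
    for a, b in itertools.combinations(range(k), 2):
        mask = (codes == a) | (codes == b)
        v, c, s = values[mask], (codes[mask] == b).astype(int), strata[mask]
        obs_d = abs(v[c == 1].mean() - v[c == 0].mean())
        s_idx = [np.flatnonzero(s == u) for u in np.unique(s)]
        cnt = 0
        for _ in range(n_permutations):
            pc = _permute_within_strata(rng, c, s_idx)
            if pc.sum() in (0, pc.size):
                d = 0.0
            else:
                d = abs(v[pc == 1].mean() - v[pc == 0].mean())
            if d >= obs_d - 1e-12:
                cnt += 1
        pair_rows.append(
            {
                "group_a": str(names[a]),
                "group_b": str(names[b]),
                "mean_diff": float(v[c == 1].mean() - v[c == 0].mean()),
                "p_raw": (1 + cnt) / (1 + n_permutations),
            }
        )
    pairwise = pd.DataFrame(pair_rows)
    pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]
    sig = {
        frozenset((r.group_a, r.group_b))
        for r in pairwise.itertuples()
        if r.p_holm <= alpha
    }
    letters = _compact_letters([str(g) for g in names], means, sig)
    return GroupTestResult(
        statistic=obs_f,
        p_value=p,
        n_permutations=n_permutations,
        group_means=means,
        pairwise=pairwise,
        letters=letters,
    )
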