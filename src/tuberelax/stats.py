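"""Group comparison, compact letter displays and PCA for tuber measurements.

Comparisons follow a normality-gated dispatch at a 95 % confidence
level: residuals (values minus their group mean) are tested with
Shapiro-Wilk at alpha = 0.05; when normality holds, two groups are
compared with Student's t-test and three or more with one-way ANOVA
followed by Tukey's HSD; otherwise the Mann-Whitney test replaces the
t-test and the Kruskal-Wallis test followed by Bonferroni-corrected
pairwise Mann-Whitney comparisons replaces ANOVA.  Outcomes are
summarised as compact letter displays: groups sharing no letter differ
significantly.

PCA operates on the correlation matrix (columns centred and scaled to
unit variance) because the variables mix units (%, ms, umol/g, ...).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatOutcome",
    "PCAResult",
    "water_content",
    "compare_two",
    "compare_many",
    "letters_from_significance",
    "run_pca",
    "type_i_error_check",
]

ALPHA = 0.05


def water_content(fw: float, dw: float) -> float:
    """Water content in percent of fresh weight: (FW - DW)/FW * 100."""
    if fw <= 0:
        raise ValueError("fresh weight must be positive")
    if dw < 0 or dw > fw:
        raise ValueError("dry weight must lie in [0, fresh weight]")
    return (fw - dw) / fw * 100.0


@dataclass
class StatOutcome:
    """Outcome of one group comparison with its letter display."""

    grouping_factor: str
    cells: list[str]
    test_used: str           # t | mann_whitney | anova_tukey | kruskal_bonferroni
    p_value: float           # overall test p-value
    letters: dict[str, str]
    alpha: float = ALPHA
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _residuals_normal(groups: list[np.ndarray], alpha: float = ALPHA) -> bool:
    """Shapiro-Wilk on pooled within-group residuals; gate for the dispatch.

    Degenerate residual sets (fewer than 3 values or zero spread) pass
    the gate: there is no evidence against normality to act on.
    """
    resid = np.concatenate([g - g.mean() for g in groups])
    if len(resid) < 3 or np.ptp(resid) == 0:
        return True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.shapiro(resid)
    return bool(p >= alpha)


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    if any(not np.all(np.isfinite(g)) for g in gs):
        raise ValueError("values must be finite")
    return gs


def compare_two(group_a, group_b, grouping_factor: str = "group",
                names: tuple[str, str] = ("a", "b"),
                method: str = "auto", alpha: float = ALPHA) -> StatOutcome:
    """Two-group comparison with normality-gated test choice.

    ``method`` may force ``"t"`` or ``"mann_whitney"``; ``"auto"``
    applies the Shapiro-Wilk gate.  Letters are 'a','a' when the groups
    do not differ at ``alpha`` and 'a','b' when they do.
    """
    a, b = _check_groups([group_a, group_b])
    if method == "auto":
        method = "t" if _residuals_normal([a, b], alpha) else "mann_whitney"
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
    elif method == "t":
        _, p = sps.ttest_ind(a, b)
    elif method == "mann_whitney":
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(p)
    letters = {names[0]: "a", names[1]: "a" if p >= alpha else "b"}
    return StatOutcome(grouping_factor=grouping_factor, cells=list(names),
                       test_used=method, p_value=p, letters=letters, alpha=alpha,
                       pairwise_p={(names[0], names[1]): p})


def letters_from_significance(cells: list[str],
                              differ: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Starts from one letter shared by every cell; each significantly
    different pair splits every letter set containing both; redundant
    subsets are absorbed.  Cells sharing a letter are never declared
    different, and cells never declared different always share one.
    """
    sets: list[set[str]] = [set(cells)]
    for (i, j), d in differ.items():
        if not d:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.extend([s - {i}, s - {j}])
            else:
                new_sets.append(s)
        # absorb: drop empty sets and strict subsets
        new_sets = [s for s in new_sets if s]
        sets = [s for s in new_sets
                if not any(s < t for t in new_sets)]
        # dedupe while keeping order
        seen: list[set[str]] = []
        for s in sets:
            if s not in seen:
                seen.append(s)
        sets = seen
    # assign letter characters in cell order of first appearance
    sets.sort(key=lambda s: min(cells.index(c) for c in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {c: "" for c in cells}
    for letter, s in zip(alphabet, sets):
        for c in cells:
            if c in s:
                out[c] += letter
    return out


def compare_many(groups: dict[str, np.ndarray] | list,
                 grouping_factor: str = "group",
                 post_hoc: str = "auto", alpha: float = ALPHA) -> StatOutcome:
    """Comparison of three or more groups with a letter display.

    Parametric branch: one-way ANOVA, Tukey HSD pairwise p-values.
    Non-parametric branch: Kruskal-Wallis, pairwise Mann-Whitney with
    Bonferroni correction (``post_hoc="dunn"`` is accepted as an alias
    for the same pairwise scheme on rank sums via Mann-Whitney).
    """
    if isinstance(groups, dict):
        names = list(groups.keys())
        gs = _check_groups(list(groups.values()))
    else:
        gs = _check_groups(groups)
        names = [f"g{i+1}" for i in range(len(gs))]
    if len(gs) < 3:
        raise ValueError("compare_many needs >= 3 groups")

    parametric = _residuals_normal(gs, alpha) if post_hoc == "auto" else post_hoc == "tukey"
    pairs = list(itertools.combinations(range(len(gs)), 2))
    pairwise: dict[tuple[str, str], float] = {}

    if all(np.ptp(g) == 0 for g in gs) and len({g[0] for g in gs}) == 1:
        p_overall = 1.0
        for i, j in pairs:
            pairwise[(names[i], names[j])] = 1.0
        test_used = "anova_tukey"
    elif parametric:
        _, p_overall = sps.f_oneway(*gs)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        values = np.concatenate(gs)
        codes = np.concatenate([[names[i]] * len(g) for i, g in enumerate(gs)])
        tk = pairwise_tukeyhsd(values, codes, alpha=alpha)
        uniq = [str(g) for g in tk.groupsunique]
        for (g1, g2), pv in zip(itertools.combinations(uniq, 2), tk.pvalues):
            key = (g1, g2) if names.index(g1) < names.index(g2) else (g2, g1)
            pairwise[key] = float(pv)
        test_used = "anova_tukey"
    else:
        _, p_overall = sps.kruskal(*gs)
        m = len(pairs)
        for i, j in pairs:
            if np.ptp(gs[i]) == 0 and np.ptp(gs[j]) == 0 and gs[i][0] == gs[j][0]:
                p = 1.0
            else:
                _, p = sps.mannwhitneyu(gs[i], gs[j], alternative="two-sided")
            pairwise[(names[i], names[j])] = min(1.0, float(p) * m)
        test_used = "kruskal_bonferroni"

    differ = {k: v < alpha for k, v in pairwise.items()}
    letters = letters_from_significance(names, differ)
    return StatOutcome(grouping_factor=grouping_factor, cells=names,
                       test_used=test_used, p_value=float(p_overall),
                       letters=letters, alpha=alpha, pairwise_p=pairwise)


@dataclass
class PCAResult:
    scores: pd.DataFrame              # observations x components
    loadings: pd.DataFrame            # variables x components, orthonormal cols
    explained_variance_pct: np.ndarray


def run_pca(table: pd.DataFrame, variables: list[str],
            obs_keys: list[str] | None = None) -> PCAResult:
    """PCA of a long table pivoted to observations x variables.

    Observations are identified by ``obs_keys`` (default: every one of
    ``sample_id, tissue, dase, regime`` present).  Columns are centred
    and scaled to unit variance, so the decomposition diagonalises the
    sample correlation matrix; explained-variance percentages are the
    eigenvalue shares.  Constant variables are dropped with a warning;
    incomplete observations are dropped.
    """
    if len(variables) < 2:
        raise ValueError("PCA needs at least 2 variables")
    if obs_keys is None:
        obs_keys = [c for c in ("sample_id", "tissue", "dase", "regime")
                    if c in table.columns]
    wide = table.pivot_table(index=obs_keys, columns="variable",
                             values="value", aggfunc="mean")
    missing = [v for v in variables if v not in wide.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    wide = wide[variables].dropna()
    keep = []
    for v in variables:
        if np.ptp(wide[v].to_numpy()) == 0:
            warnings.warn(f"dropping constant variable {v!r}")
        else:
            keep.append(v)
    wide = wide[keep]
    n, p = wide.shape
    if n < 3 or p < 2:
        raise ValueError("PCA needs >= 3 complete observations and >= 2 varying variables")
    X = wide.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s ** 2 / (n - 1)
    expl = 100.0 * eig / eig.sum()
    comp_names = [f"PC{i+1}" for i in range(len(s))]
    scores = pd.DataFrame(U * s, index=wide.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=keep, columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings, explained_variance_pct=expl)


def type_i_error_check(test: str, n: int, reps: int, seed: int,
                       n_groups: int | None = None) -> float:
    """Empirical type-I error of the normality-gated dispatcher.

    Simulates ``reps`` draws of identical Gaussian cells (null), runs
    the two-group (``test="two"``) or many-group (``test="many"``)
    dispatcher and returns the fraction of overall p-values below 0.05.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if test not in ("two", "many"):
        raise ValueError("test must be 'two' or 'many'")
    k = n_groups or (2 if test == "two" else 3)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        cells = [rng.normal(0.0, 1.0, n) for _ in range(k)]
        # same gate and overall test as the compare_* dispatchers; the
        # post-hoc letter construction does not affect the rejection
        normal = _residuals_normal(cells)
        if test == "two":
            if normal:
                _, p = sps.ttest_ind(cells[0], cells[1])
            else:
                _, p = sps.mannwhitneyu(cells[0], cells[1], alternative="two-sided")
        else:
            _, p = sps.f_oneway(*cells) if normal else sps.kruskal(*cells)
        rejections += p < ALPHA
    return rejections / reps
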