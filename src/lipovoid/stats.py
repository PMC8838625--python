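"""Assumption-gated group comparisons with compact-letter displays.

Replicate-level metrics (z, v, R_43, ...) are compared across the four
cells of a base-fat factorial design (emulsifier x shear type).  The
Brown-Forsythe test (Levene's test on deviations from the median) gates
the branch: homoscedastic data go through ordinary two-way ANOVA with
Tukey HSD pairwise comparisons; heteroscedastic data go through Welch's
ANOVA with Dunnett T3 pairwise comparisons (Welch t statistics with
Satterthwaite degrees of freedom against Sidak-style studentized-maximum-
modulus critical values).  Pairwise results are summarized as compact
letter displays: groups sharing a letter are not significantly different
at the stated alpha.  Comparisons are made within one base fat only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupLabel",
    "SampleGroup",
    "ComparisonResult",
    "check_homoscedasticity",
    "welch_anova_pvalue",
    "dunnett_t3_pvalues",
    "compact_letter_display",
    "compare_groups",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class GroupLabel:
    base_fat: str  # "CB" | "TL"
    emulsifier: bool
    shear_type: str  # "RS" | "LS"
    shear_rate: float = 500.0

    def __post_init__(self):
        if self.shear_type not in ("RS", "LS"):
            raise ValueError(f"shear_type must be 'RS' or 'LS', got {self.shear_type!r}")
        if self.shear_rate <= 0:
            raise ValueError("shear_rate must be positive")

    def __str__(self) -> str:
        m = "/M" if self.emulsifier else ""
        return f"{self.base_fat}{m} {self.shear_type}"


@dataclass
class SampleGroup:
    label: GroupLabel
    replicate_values: list[float]

    def __post_init__(self):
        self.replicate_values = [float(v) for v in self.replicate_values]

    @property
    def n(self) -> int:
        return len(self.replicate_values)


@dataclass
class ComparisonResult:
    metric_name: str
    branch: str  # "ordinary_two_way" | "welch"
    factor_p_values: dict[str, float]
    pairwise_p_values: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float = ALPHA_DEFAULT
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    homoscedasticity: tuple[float, float] | None = None  # (statistic, p)
    warnings: list[str] = field(default_factory=list)
    degenerate: bool = False


def check_homoscedasticity(groups: list[SampleGroup]):
    """Brown-Forsythe test for equal variances across groups.

    Returns ``(statistic, p, homoscedastic)``; homoscedastic iff p > 0.05.
    Zero variance in every group is degenerate and flagged homoscedastic
    with the p = 1 convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label} has fewer than two replicates")
    samples = [np.asarray(g.replicate_values) for g in groups]
    if all(s.std() == 0 for s in samples):
        return 0.0, 1.0, True
    stat, p = sps.levene(*samples, center="median")
    return float(stat), float(p), bool(p > ALPHA_DEFAULT)


def welch_anova_pvalue(samples: list[np.ndarray]) -> float:
    """Welch's heteroscedasticity-robust one-way ANOVA p-value."""
    k = len(samples)
    ns = np.array([len(s) for s in samples], dtype=float)
    means = np.array([np.mean(s) for s in samples])
    vars_ = np.array([np.var(s, ddof=1) for s in samples])
    if np.any(vars_ == 0):
        vars_ = np.maximum(vars_, 1e-300)
    w = ns / vars_
    mw = np.sum(w * means) / np.sum(w)
    a = np.sum(w * (means - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (ns - 1))
    b = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = a / b
    df2 = (k**2 - 1) / (3 * lam)
    return float(sps.f.sf(f, k - 1, df2))


def dunnett_t3_pvalues(groups: list[SampleGroup]) -> dict[tuple[str, str], float]:
    """Dunnett T3 all-pairs p-values.

    Welch t statistic and Satterthwaite degrees of freedom per pair, with a
    Sidak-style studentized-maximum-modulus adjustment over the number of
    comparisons: ``p = 1 - (2 F_t(|t|; df) - 1)^k``.
    """
    pairs = list(itertools.combinations(groups, 2))
    k = len(pairs)
    out: dict[tuple[str, str], float] = {}
    for ga, gb in pairs:
        a = np.asarray(ga.replicate_values)
        b = np.asarray(gb.replicate_values)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / len(a) + vb / len(b)
        key = (str(ga.label), str(gb.label))
        if se2 == 0:
            # zero-variance degenerate pair: no dispersion to test against
            out[key] = 1.0 if a.mean() == b.mean() else 0.0
            continue
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / len(a)) ** 2 / (len(a) - 1)
                       + (vb / len(b)) ** 2 / (len(b) - 1))
        p_raw = 2 * sps.t.sf(abs(t), df)
        out[key] = float(1 - (1 - p_raw) ** k) if k > 1 else float(p_raw)
    return out


def compact_letter_display(
    names: list[str],
    pairwise_p: dict[tuple[str, str], float],
    alpha: float = ALPHA_DEFAULT,
    order_by: dict[str, float] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pairwise p-value exceeds ``alpha``.
    Groups are lettered in descending order of ``order_by`` (typically the
    group means) for the conventional presentation.
    """
    ordered = sorted(names, key=lambda n: (-(order_by or {}).get(n, 0.0), n))

    def p_of(a: str, b: str) -> float:
        return pairwise_p.get((a, b), pairwise_p.get((b, a), 1.0))

    columns: list[set[str]] = [set(ordered)]
    for a, b in itertools.combinations(ordered, 2):
        if p_of(a, b) > alpha:
            continue
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb: drop empty columns, duplicates and proper subsets
        columns = []
        for col in new_cols:
            if not col:
                continue
            if any(col < other for other in new_cols if other is not col):
                continue
            if col in columns:
                continue
            columns.append(col)
    # deterministic column order: by position of first member
    pos = {n: i for i, n in enumerate(ordered)}
    columns.sort(key=lambda col: min(pos[n] for n in col))
    letters = {n: "" for n in ordered}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, col in enumerate(columns):
        ch = alphabet[i % 26] * (1 + i // 26)
        for n in ordered:
            if n in col:
                letters[n] += ch
    return letters


def _two_way_pvalues(df: pd.DataFrame) -> dict[str, float]:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("value ~ C(emulsifier) * C(shear_type)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "emulsifier": float(table.loc["C(emulsifier)", "PR(>F)"]),
        "shear_type": float(table.loc["C(shear_type)", "PR(>F)"]),
        "interaction": float(table.loc["C(emulsifier):C(shear_type)", "PR(>F)"]),
    }


def _tukey_pvalues(df: pd.DataFrame) -> dict[tuple[str, str], float]:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(df["value"].to_numpy(), df["cell"].to_numpy())
    groups = res.groupsunique
    out = {}
    for (i, j), p in zip(itertools.combinations(range(len(groups)), 2), res.pvalues):
        out[(str(groups[i]), str(groups[j]))] = float(p)
    return out


def compare_groups(
    groups: list[SampleGroup],
    metric_name: str = "",
    alpha: float = ALPHA_DEFAULT,
) -> ComparisonResult:
    """Run the gated comparison workflow across the cells of one base fat.

    Homoscedastic data (Brown-Forsythe p > 0.05) are analysed with ordinary
    two-way ANOVA (emulsifier, shear type, interaction) and Tukey HSD
    pairwise tests across the cells; heteroscedastic data with Welch's
    ANOVA and Dunnett T3.  A design unbalanced by more than one replicate
    forces the Welch branch with a recorded warning.  Zero variance
    everywhere short-circuits to a degenerate "no difference detectable"
    result.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    fats = {g.label.base_fat for g in groups}
    if len(fats) != 1:
        raise ValueError(
            f"groups span base fats {sorted(fats)}; compare within one base fat"
        )
    names = [str(g.label) for g in groups]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group labels")
    means = {str(g.label): float(np.mean(g.replicate_values)) for g in groups}
    sds = {str(g.label): (float(np.std(g.replicate_values, ddof=1))
                          if g.n >= 2 else float("nan")) for g in groups}
    warnings: list[str] = []

    stat, p_bf, homo = check_homoscedasticity(groups)

    if all(np.std(g.replicate_values) == 0 for g in groups):
        letters = dict.fromkeys(names, "a")
        return ComparisonResult(
            metric_name=metric_name, branch="welch", factor_p_values={},
            pairwise_p_values={}, letters=letters, alpha=alpha, means=means,
            sds=sds, homoscedasticity=(stat, p_bf), degenerate=True,
            warnings=["zero variance in every group: no difference detectable"],
        )

    ns = [g.n for g in groups]
    unbalanced = max(ns) - min(ns) > 1
    if unbalanced:
        warnings.append(
            "design unbalanced beyond one missing replicate: Welch branch forced"
        )

    use_welch = (not homo) or unbalanced
    df = pd.DataFrame({
        "value": [v for g in groups for v in g.replicate_values],
        "cell": [str(g.label) for g in groups for _ in g.replicate_values],
        "emulsifier": [g.label.emulsifier for g in groups for _ in g.replicate_values],
        "shear_type": [g.label.shear_type for g in groups for _ in g.replicate_values],
    })

    if use_welch:
        branch = "welch"
        samples = [np.asarray(g.replicate_values) for g in groups]
        factor_p = {"welch_anova": welch_anova_pvalue(samples)}
        pairwise = dunnett_t3_pvalues(groups)
    else:
        branch = "ordinary_two_way"
        if df["emulsifier"].nunique() > 1 and df["shear_type"].nunique() > 1:
            factor_p = _two_way_pvalues(df)
        else:
            # not a factorial layout; fall back to the one-way omnibus
            factor_p = {"anova": float(sps.f_oneway(
                *[np.asarray(g.replicate_values) for g in groups]).pvalue)}
        pairwise = _tukey_pvalues(df)

    letters = compact_letter_display(names, pairwise, alpha=alpha, order_by=means)
    return ComparisonResult(
        metric_name=metric_name, branch=branch, factor_p_values=factor_p,
        pairwise_p_values=pairwise, letters=letters, alpha=alpha, means=means,
        sds=sds, homoscedasticity=(stat, p_bf), warnings=warnings,
    )
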