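"""Inferential wrapper: one-way ANOVA with Tukey HSD (or LSD) post hoc and
compact letter displays, grouped Pearson correlation matrices, a
correlation-matrix PCA summary, and a residual-normality diagnostic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupComparison",
    "anova_tukey",
    "compact_letter_display",
    "significance_stars",
    "pearson_by_group",
    "PCASummary",
    "pca_summary",
    "residual_normality",
    "DEFAULT_PCA_GROUPS",
]

#: Sample clustering used for grouped correlations, as observed in the
#: ordination of the post-incubation data: the unamended control separates
#: from the mineral-P-like cluster (MAP, CaH2PO4, phytate) and from the
#: labile organic cluster (AMP, RNA).
DEFAULT_PCA_GROUPS: dict[str, tuple[str, ...]] = {
    "control": ("control",),
    "mineral_like": ("MAP", "CaH2PO4", "phytate"),
    "labile_organic": ("AMP", "RNA"),
}


def significance_stars(p: float) -> str:
    """Star annotation at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# ANOVA + post hoc
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    variable: str
    f_stat: float
    p_value: float
    letters: dict[str, str]
    posthoc: str
    pairwise_p: pd.DataFrame
    group_means: dict[str, float] = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def compact_letter_display(groups: list[str], pairwise_p: pd.DataFrame,
                           alpha: float = 0.05,
                           means: dict[str, float] | None = None) -> dict[str, str]:
    """Derive a compact letter display from a pairwise p-value matrix.

    Greedy insert–absorb scheme over the non-significance graph: groups are
    visited in descending mean order; each group joins every existing letter
    whose members it does not differ from, and spawns a new letter when none
    admits it. Two groups share a letter iff they are not significantly
    different in the pairwise matrix (so equal means always share).
    """
    order = sorted(groups, key=lambda g: -(means or {}).get(g, 0.0))

    def differ(a: str, b: str) -> bool:
        return bool(pairwise_p.loc[a, b] < alpha)

    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(not differ(g, other) for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb redundant letters (subsets of another letter)
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def anova_tukey(values, groups, posthoc: str = "tukey", alpha: float = 0.05,
                variable: str = "") -> GroupComparison:
    """Classical one-way ANOVA with Tukey HSD (default) or Fisher's LSD
    pairwise comparisons and a compact letter display.

    LSD uses unadjusted pairwise t-tests on the pooled within-group mean
    square, the fallback used when Tukey separates nothing.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {g: values[groups == g] for g in labels}
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("each group needs at least 2 observations")
    if all(np.std(v, ddof=1) == 0 for v in by_group.values()) and \
            len({float(np.mean(v)) for v in by_group.values()}) == 1:
        raise ValueError("zero within-group variance everywhere")

    f_stat, p_value = stats.f_oneway(*[by_group[g] for g in labels])

    pairwise = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    if posthoc == "tukey":
        res = pairwise_tukeyhsd(values, groups, alpha=alpha)
        for (g1, g2), p in zip(itertools.combinations(res.groupsunique, 2), res.pvalues):
            pairwise.loc[g1, g2] = pairwise.loc[g2, g1] = p
    elif posthoc == "lsd":
        n_total = values.size
        k = len(labels)
        msw = sum(np.sum((by_group[g] - np.mean(by_group[g])) ** 2) for g in labels) / (n_total - k)
        for g1, g2 in itertools.combinations(labels, 2):
            a, b = by_group[g1], by_group[g2]
            se = np.sqrt(msw * (1 / len(a) + 1 / len(b)))
            if se == 0:
                p = 1.0 if np.mean(a) == np.mean(b) else 0.0
            else:
                t = (np.mean(a) - np.mean(b)) / se
                p = 2 * stats.t.sf(abs(t), n_total - k)
            pairwise.loc[g1, g2] = pairwise.loc[g2, g1] = p
    else:
        raise ValueError("posthoc must be 'tukey' or 'lsd'")

    means = {g: float(np.mean(by_group[g])) for g in labels}
    letters = compact_letter_display(labels, pairwise, alpha=alpha, means=means)
    return GroupComparison(variable=variable, f_stat=float(f_stat), p_value=float(p_value),
                           letters=letters, posthoc=posthoc, pairwise_p=pairwise,
                           group_means=means)


# ---------------------------------------------------------------------------
# Grouped Pearson correlations
# ---------------------------------------------------------------------------


def pearson_by_group(data: pd.DataFrame, group_assignment: dict[str, tuple[str, ...]] | None = None,
                     treatment_col: str = "treatment") -> dict[str, dict[str, pd.DataFrame]]:
    """Pairwise Pearson r and p per sample cluster.

    ``data`` is per-replicate wide data; numeric columns enter the matrix.
    ``group_assignment`` maps cluster name -> treatments (default: the
    three ordination clusters). Variables constant within a cluster yield
    NaN r for their pairs (flagged via the returned 'constant' list).
    """
    groups = group_assignment or DEFAULT_PCA_GROUPS
    numeric = data.select_dtypes(include=[np.number]).columns.drop(
        [c for c in ("replicate",) if c in data.columns], errors="ignore"
    )
    out: dict[str, dict] = {}
    for name, members in groups.items():
        sub = data[data[treatment_col].isin(members)][numeric].dropna(axis=1, how="all")
        if len(sub) < 3:
            raise ValueError(f"cluster {name!r} has fewer than 3 samples")
        cols = list(sub.columns)
        r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
        p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
        constant = [c for c in cols if sub[c].nunique() <= 1]
        for c1, c2 in itertools.combinations(cols, 2):
            pair = sub[[c1, c2]].dropna()
            if c1 in constant or c2 in constant or len(pair) < 3:
                r.loc[c1, c2] = r.loc[c2, c1] = np.nan
                p.loc[c1, c2] = p.loc[c2, c1] = np.nan
                continue
            rv, pv = stats.pearsonr(pair[c1], pair[c2])
            r.loc[c1, c2] = r.loc[c2, c1] = rv
            p.loc[c1, c2] = p.loc[c2, c1] = pv
        out[name] = {"r": r, "p": p, "constant": constant, "n": len(sub)}
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCASummary:
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    loadings: pd.DataFrame  # variables × components
    scores: pd.DataFrame    # samples × components
    dropped: list[str]


def pca_summary(matrix: pd.DataFrame, standardize: bool = True) -> PCASummary:
    """PCA of a samples × variables matrix.

    Standardized (correlation-matrix) PCA by default, matching prcomp with
    scale. Constant columns are dropped with a warning entry. Sign
    convention: each loading vector's largest-magnitude element is positive.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("PCA needs >= 3 samples and >= 2 variables")
    if matrix.isna().any().any():
        raise ValueError("PCA input must have no missing values (apply listwise deletion upstream)")
    dropped = [c for c in matrix.columns if matrix[c].nunique() <= 1]
    X = matrix.drop(columns=dropped)
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / X.std(axis=0, ddof=1)
    n = len(X)
    cov = (Xc.T @ Xc) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov.values)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest |loading| positive per component
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    comp_names = [f"PC{i+1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=X.columns, columns=comp_names)
    scores = pd.DataFrame(Xc.values @ eigvec, index=X.index, columns=comp_names)
    total = eigval.sum()
    frac = eigval / total if total > 0 else np.full_like(eigval, np.nan)
    return PCASummary(eigenvalues=eigval, explained_fraction=frac,
                      loadings=loadings, scores=scores, dropped=dropped)


def residual_normality(values, groups) -> dict:
    """Shapiro–Wilk screen on within-group-centered residuals.

    Diagnostic only — never gates the ANOVA.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    resid = np.concatenate([
        values[groups == g] - np.mean(values[groups == g]) for g in pd.unique(groups)
    ])
    w, p = stats.shapiro(resid)
    return {"w": float(w), "p": float(p), "normal_at_0.05": bool(p >= 0.05)}
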