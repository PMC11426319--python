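"""Ecoenzymatic stoichiometry: SMA type-II regression, TER, CUE,
homeostasis and nutrient-limitation tests.

The threshold elemental ratio (TER) is the resource C:X ratio at which a
microbial community's metabolism switches between energy (C) limitation and
nutrient (X = N or P) limitation:

    TER_C:P = (EEA_C:P * B_C:P) / rho0,   EEA_C:P = BG / (Phm + Phd)
    TER_C:N = (EEA_C:N * B_C:N) / n0,     EEA_C:N = BG / NAG

where B_C:X is the microbial biomass ratio and the normalization constants
rho0 and n0 come from the intercepts of standardized major axis (SMA)
regressions between ln enzyme activities. Carbon use efficiency follows a
saturating model of a scarcity index S:

    S_C:X = (1 / EEA_C:X) * (B_C:X / L_C:X)
    CUE_C:X = CUE_MAX * S_C:X / (S_C:X + KX),  CUE = sqrt(CUE_C:N * CUE_C:P)

with CUE_MAX = 0.6 (thermodynamic bound) and KX = 0.5. Homeostasis of
biomass stoichiometry is tested by regressing ln(biomass ratio) on
ln(resource ratio): a slope distinguishable from 0 marks a non-homeostatic
community. The limitation verdict compares ln TER against the ln resource
ratio with a two-sample t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .experiment_model import StoichConstants

__all__ = [
    "SMAFit",
    "sma_fit",
    "normalization_constants",
    "eea_cp",
    "eea_cn",
    "ter",
    "cue_cx",
    "cue_overall",
    "HomeostasisResult",
    "homeostasis_test",
    "limitation_verdict",
    "TERResult",
    "CUEResult",
    "treatment_stoichiometry",
]


# ---------------------------------------------------------------------------
# SMA (standardized major axis, a.k.a. reduced major axis) regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SMAFit:
    """Fit of y = intercept + slope * x by standardized major axis.

    |slope| = sd(y)/sd(x), signed by the correlation; p_corr is the p-value
    of the test r != 0 (the slope of an SMA cannot itself be zero, so
    significance statements ride on the correlation).
    """

    slope: float
    intercept: float
    r: float
    p_corr: float
    n: int
    x_name: str = "x"
    y_name: str = "y"


def sma_fit(x, y, x_name: str = "x", y_name: str = "y") -> SMAFit:
    """Standardized major axis (type II) regression of y on x.

    slope = sign(r) * sd(y)/sd(x); intercept = mean(y) - slope*mean(x).
    Requires n >= 3 and nonzero variance on both axes. When r == 0 the
    slope sign convention is positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise ValueError("SMA requires at least 3 points")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate axis: zero variance")
    r, p = stats.pearsonr(x, y)
    slope = float(np.copysign(sy / sx, r) if r != 0 else sy / sx)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return SMAFit(slope=slope, intercept=intercept, r=float(r), p_corr=float(p),
                  n=int(n), x_name=x_name, y_name=y_name)


def normalization_constants(
    panels: pd.DataFrame,
    intercept_scale: str = "ln",
) -> tuple[float, float]:
    """TER normalization constants (rho0, n0) from per-sample enzyme panels.

    ``panels`` must carry positive columns bg, nag, phm, phd. rho0 comes
    from the SMA of y = ln(BG) on x = ln(Phm + Phd); n0 from y = ln(BG) on
    x = ln(NAG). With ``intercept_scale='ln'`` (default) the constants are
    the exponentiated intercepts, so TER computed on the raw-ratio scale is
    dimensionless; ``'raw'`` returns the intercepts themselves (the literal
    reading of "the intercept ... is the normalization constant").

    Samples with any non-positive activity are excluded with a warning; at
    least 3 usable samples are required.
    """
    if intercept_scale not in ("ln", "raw"):
        raise ValueError("intercept_scale must be 'ln' or 'raw'")
    needed = ["bg", "nag", "phm", "phd"]
    df = panels[needed].astype(float).copy()
    df["phm_phd"] = df["phm"] + df["phd"]
    usable = (df[["bg", "nag", "phm_phd"]] > 0).all(axis=1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} sample(s) with non-positive activity from ln-ln fits")
    df = df[usable]
    if len(df) < 3:
        raise ValueError("fewer than 3 usable samples for normalization constants")
    fit_p = sma_fit(np.log(df["phm_phd"]), np.log(df["bg"]), "ln(Phm+Phd)", "ln(BG)")
    fit_n = sma_fit(np.log(df["nag"]), np.log(df["bg"]), "ln(NAG)", "ln(BG)")
    if intercept_scale == "ln":
        return math.exp(fit_p.intercept), math.exp(fit_n.intercept)
    return fit_p.intercept, fit_n.intercept


# ---------------------------------------------------------------------------
# EEA ratios, TER, CUE
# ---------------------------------------------------------------------------


def eea_cp(bg: float, phm: float, phd: float, include_phd: bool = True) -> float:
    """Ecoenzymatic C:P activity ratio BG/(Phm+Phd); ``include_phd=False``
    gives the BG/Phm variant."""
    den = phm + phd if include_phd else phm
    if den <= 0 or bg < 0:
        return float("nan")
    return bg / den


def eea_cn(bg: float, nag: float) -> float:
    """Ecoenzymatic C:N activity ratio BG/NAG."""
    if nag <= 0 or bg < 0:
        return float("nan")
    return bg / nag


def ter(eea_ratio: float, biomass_ratio: float, norm_const: float) -> float:
    """Threshold elemental ratio: EEA ratio × biomass ratio / normalization
    constant. NaN (flagged) if any component is not positive."""
    if not all(np.isfinite([eea_ratio, biomass_ratio, norm_const])):
        return float("nan")
    if eea_ratio <= 0 or biomass_ratio <= 0 or norm_const <= 0:
        return float("nan")
    return eea_ratio * biomass_ratio / norm_const


def cue_cx(eea: float, b_cx: float, l_cx: float,
           constants: StoichConstants | None = None) -> tuple[float, float]:
    """Scarcity index S_C:X and the saturating carbon use efficiency.

    S = (1/EEA) * (B/L); CUE = cue_max * S / (S + kx). Both are NaN when any
    input is not positive.
    """
    c = constants or StoichConstants()
    if not all(np.isfinite([eea, b_cx, l_cx])) or eea <= 0 or b_cx <= 0 or l_cx <= 0:
        return float("nan"), float("nan")
    s = (1.0 / eea) * (b_cx / l_cx)
    return s, c.cue_max * s / (s + c.kx)


def cue_overall(cue_cn: float, cue_cp: float) -> float:
    """Community CUE as the geometric mean of the C:N and C:P efficiencies."""
    if cue_cn < 0 or cue_cp < 0:
        raise ValueError("CUE components must be >= 0")
    return math.sqrt(cue_cn * cue_cp)


# ---------------------------------------------------------------------------
# Homeostasis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomeostasisResult:
    """Slope test of ln(biomass ratio) on ln(resource ratio) for one group."""

    treatment: str
    element_pair: str  # "C:P" or "C:N"
    slope: float
    intercept: float
    p_slope: float
    r2: float
    r2_adjusted: float
    n: int
    regression_kind: str  # "ols" | "sma"
    alpha: float = 0.05

    @property
    def verdict(self) -> str:
        return "non-homeostatic" if self.p_slope < self.alpha else "homeostatic"


def homeostasis_test(
    ln_resource,
    ln_biomass,
    regression_kind: str = "ols",
    alpha: float = 0.05,
    treatment: str = "",
    element_pair: str = "C:P",
) -> HomeostasisResult:
    """Test stoichiometric homeostasis for one treatment.

    Regresses y = ln(biomass ratio) on x = ln(resource ratio). Under OLS
    (default) the slope-vs-0 p-value is the standard slope t-test; under SMA
    the slope cannot be 0 by construction, so the correlation p-value
    carries the test. A slope indistinguishable from 0 (p >= alpha) means
    the community holds its biomass stoichiometry constant: homeostatic.
    """
    x = np.asarray(ln_resource, dtype=float)
    y = np.asarray(ln_biomass, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("homeostasis test requires n >= 3")
    n = x.size
    if regression_kind == "ols":
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        p_slope = float(res.pvalue)
        r2 = float(res.rvalue) ** 2
    elif regression_kind == "sma":
        fit = sma_fit(x, y)
        slope, intercept = fit.slope, fit.intercept
        p_slope = fit.p_corr
        r2 = fit.r**2
    else:
        raise ValueError("regression_kind must be 'ols' or 'sma'")
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return HomeostasisResult(
        treatment=treatment, element_pair=element_pair, slope=slope,
        intercept=intercept, p_slope=p_slope, r2=r2, r2_adjusted=r2_adj,
        n=int(n), regression_kind=regression_kind, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Limitation verdict
# ---------------------------------------------------------------------------


def limitation_verdict(ln_ter_values, ln_resource_values, alpha: float = 0.05,
                       welch: bool = False) -> dict:
    """Compare ln TER against the ln resource ratio for one treatment.

    Two-sample Student's t (equal variance by default; Welch by flag).
    TER significantly below the resource ratio: the community sits past its
    threshold — nutrient-limited, immobilization dominates. Significantly
    above: energy-limited, mineralization dominates. No difference:
    co-limited.
    """
    a = np.asarray(ln_ter_values, dtype=float)
    b = np.asarray(ln_resource_values, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both samples")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return {"verdict": "co-limited", "t": 0.0, "p": 1.0,
                    "mean_ln_ter": float(np.mean(a)), "mean_ln_resource": float(np.mean(b))}
        raise ValueError("degenerate variance in both samples")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if p < alpha:
        verdict = "nutrient-limited (immobilization)" if np.mean(a) < np.mean(b) \
            else "energy-limited (mineralization)"
    else:
        verdict = "co-limited"
    return {"verdict": verdict, "t": float(t), "p": float(p),
            "mean_ln_ter": float(np.mean(a)), "mean_ln_resource": float(np.mean(b))}


# ---------------------------------------------------------------------------
# Treatment-level orchestration
# ---------------------------------------------------------------------------


@dataclass
class TERResult:
    treatment: str
    ter_cp: float
    ter_cn: float
    ln_ter_cp: float
    ln_ter_cn: float


@dataclass
class CUEResult:
    treatment: str
    s_cp: float
    s_cn: float
    cue_cp: float
    cue_cn: float
    cue: float


def treatment_stoichiometry(
    post: pd.DataFrame,
    constants: StoichConstants | None = None,
    regression_kind: str = "ols",
    alpha: float = 0.05,
    welch: bool = False,
    include_phd_in_cue: bool = True,
    intercept_scale: str = "ln",
) -> dict[str, pd.DataFrame]:
    """Run the full stoichiometric analysis over post-incubation replicates.

    ``post`` is wide per-replicate data with columns treatment, replicate,
    bg, nag, phm, phd, cmic, nmic, pmic, doc, don, dop. Normalization
    constants are fit over the pooled panel (all treatments), matching the
    single-soil design; everything downstream is per replicate, then
    summarized per treatment as means of ln TER / CUE.

    Returns DataFrames: 'replicates' (per-replicate TER/CUE components),
    'ter' and 'cue' (per-treatment summaries), 'homeostasis' (per treatment
    × element pair), 'limitation' (per treatment × element pair).
    """
    c = constants or StoichConstants()
    rho0, n0 = c.rho0, c.n0
    if rho0 is None or n0 is None:
        fit_rho0, fit_n0 = normalization_constants(post, intercept_scale=intercept_scale)
        rho0 = rho0 if rho0 is not None else fit_rho0
        n0 = n0 if n0 is not None else fit_n0

    rows = []
    for _, r in post.iterrows():
        b_cp = r["cmic"] / r["pmic"] if r.get("pmic", 0) > 0 else np.nan
        b_cn = r["cmic"] / r["nmic"] if r.get("nmic", 0) > 0 else np.nan
        l_cp = r["doc"] / r["dop"] if r.get("dop", 0) > 0 else np.nan
        l_cn = r["doc"] / r["don"] if r.get("don", 0) > 0 else np.nan
        e_cp = eea_cp(r["bg"], r["phm"], r["phd"])
        e_cn = eea_cn(r["bg"], r["nag"])
        t_cp = ter(e_cp, b_cp, rho0)
        t_cn = ter(e_cn, b_cn, n0)
        e_cp_cue = e_cp if include_phd_in_cue else eea_cp(r["bg"], r["phm"], r["phd"], include_phd=False)
        s_cp, cue_p = cue_cx(e_cp_cue, b_cp, l_cp, c)
        s_cn, cue_n = cue_cx(e_cn, b_cn, l_cn, c)
        cue = cue_overall(cue_n, cue_p) if np.isfinite(cue_n) and np.isfinite(cue_p) else np.nan
        rows.append({
            "treatment": r["treatment"], "replicate": r["replicate"],
            "b_cp": b_cp, "b_cn": b_cn, "l_cp": l_cp, "l_cn": l_cn,
            "eea_cp": e_cp, "eea_cn": e_cn,
            "ter_cp": t_cp, "ter_cn": t_cn,
            "ln_ter_cp": np.log(t_cp) if t_cp > 0 else np.nan,
            "ln_ter_cn": np.log(t_cn) if t_cn > 0 else np.nan,
            "ln_l_cp": np.log(l_cp) if l_cp > 0 else np.nan,
            "ln_l_cn": np.log(l_cn) if l_cn > 0 else np.nan,
            "ln_b_cp": np.log(b_cp) if b_cp > 0 else np.nan,
            "ln_b_cn": np.log(b_cn) if b_cn > 0 else np.nan,
            "s_cp": s_cp, "s_cn": s_cn,
            "cue_cp": cue_p, "cue_cn": cue_n, "cue": cue,
        })
    reps = pd.DataFrame(rows)

    ter_summary = reps.groupby("treatment")[["ter_cp", "ter_cn", "ln_ter_cp", "ln_ter_cn"]] \
        .agg(["mean", "sem"])
    cue_summary = reps.groupby("treatment")[["s_cp", "s_cn", "cue_cp", "cue_cn", "cue"]] \
        .agg(["mean", "sem"])

    homeo_rows, limit_rows = [], []
    for treatment, grp in reps.groupby("treatment"):
        for pair, lx, ly, lt in (("C:P", "ln_l_cp", "ln_b_cp", "ln_ter_cp"),
                                 ("C:N", "ln_l_cn", "ln_b_cn", "ln_ter_cn")):
            sub = grp[[lx, ly, lt]].dropna(subset=[lx, ly])
            if len(sub) >= 3 and sub[lx].nunique() > 1:
                h = homeostasis_test(sub[lx], sub[ly], regression_kind=regression_kind,
                                     alpha=alpha, treatment=str(treatment), element_pair=pair)
                homeo_rows.append({
                    "treatment": treatment, "element_pair": pair, "slope": h.slope,
                    "intercept": h.intercept, "p_slope": h.p_slope, "r2": h.r2,
                    "r2_adjusted": h.r2_adjusted, "n": h.n, "verdict": h.verdict,
                    "regression_kind": h.regression_kind,
                })
            tvals = grp[lt].dropna()
            lvals = grp[lx].dropna()
            if len(tvals) >= 2 and len(lvals) >= 2:
                v = limitation_verdict(tvals, lvals, alpha=alpha, welch=welch)
                limit_rows.append({"treatment": treatment, "element_pair": pair, **v})

    return {
        "replicates": reps,
        "ter": ter_summary,
        "cue": cue_summary,
        "homeostasis": pd.DataFrame(homeo_rows),
        "limitation": pd.DataFrame(limit_rows),
        "constants": pd.DataFrame([{"rho0": rho0, "n0": n0, "cue_max": c.cue_max, "kx": c.kx,
                                    "intercept_scale": intercept_scale}]),
    }
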