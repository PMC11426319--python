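"""Synthetic incubation experiments with the statistical structure the
analysis assumes.

The generator emulates a 6-treatment × 5-replicate soil P-addition
incubation: per-treatment, per-analyte targets are the published treatment
means ± standard errors of the study this pipeline reimplements (n = 5, so
per-replicate sd is reconstructed as SE·√5). Each replicate carries paired
pre/post measurements linked by a shared replicate-level random effect, a
six-enzyme activity panel, fumigated/unfumigated extract pairs that invert
exactly to the intended biomass pools through the k-factors, and an
alkali-trap titration series whose accumulated CO2-C equals the replicate's
drawn mineralization target.

Two optional layers impose known stoichiometric structure for parameter-
recovery studies:

* structured enzyme coupling (``rho0``/``n0`` set): ln BG is generated as
  ln rho0 + ln(Phm+Phd) + noise and ln NAG as ln BG − ln n0 + noise, so the
  SMA-derived normalization constants have known generating values;
* per-treatment homeostasis slopes: ln(biomass ratio) is generated as an
  affine function of ln(resource ratio) with a chosen slope and an R²
  target, the phytate-like default being slope −0.2 (C:P);
* per-treatment ln TER − ln(resource ratio) separations (``ter_offset_ln``)
  for limitation-verdict power studies.

What the generator does NOT emulate: mechanistic mineralization dynamics,
replicate-level covariance between chemistry analytes (independent within
phase by default), or assay-specific measurement error structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .experiment_model import (
    ANALYTE_UNITS,
    ENZYMES,
    TREATMENTS,
    IncubationDataset,
    canonical_treatment,
)

__all__ = [
    "SyntheticConfig",
    "TitrationSchedule",
    "generate_experiment",
    "inject_effects",
    "POST_CHEMISTRY",
    "PRE_CHEMISTRY",
    "SEA_POST",
    "BIOMASS_RATIO_TARGETS",
    "CO2_ACCUM",
    "post_enzyme_targets",
]

# ---------------------------------------------------------------------------
# Study-condition targets: per-treatment (mean, SE) at n = 5
# ---------------------------------------------------------------------------

_T = TREATMENTS  # ("control", "MAP", "CaH2PO4", "RNA", "AMP", "phytate")


def _by_treatment(vals: list[tuple[float, float]]) -> dict[str, tuple[float, float]]:
    return dict(zip(_T, vals))


#: Post-incubation chemistry and biomass: analyte -> treatment -> (mean, SE),
#: µg g⁻¹ dry soil except pH.
POST_CHEMISTRY: dict[str, dict[str, tuple[float, float]]] = {
    "ph": _by_treatment([(8.1, 0.12), (8.1, 0.06), (8.1, 0.05), (8.2, 0.04), (8.1, 0.03), (8.1, 0.06)]),
    "cmic": _by_treatment([(1283, 76), (1027, 69), (1057, 78), (673, 99), (611, 93), (690, 13)]),
    "nmic": _by_treatment([(45, 9), (39, 4), (43, 6), (58, 6), (46, 5), (50, 12)]),
    "pmic": _by_treatment([(4.56, 0.79), (15.44, 3), (20.01, 4.47), (36.95, 5), (27.22, 1), (10, 2)]),
    "doc": _by_treatment([(164, 24), (95, 12), (189, 67), (50, 6), (30, 4), (64, 5)]),
    "don": _by_treatment([(0.74, 0.15), (0.57, 0.12), (2.81, 0.08), (2.17, 0.16), (0.68, 0.16), (0.69, 0.06)]),
    "dop": _by_treatment([(0.13, 0.02), (0.38, 0.06), (0.57, 0.11), (0.72, 0.07), (0.7, 0.08), (0.5, 0.12)]),
    "nh4": _by_treatment([(0, 0), (0.004, 0.004), (0, 0), (0.062, 0.062), (0, 0), (0, 0)]),
    "no3": _by_treatment([(57, 6), (69, 9), (51, 6), (102, 7), (135, 7), (58, 7)]),
    "hpo4": _by_treatment([(6.3, 0.96), (15.2, 2), (17.3, 5), (10.6, 1.43), (11.9, 1.35), (10.8, 1)]),
}

#: Accumulated CO2-C over the 19-day incubation: treatment -> (mean, SE).
CO2_ACCUM: dict[str, tuple[float, float]] = _by_treatment(
    [(739, 6), (831, 11), (781, 17), (863, 9), (950, 17), (802, 4)]
)

#: Pre-incubation baseline (single soil, before treatments diverge):
#: analyte -> (mean, SE).
PRE_CHEMISTRY: dict[str, tuple[float, float]] = {
    "ph": (8.1, 0.017),
    "moisture_fraction": (0.29, 0.006),
    "doc": (28, 2.9),
    "don": (1.64, 0.51),
    "dop": (0.28, 0.084),
    "nh4": (0.22, 0.216),
    "no3": (15, 1.5),
    "hpo4": (3.4, 1.479),
    "cmic": (1190, 192),
    "nmic": (70, 5.4),
    "pmic": (5, 0.86),
}

#: Pre-incubation enzyme activities (µmol g⁻¹ h⁻¹): enzyme -> (mean, SE).
PRE_ENZYMES: dict[str, tuple[float, float]] = {
    "phm": (0.030, 0.015),
    "phd": (0.157, 0.041),
    "phy": (0.056, 0.056),
    "nag": (0.008, 0.003),
    "bg": (0.005, 0.002),
    "pox": (0.196, 0.046),
}

#: Post-incubation specific enzyme activity (µmol per mg Cmic per h):
#: enzyme -> treatment -> (mean, SE). Raw post activities are reconstructed
#: as SEA × mean Cmic (mg), since SEA and biomass are what the study reports.
SEA_POST: dict[str, dict[str, tuple[float, float]]] = {
    "bg": _by_treatment([(0.069, 0.02), (0.06, 0.014), (0.049, 0.012), (0.102, 0.038), (0.139, 0.057), (0.132, 0.074)]),
    "pox": _by_treatment([(0.244, 0.04), (0.171, 0.05), (0.082, 0.052), (0.493, 0.082), (0.371, 0.195), (0.540, 0.134)]),
    "nag": _by_treatment([(0.014, 0.006), (0.027, 0.006), (0.030, 0.007), (0.004, 0.001), (0.001, 0.001), (0.066, 0.033)]),
    "phm": _by_treatment([(0.013, 0.007), (0.025, 0.015), (0.16, 0.134), (0.068, 0.017), (0.097, 0.054), (0.052, 0.017)]),
    "phd": _by_treatment([(0.164, 0.01), (0.171, 0.018), (0.167, 0.015), (0.429, 0.123), (0.408, 0.078), (0.480, 0.13)]),
    "phy": _by_treatment([(0.896, 0.31), (0.403, 0.207), (0.793, 0.415), (0.696, 0.373), (1.213, 0.61), (0.497, 0.32)]),
}

#: Post-incubation biomass ratio targets (mass basis): used to calibrate the
#: structured homeostasis layer.
BIOMASS_RATIO_TARGETS: dict[str, dict[str, float]] = {
    "cmic_pmic": dict(zip(_T, [310.0, 82.0, 68.0, 18.0, 25.0, 58.0])),
    "cmic_nmic": dict(zip(_T, [34.0, 28.0, 26.0, 11.0, 15.0, 14.0])),
}


def post_enzyme_targets() -> dict[str, dict[str, tuple[float, float]]]:
    """Raw post-incubation enzyme activity targets (µmol g⁻¹ h⁻¹) derived
    from the SEA targets and mean Cmic per treatment."""
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for enz, per_t in SEA_POST.items():
        out[enz] = {}
        for t, (m, se) in per_t.items():
            cmic_mg = POST_CHEMISTRY["cmic"][t][0] / 1000.0
            out[enz][t] = (m * cmic_mg, se * cmic_mg)
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class TitrationSchedule:
    """Trap titration schedule: every third day over the 19-day incubation,
    closing on day 19."""

    days: tuple[float, ...] = (3, 6, 9, 12, 15, 18, 19)
    v_blank: float = 10.0
    hcl_molarity: float = 1.0
    naoh_volume: float = 10.0

    def __post_init__(self) -> None:
        if any(d <= 0 or d > 19 for d in self.days):
            raise ValueError("titration days must lie in (0, 19]")

    @property
    def interval_weights(self) -> np.ndarray:
        edges = np.concatenate([[0.0], np.asarray(self.days, dtype=float)])
        w = np.diff(edges)
        return w / w.sum()


@dataclass
class SyntheticConfig:
    """Knobs of the generator. Defaults ARE the study conditions."""

    n_replicates: int = 5
    seed: int = 0
    noise_family: str = "truncated-normal"  # or "lognormal"
    replicate_correlation: float = 0.5
    table_n: int = 5  # the n behind the published SEs
    soil_dry_mass: float = 71.0  # g dry soil per 100 g microcosm at 29% moisture
    titration: TitrationSchedule = field(default_factory=TitrationSchedule)
    # structured enzyme coupling (None -> marginal lognormal panel)
    rho0: float | None = None
    n0: float | None = None
    coupling_noise_sd: float = 0.1
    # per-treatment generating slopes of ln(biomass ratio) on ln(resource ratio)
    homeostasis_slope_cp: dict[str, float] = field(default_factory=lambda: {"phytate": -0.2})
    homeostasis_slope_cn: dict[str, float] = field(default_factory=lambda: {"phytate": -2.5})
    homeostasis_r2: float = 0.9
    # per-treatment ln TER − ln(DOC:DOP) separation (needs rho0 set)
    ter_offset_ln: dict[str, float] = field(default_factory=dict)
    treatments: tuple[str, ...] = TREATMENTS

    def __post_init__(self) -> None:
        if self.noise_family not in ("truncated-normal", "lognormal"):
            raise ValueError("noise_family must be 'truncated-normal' or 'lognormal'")
        if not (0 <= self.replicate_correlation < 1):
            raise ValueError("replicate_correlation must lie in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.ter_offset_ln and self.rho0 is None:
            raise ValueError("ter_offset_ln requires structured enzymes (set rho0 and n0)")
        self.treatments = tuple(canonical_treatment(t) for t in self.treatments)

    def sd(self, se: float) -> float:
        return se * np.sqrt(self.table_n)


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------


def _check_normal_feasible(mean: float, sd: float) -> None:
    # more than half the mass below zero is unrepresentable for a pool
    if sd > 0 and mean <= 0:
        raise ValueError(
            f"normal family puts > 50% mass below 0 for mean={mean}, sd={sd}; "
            "use noise_family='lognormal'"
        )


def _transform(z: np.ndarray, mean: float, sd: float, family: str) -> np.ndarray:
    """Map standard-normal draws to the target marginal, preserving rank
    correlation across phases."""
    z = np.asarray(z, dtype=float)
    if sd == 0:
        return np.full_like(z, float(mean))
    if family == "lognormal":
        if mean <= 0:
            return np.zeros_like(z)
        cv = sd / mean
        sigma2 = np.log1p(cv * cv)
        mu = np.log(mean) - sigma2 / 2.0
        return np.exp(mu + np.sqrt(sigma2) * z)
    _check_normal_feasible(mean, sd)
    a = (0.0 - mean) / sd  # truncate at zero
    return stats.truncnorm.ppf(stats.norm.cdf(z), a, np.inf, loc=mean, scale=sd)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_experiment(config: SyntheticConfig | None = None) -> tuple[IncubationDataset, dict]:
    """Generate a complete synthetic incubation dataset plus its generating
    ground truth. Fully reproducible from ``config.seed``."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.replicate_correlation
    n = cfg.n_replicates
    fam = cfg.noise_family
    enzyme_post = post_enzyme_targets()

    rows: list[dict] = []
    titr_rows: list[dict] = []
    truth: dict = {
        "seed": cfg.seed,
        "n_replicates": n,
        "noise_family": fam,
        "rho0": cfg.rho0,
        "n0": cfg.n0,
        "homeostasis_slope_cp": dict(cfg.homeostasis_slope_cp),
        "homeostasis_slope_cn": dict(cfg.homeostasis_slope_cn),
        "ter_offset_ln": dict(cfg.ter_offset_ln),
        "per_treatment": {},
    }

    def push(t: str, rep: int, phase: str, analyte: str, value: float) -> None:
        rows.append({
            "sample_id": f"{t}-{rep}-{phase}",
            "treatment": t, "replicate": rep, "phase": phase,
            "analyte": analyte, "value": float(value), "unit": ANALYTE_UNITS[analyte],
        })

    chem_analytes = ("doc", "don", "dop", "no3", "nh4", "hpo4")

    for t in cfg.treatments:
        tt: dict = {"post": {}, "pre": {}}
        # --- paired chemistry, biomass, pH: shared replicate effect ---------
        draws_post: dict[str, np.ndarray] = {}
        draws_pre: dict[str, np.ndarray] = {}
        for analyte in ("ph",) + chem_analytes + ("cmic", "nmic", "pmic"):
            z_shared = rng.standard_normal(n)
            z_pre = rho * z_shared + np.sqrt(1 - rho * rho) * rng.standard_normal(n)
            z_post = rho * z_shared + np.sqrt(1 - rho * rho) * rng.standard_normal(n)
            m_pre, se_pre = PRE_CHEMISTRY[analyte]
            m_post, se_post = POST_CHEMISTRY[analyte][t]
            draws_pre[analyte] = _transform(z_pre, m_pre, cfg.sd(se_pre), fam)
            draws_post[analyte] = _transform(z_post, m_post, cfg.sd(se_post), fam)
        moisture = _transform(
            rng.standard_normal(n),
            PRE_CHEMISTRY["moisture_fraction"][0],
            cfg.sd(PRE_CHEMISTRY["moisture_fraction"][1]),
            "truncated-normal",
        )

        # --- enzyme panel (post) --------------------------------------------
        enz_post: dict[str, np.ndarray] = {}
        for e in ENZYMES:
            m, se = enzyme_post[e][t]
            enz_post[e] = _transform(rng.standard_normal(n), m, cfg.sd(se), fam)
        enz_pre: dict[str, np.ndarray] = {}
        for e in ENZYMES:
            m, se = PRE_ENZYMES[e]
            enz_pre[e] = _transform(rng.standard_normal(n), m, cfg.sd(se), fam)

        # --- structured homeostasis layer -----------------------------------
        # ln(biomass ratio) = alpha + beta * ln(resource ratio) + eps, with
        # alpha calibrated to the treatment's biomass-ratio target and eps
        # scaled so the generating R^2 matches homeostasis_r2.
        ln_l_cp = np.log(draws_post["doc"] / draws_post["dop"])
        ln_l_cn = np.log(draws_post["doc"] / draws_post["don"])
        slope_cp = float(cfg.homeostasis_slope_cp.get(t, 0.0))
        slope_cn = float(cfg.homeostasis_slope_cn.get(t, 0.0))
        if slope_cp != 0.0:
            target = BIOMASS_RATIO_TARGETS["cmic_pmic"][t]
            alpha = np.log(target) - slope_cp * float(np.mean(ln_l_cp))
            sd_x = float(np.std(ln_l_cp, ddof=1)) if n > 1 else 0.0
            sd_eps = abs(slope_cp) * sd_x * np.sqrt(max(1.0 / cfg.homeostasis_r2 - 1.0, 0.0))
            ln_b_cp = alpha + slope_cp * ln_l_cp + sd_eps * rng.standard_normal(n)
            draws_post["pmic"] = draws_post["cmic"] / np.exp(ln_b_cp)
            tt["homeostasis_alpha_cp"] = float(alpha)
        if slope_cn != 0.0:
            target = BIOMASS_RATIO_TARGETS["cmic_nmic"][t]
            alpha = np.log(target) - slope_cn * float(np.mean(ln_l_cn))
            sd_x = float(np.std(ln_l_cn, ddof=1)) if n > 1 else 0.0
            sd_eps = abs(slope_cn) * sd_x * np.sqrt(max(1.0 / cfg.homeostasis_r2 - 1.0, 0.0))
            ln_b_cn = alpha + slope_cn * ln_l_cn + sd_eps * rng.standard_normal(n)
            draws_post["nmic"] = draws_post["cmic"] / np.exp(ln_b_cn)
            tt["homeostasis_alpha_cn"] = float(alpha)

        # --- structured enzyme coupling / TER separation --------------------
        if cfg.rho0 is not None:
            eps = cfg.coupling_noise_sd * rng.standard_normal(n)
            offset = cfg.ter_offset_ln.get(t)
            if offset is not None:
                # pins E[ln TER_C:P − ln(DOC:DOP)] at `offset`
                ln_b_cp_now = np.log(draws_post["cmic"] / draws_post["pmic"])
                enz_post["bg"] = np.exp(
                    np.log(cfg.rho0) + np.log(enz_post["phm"] + enz_post["phd"])
                    + offset + ln_l_cp - ln_b_cp_now + eps
                )
            else:
                enz_post["bg"] = np.exp(
                    np.log(cfg.rho0) + np.log(enz_post["phm"] + enz_post["phd"]) + eps
                )
            if cfg.n0 is not None:
                eps2 = cfg.coupling_noise_sd * rng.standard_normal(n)
                enz_post["nag"] = np.exp(np.log(enz_post["bg"]) - np.log(cfg.n0) + eps2)

        # --- titration: distribute the replicate's CO2 target over intervals
        m_co2, se_co2 = CO2_ACCUM[t]
        co2_targets = _transform(rng.standard_normal(n), m_co2, cfg.sd(se_co2), fam)
        weights = cfg.titration.interval_weights

        # --- emit rows -------------------------------------------------------
        for i in range(n):
            rep = i + 1
            for phase, chem, enz in (("pre", draws_pre, enz_pre), ("post", draws_post, enz_post)):
                for analyte in chem_analytes:
                    push(t, rep, phase, analyte, chem[analyte][i])
                push(t, rep, phase, "ph", chem["ph"][i])
                push(t, rep, phase, "moisture_fraction", moisture[i])
                push(t, rep, phase, "soil_dry_mass", cfg.soil_dry_mass)
                for a in ("cmic", "nmic", "pmic"):
                    push(t, rep, phase, a, chem[a][i])
                # fumigated/unfumigated extract pairs that invert exactly
                for a, k, base in (("c", 0.45, 40.0), ("n", 0.54, 8.0), ("p", 0.4, 2.0)):
                    pool = chem[{"c": "cmic", "n": "nmic", "p": "pmic"}[a]][i]
                    push(t, rep, phase, f"unfumigated_{a}", base)
                    push(t, rep, phase, f"fumigated_{a}", base + k * pool)
                for e in ENZYMES:
                    push(t, rep, phase, e, enz[e][i])
            per_interval = co2_targets[i] * weights
            v_diff = per_interval * cfg.soil_dry_mass / (cfg.titration.hcl_molarity * 6.0 * 1000.0)
            for day, dv in zip(cfg.titration.days, v_diff):
                titr_rows.append({
                    "treatment": t, "replicate": rep, "day": float(day),
                    "v_blank": cfg.titration.v_blank,
                    "v_sample": cfg.titration.v_blank - dv,
                    "hcl_molarity": cfg.titration.hcl_molarity,
                    "naoh_volume": cfg.titration.naoh_volume,
                    "soil_dry_mass": cfg.soil_dry_mass,
                })

        tt["post"] = {a: POST_CHEMISTRY[a][t] for a in POST_CHEMISTRY}
        tt["co2_accum_target"] = (m_co2, se_co2)
        tt["co2_accum_drawn"] = co2_targets.tolist()
        tt["homeostasis_slope_cp"] = slope_cp
        tt["homeostasis_slope_cn"] = slope_cn
        truth["per_treatment"][t] = tt

    measurements = pd.DataFrame(rows)
    titration = pd.DataFrame(titr_rows)
    return IncubationDataset(measurements=measurements, titration=titration), truth


# ---------------------------------------------------------------------------
# Effect injection
# ---------------------------------------------------------------------------


def inject_effects(dataset: IncubationDataset, effect_spec: list[Mapping]) -> IncubationDataset:
    """Apply deterministic shifts for power studies.

    Each effect is a mapping with keys ``treatment``, ``analyte``, ``mode``
    ("add" | "mul"), ``value`` and optional ``phase``. Unknown analytes are
    an error; a zero additive / unit multiplicative shift is a no-op.
    """
    df = dataset.measurements.copy()
    known = set(df["analyte"].unique())
    for eff in effect_spec:
        analyte = eff["analyte"]
        if analyte not in known:
            raise ValueError(f"unknown analyte {analyte!r}")
        t = canonical_treatment(eff["treatment"])
        mode = eff.get("mode", "add")
        value = float(eff["value"])
        mask = (df["treatment"] == t) & (df["analyte"] == analyte)
        if "phase" in eff:
            mask &= df["phase"] == eff["phase"]
        if mode == "add":
            df.loc[mask, "value"] += value
        elif mode == "mul":
            df.loc[mask, "value"] *= value
        else:
            raise ValueError("mode must be 'add' or 'mul'")
    return IncubationDataset(measurements=df, titration=dataset.titration.copy())
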