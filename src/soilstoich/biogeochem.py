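"""Deterministic derivations from raw incubation measurements.

Everything here is closed-form arithmetic: chloroform fumigation–extraction
biomass, CO2-C from alkali-trap titrations, accumulated mineralization and
the metabolic quotient (qCO2), pre/post pool changes, net nitrification,
mass-basis elemental ratios, and specific enzyme activity (SEA, activity per
mg biomass C). Per-replicate quantities are computed first and summarized
afterwards (mean of per-replicate values), so nonlinear quantities such as
qCO2 and ratios are never computed from group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiment_model import (
    ENZYMES,
    BIOMASS_ANALYTES,
    POOL_ANALYTES,
    IncubationDataset,
    TitrationSeries,
)

__all__ = [
    "fumigation_biomass",
    "titration_co2c",
    "accumulate_mineralization",
    "metabolic_quotient",
    "net_change",
    "net_nitrification",
    "element_ratio",
    "specific_enzyme_activity",
    "DerivedSample",
    "derive_replicates",
    "summarize_treatments",
    "RATIO_DEFS",
]

#: mg of CO2-derived C per meq of NaOH consumed by trapped CO2.
#: CO2 + 2 NaOH -> Na2CO3 (carbonate then precipitated with BaCl2), so each
#: mmol CO2 consumes 2 meq alkalinity and carries 12 mg C: 12/2 = 6.
MG_C_PER_MEQ = 6.0

#: Ratios reported per sample, as (name, numerator, denominator).
RATIO_DEFS: tuple[tuple[str, str, str], ...] = (
    ("doc_don", "doc", "don"),
    ("doc_dop", "doc", "dop"),
    ("don_dop", "don", "dop"),
    ("cmic_nmic", "cmic", "nmic"),
    ("cmic_pmic", "cmic", "pmic"),
    ("nmic_pmic", "nmic", "pmic"),
)


def fumigation_biomass(fumigated: float, unfumigated: float, k: float) -> float:
    """Biomass pool from a fumigated/unfumigated extract pair.

    Returns ``(fumigated - unfumigated) / k`` where ``k`` is the extraction
    efficiency (kEC 0.45 for C, kEN 0.54 for N, Kp 0.4 for P). A negative
    difference is returned as computed — downstream ratio arithmetic treats
    negative biomass as missing rather than clamping, which would bias
    pre/post differences.
    """
    if k <= 0 or k > 1:
        raise ValueError("conversion factor k must lie in (0, 1]")
    return (fumigated - unfumigated) / k


def titration_co2c(series: TitrationSeries) -> np.ndarray:
    """Per-interval CO2-C (µg per g dry soil) from a trap titration series.

    For interval *i* the trapped CO2-C is
    ``(v_blank - v_sample) [mL] * M [mmol/mL] * 6 [mg C / meq] * 1000 / mass [g]``.
    A sample titre exceeding the blank (apparent negative respiration) is
    clamped to zero with a warning — titration noise, not a sink.
    """
    if series.soil_dry_mass <= 0:
        raise ValueError("soil_dry_mass must be > 0")
    diffs = np.array([vb - vs for _, vb, vs in series.intervals], dtype=float)
    if (diffs < 0).any():
        warnings.warn("v_sample exceeds v_blank in some interval(s); clamping CO2-C to 0")
        diffs = np.clip(diffs, 0.0, None)
    return diffs * series.hcl_molarity * MG_C_PER_MEQ * 1000.0 / series.soil_dry_mass


def accumulate_mineralization(per_interval: np.ndarray | list[float]) -> tuple[float, np.ndarray]:
    """Total accumulated CO2-C and the running partial sums (for curves)."""
    arr = np.asarray(per_interval, dtype=float)
    if arr.size == 0:
        raise ValueError("empty mineralization series")
    partial = np.cumsum(arr)
    return float(partial[-1]), partial


def metabolic_quotient(co2_c_accum: float, cmic_post: float) -> float:
    """qCO2: accumulated CO2-C divided by post-incubation biomass C.

    Reported per whole incubation (unitless µg CO2-C per µg Cmic). Undefined
    (NaN) when Cmic is not positive.
    """
    if cmic_post <= 0:
        warnings.warn("qCO2 undefined for non-positive Cmic; returning NaN")
        return float("nan")
    return co2_c_accum / cmic_post


def net_change(post: float, pre: float) -> float:
    """Signed pool change over the incubation: post - pre."""
    return post - pre


def net_nitrification(no3_post: float, no3_pre: float) -> float:
    """Net nitrification: increase in available NO3 over the incubation."""
    return net_change(no3_post, no3_pre)


def element_ratio(numerator: float, denominator: float) -> float:
    """Mass-basis elemental ratio (µg/µg); NaN when the denominator is not
    positive (flagged upstream as missing)."""
    if denominator <= 0 or not np.isfinite(denominator):
        return float("nan")
    return numerator / denominator


def specific_enzyme_activity(activity: float, cmic: float) -> float:
    """SEA: enzyme activity per mg of microbial biomass C.

    ``activity`` is µmol g⁻¹ h⁻¹, ``cmic`` µg g⁻¹; the µg→mg conversion is
    internal, giving µmol (mg Cmic)⁻¹ h⁻¹.
    """
    if cmic <= 0:
        return float("nan")
    return activity / (cmic / 1000.0)


# ---------------------------------------------------------------------------
# Dataset-level derivation
# ---------------------------------------------------------------------------


@dataclass
class DerivedSample:
    """All derived quantities for one (treatment, replicate)."""

    treatment: str
    replicate: int
    co2_c_accum: float = float("nan")
    qco2: float = float("nan")
    net_nitrification: float = float("nan")
    delta_pools: dict[str, float] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)
    ratios_pre: dict[str, float] = field(default_factory=dict)
    sea: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float | str | int]:
        row: dict[str, float | str | int] = {
            "treatment": self.treatment,
            "replicate": self.replicate,
            "co2_c_accum": self.co2_c_accum,
            "qco2": self.qco2,
            "net_nitrification": self.net_nitrification,
        }
        row.update({f"delta_{k}": v for k, v in self.delta_pools.items()})
        row.update({f"ratio_{k}": v for k, v in self.ratios.items()})
        row.update({f"sea_{k}": v for k, v in self.sea.items()})
        return row


def derive_replicates(dataset: IncubationDataset, per_day_qco2: bool = False,
                      incubation_days: float = 19.0) -> pd.DataFrame:
    """Compute every per-replicate derived quantity available in a dataset.

    Stages degrade gracefully: Δ-pools need paired pre/post chemistry, qCO2
    needs titration plus post Cmic, SEA needs post enzymes plus post Cmic.
    Missing inputs leave NaN columns rather than aborting.
    """
    wide = dataset.wide()
    post = wide[wide["phase"] == "post"].set_index(["treatment", "replicate"])
    pre = wide[wide["phase"] == "pre"].set_index(["treatment", "replicate"])

    rows: list[dict] = []
    for key in post.index:
        treatment, replicate = key
        p = post.loc[key]
        d = DerivedSample(treatment=treatment, replicate=int(replicate))

        has_pre = key in pre.index
        if has_pre:
            q = pre.loc[key]
            for analyte in POOL_ANALYTES + BIOMASS_ANALYTES:
                if analyte in p.index and analyte in q.index:
                    pv, qv = p.get(analyte), q.get(analyte)
                    if pd.notna(pv) and pd.notna(qv):
                        d.delta_pools[analyte] = net_change(float(pv), float(qv))
            if pd.notna(p.get("no3")) and pd.notna(q.get("no3")):
                d.net_nitrification = net_nitrification(float(p["no3"]), float(q["no3"]))

        for name, num, den in RATIO_DEFS:
            nv, dv = p.get(num), p.get(den)
            if pd.notna(nv) and pd.notna(dv):
                d.ratios[name] = element_ratio(float(nv), float(dv))
            if has_pre:
                q = pre.loc[key]
                nv, dv = q.get(num), q.get(den)
                if pd.notna(nv) and pd.notna(dv):
                    d.ratios_pre[name] = element_ratio(float(nv), float(dv))

        cmic = p.get("cmic")
        try:
            series = dataset.titration_series(treatment, int(replicate))
        except KeyError:
            series = None
        if series is not None:
            total, _ = accumulate_mineralization(titration_co2c(series))
            d.co2_c_accum = total
            if pd.notna(cmic) and float(cmic) > 0:
                d.qco2 = metabolic_quotient(total, float(cmic))
                if per_day_qco2:
                    d.qco2 /= incubation_days

        if pd.notna(cmic) and float(cmic) > 0:
            for e in ENZYMES:
                act = p.get(e)
                if pd.notna(act):
                    d.sea[e] = specific_enzyme_activity(float(act), float(cmic))

        rows.append(d.as_row())

    return pd.DataFrame(rows)


def summarize_treatments(derived: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment mean and standard error of every derived column.

    Mean-of-per-replicate convention throughout: each replicate's qCO2, Δ
    and ratio values are averaged, never recomputed from treatment means.
    """
    value_cols = [c for c in derived.columns if c not in ("treatment", "replicate")]
    grouped = derived.groupby("treatment")[value_cols]
    mean = grouped.mean()
    se = grouped.sem()
    out = pd.concat({"mean": mean, "se": se}, axis=1)
    out = out.swaplevel(axis=1).sort_index(axis=1)
    return out
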