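"""Domain types, controlled vocabulary, units and validation for P-addition
soil incubation experiments.

The experiment is a one-factor design: six treatments (an unamended control,
two inorganic P sources and three organic P sources) applied to replicate
soil microcosms, each measured before ("pre") and after ("post") incubation.
All pool concentrations are carried internally in µg per g dry soil and all
enzyme activities in µmol per g dry soil per hour; the loaders never rescale
silently — a unit mismatch in the input is an error.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TREATMENTS",
    "P_SOURCE_CLASS",
    "ANALYTE_UNITS",
    "ENZYMES",
    "POOL_ANALYTES",
    "SampleRecord",
    "EnzymePanel",
    "BiomassPools",
    "TitrationSeries",
    "StoichConstants",
    "IncubationDataset",
    "ValidationIssue",
    "ValidationReport",
    "canonical_treatment",
    "p_source_class",
    "validate_dataset",
    "read_long_csv",
    "write_long_csv",
    "read_wide_csv",
]

# ---------------------------------------------------------------------------
# Controlled vocabulary
# ---------------------------------------------------------------------------

#: Canonical treatment labels, in the order used throughout reports.
TREATMENTS: tuple[str, ...] = ("control", "MAP", "CaH2PO4", "RNA", "AMP", "phytate")

#: Which class of P source each treatment carries.
P_SOURCE_CLASS: Mapping[str, str] = {
    "control": "none",
    "MAP": "inorganic",
    "CaH2PO4": "inorganic",
    "RNA": "organic",
    "AMP": "organic",
    "phytate": "organic",
}

# Case-insensitive aliases for the spellings that appear in the literature.
_TREATMENT_ALIASES: dict[str, str] = {
    "control": "control",
    "c": "control",
    "map": "MAP",
    "monoammonium phosphate": "MAP",
    "ammonium phosphate": "MAP",
    "cah2po4": "CaH2PO4",
    "ca(h2po4)2": "CaH2PO4",
    "cah2po42": "CaH2PO4",
    "calcium phosphate": "CaH2PO4",
    "calcium phosphate monobasic": "CaH2PO4",
    "rna": "RNA",
    "amp": "AMP",
    "adenosine monophosphate": "AMP",
    "phytate": "phytate",
    "phytic acid": "phytate",
    "phytic_acid": "phytate",
}

PHASES: tuple[str, str] = ("pre", "post")

#: Enzymes of the assay panel. BG and NAG target C and N acquisition,
#: Phm/Phd/Phy target P acquisition, POX is oxidative.
ENZYMES: tuple[str, ...] = ("bg", "nag", "phm", "phd", "phy", "pox")

#: Chemistry analytes carried per sample record.
POOL_ANALYTES: tuple[str, ...] = ("doc", "don", "dop", "no3", "nh4", "hpo4")

BIOMASS_ANALYTES: tuple[str, ...] = ("cmic", "nmic", "pmic")

#: Fixed internal unit per analyte. The long-CSV loader requires the `unit`
#: column to match these strings exactly.
ANALYTE_UNITS: dict[str, str] = {
    **{a: "ug_g" for a in POOL_ANALYTES},
    **{a: "ug_g" for a in BIOMASS_ANALYTES},
    **{e: "umol_g_h" for e in ENZYMES},
    # raw fumigation-extraction extract concentrations, per element
    **{f"{p}_{el}": "ug_g" for p in ("fumigated", "unfumigated") for el in ("c", "n", "p")},
    "ph": "unitless",
    "moisture_fraction": "fraction",
    "soil_dry_mass": "g",
}

#: Analytes that must be >= 0 (concentrations and activities). Biomass pools
#: are excluded: a fumigated extract below its unfumigated pair legitimately
#: yields a negative (flagged) biomass value.
_NONNEGATIVE = (
    set(POOL_ANALYTES)
    | set(ENZYMES)
    | {f"{p}_{el}" for p in ("fumigated", "unfumigated") for el in ("c", "n", "p")}
)


def canonical_treatment(label: str) -> str:
    """Map any recognized treatment spelling to its canonical label.

    Raises ``ValueError`` for labels outside the closed vocabulary.
    """
    key = str(label).strip().lower()
    try:
        return _TREATMENT_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown treatment label {label!r}; expected one of {TREATMENTS}"
        ) from None


def p_source_class(treatment: str) -> str:
    """Classify a treatment's P source as none / inorganic / organic."""
    return P_SOURCE_CLASS[canonical_treatment(treatment)]


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    """One replicate microcosm in one phase: soil chemistry context.

    Concentrations are µg per g dry soil.
    """

    treatment: str
    replicate_id: int
    phase: str
    doc: float
    don: float
    dop: float
    no3: float
    nh4: float
    hpo4: float
    ph: float
    moisture_fraction: float
    soil_dry_mass: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", canonical_treatment(self.treatment))
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        for name in POOL_ANALYTES:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"negative concentration: {name}={v}")
        if not (0 <= self.moisture_fraction < 1):
            raise ValueError("moisture_fraction must lie in [0, 1)")
        if not (0 < self.ph < 14):
            raise ValueError("ph must lie in (0, 14)")

    @property
    def p_source_class(self) -> str:
        return P_SOURCE_CLASS[self.treatment]


@dataclass(frozen=True)
class EnzymePanel:
    """Potential activities of the six assayed ecoenzymes for one sample.

    BG, NAG, Phm, Phd are µmol pNP g⁻¹ h⁻¹; Phy is µmol Pi g⁻¹ h⁻¹; POX is
    µmol substrate-equivalent g⁻¹ h⁻¹.
    """

    bg: float
    nag: float
    phm: float
    phd: float
    phy: float
    pox: float

    def __post_init__(self) -> None:
        for e in ENZYMES:
            if getattr(self, e) < 0:
                raise ValueError(f"negative enzyme activity: {e}")

    def as_dict(self) -> dict[str, float]:
        return {e: getattr(self, e) for e in ENZYMES}


@dataclass(frozen=True)
class BiomassPools:
    """Microbial biomass C, N, P (µg g⁻¹) with fumigation–extraction
    conversion factors.

    The defaults kEC = 0.45, kEN = 0.54 and Kp = 0.4 are the standard
    chloroform fumigation–extraction efficiencies for biomass C, N and P.
    """

    cmic: float
    nmic: float
    pmic: float
    k_ec: float = 0.45
    k_en: float = 0.54
    k_p: float = 0.4

    def __post_init__(self) -> None:
        for k in (self.k_ec, self.k_en, self.k_p):
            if not (0 < k <= 1):
                raise ValueError("conversion factors must lie in (0, 1]")


@dataclass(frozen=True)
class TitrationSeries:
    """Alkali-trap titration record for one microcosm over the incubation.

    ``intervals`` is an ordered sequence of (day, v_blank, v_sample) where
    the volumes are mL of HCl consumed titrating the blank and the sample
    trap. ``naoh_volume`` is the trap volume (mL of 1 N NaOH) and sets the
    trap's absorption capacity.
    """

    intervals: tuple[tuple[float, float, float], ...]
    hcl_molarity: float
    naoh_volume: float
    soil_dry_mass: float

    def __post_init__(self) -> None:
        days = [d for d, _, _ in self.intervals]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("titration days must be strictly increasing")
        for d, vb, vs in self.intervals:
            if vb < 0 or vs < 0:
                raise ValueError("titration volumes must be >= 0")
        if self.soil_dry_mass <= 0:
            raise ValueError("soil_dry_mass must be > 0")

    def capacity_warnings(self) -> list[str]:
        """Warn (not error) where a sample titre exceeds what the trap's
        NaOH volume could have consumed."""
        out = []
        for d, vb, vs in self.intervals:
            if self.hcl_molarity > 0 and vs > self.naoh_volume / self.hcl_molarity:
                out.append(f"day {d}: v_sample {vs} mL exceeds trap capacity")
        return out


@dataclass(frozen=True)
class StoichConstants:
    """Constants of the CUE/TER framework.

    cue_max (0.6) is the thermodynamic upper bound on microbial growth
    efficiency; kx (0.5) the half-saturation constant of the CUE response;
    rho0 and n0 the SMA-derived normalization constants for TER C:P and C:N.
    """

    cue_max: float = 0.6
    kx: float = 0.5
    rho0: float | None = None
    n0: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.cue_max <= 1):
            raise ValueError("cue_max must lie in (0, 1]")
        if self.kx <= 0:
            raise ValueError("kx must be > 0")
        for c in (self.rho0, self.n0):
            if c is not None and c <= 0:
                raise ValueError("normalization constants must be > 0")


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

_MEASUREMENT_COLUMNS = ["sample_id", "treatment", "replicate", "phase", "analyte", "value", "unit"]


@dataclass
class IncubationDataset:
    """A complete incubation experiment in long (tidy) form.

    ``measurements`` has columns sample_id, treatment, replicate, phase,
    analyte, value, unit; one row per measured quantity. ``titration`` (may
    be empty) has columns treatment, replicate, day, v_blank, v_sample,
    hcl_molarity, naoh_volume, soil_dry_mass.
    """

    measurements: pd.DataFrame
    titration: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "treatment", "replicate", "day", "v_blank", "v_sample",
                "hcl_molarity", "naoh_volume", "soil_dry_mass",
            ]
        )
    )

    def __post_init__(self) -> None:
        missing = set(_MEASUREMENT_COLUMNS) - set(self.measurements.columns)
        if missing:
            raise ValueError(f"measurements missing columns: {sorted(missing)}")
        self.measurements = self.measurements[_MEASUREMENT_COLUMNS].copy()
        self.measurements["treatment"] = self.measurements["treatment"].map(canonical_treatment)

    # -- access helpers -----------------------------------------------------

    def wide(self, phase: str | None = None) -> pd.DataFrame:
        """Pivot to one row per (treatment, replicate, phase), one column per
        analyte."""
        df = self.measurements
        if phase is not None:
            df = df[df["phase"] == phase]
        out = df.pivot_table(
            index=["treatment", "replicate", "phase"],
            columns="analyte",
            values="value",
            aggfunc="first",
        ).reset_index()
        out.columns.name = None
        return out

    def analytes(self) -> set[str]:
        return set(self.measurements["analyte"].unique())

    def treatments(self) -> list[str]:
        present = set(self.measurements["treatment"].unique())
        return [t for t in TREATMENTS if t in present]

    def titration_series(self, treatment: str, replicate: int) -> TitrationSeries:
        t = self.titration
        sel = t[(t["treatment"] == canonical_treatment(treatment)) & (t["replicate"] == replicate)]
        if sel.empty:
            raise KeyError(f"no titration data for {treatment}/{replicate}")
        sel = sel.sort_values("day")
        return TitrationSeries(
            intervals=tuple(zip(sel["day"], sel["v_blank"], sel["v_sample"])),
            hcl_molarity=float(sel["hcl_molarity"].iloc[0]),
            naoh_volume=float(sel["naoh_volume"].iloc[0]),
            soil_dry_mass=float(sel["soil_dry_mass"].iloc[0]),
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str
    sample_id: str | None = None
    analyte: str | None = None


@dataclass
class ValidationReport:
    passed: bool
    n_records: int
    issues: list[ValidationIssue]
    excluded_analytes: list[str]

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def __str__(self) -> str:  # pragma: no cover - display convenience
        head = "PASS" if self.passed else "FAIL"
        lines = [f"{head}: {self.n_records} records, {len(self.issues)} issue(s)"]
        lines += [f"  [{i.severity}] {i.message}" for i in self.issues]
        return "\n".join(lines)


def validate_dataset(dataset: IncubationDataset, min_replicates: int = 3) -> ValidationReport:
    """Check structural and numeric invariants of a loaded dataset.

    Hard errors: duplicated (treatment, replicate, phase, analyte) rows,
    negative concentrations or activities, unknown units. A treatment with
    fewer than ``min_replicates`` replicates in either phase fails the
    dataset outright because every downstream group statistic needs
    within-group variance. Analytes entirely absent from a phase are flagged
    and excluded analyte-wise, not fatal.
    """
    issues: list[ValidationIssue] = []
    df = dataset.measurements

    # unit discipline
    for analyte, unit in df.groupby("analyte")["unit"].unique().items():
        expected = ANALYTE_UNITS.get(str(analyte))
        if expected is None:
            issues.append(ValidationIssue("error", f"unknown analyte {analyte!r}", analyte=str(analyte)))
            continue
        bad = [u for u in unit if u != expected]
        if bad:
            issues.append(
                ValidationIssue(
                    "error",
                    f"unit mismatch for {analyte}: got {bad}, expected {expected!r}",
                    analyte=str(analyte),
                )
            )

    # duplicates
    dup = df.duplicated(subset=["treatment", "replicate", "phase", "analyte"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["treatment", "replicate", "phase", "analyte"]].drop_duplicates()
        for _, row in keys.iterrows():
            issues.append(
                ValidationIssue(
                    "error",
                    "duplicate (treatment, replicate, phase) entry for analyte "
                    f"{row['analyte']}: {row['treatment']}/{row['replicate']}/{row['phase']}",
                )
            )

    # sign constraints
    neg = df[(df["analyte"].isin(_NONNEGATIVE)) & (df["value"] < 0)]
    for _, row in neg.iterrows():
        issues.append(
            ValidationIssue(
                "error",
                f"negative concentration: {row['analyte']}={row['value']} "
                f"({row['treatment']}/{row['replicate']}/{row['phase']})",
                sample_id=str(row["sample_id"]),
                analyte=str(row["analyte"]),
            )
        )

    # negative biomass: flagged, treated as missing downstream, never clamped
    negb = df[(df["analyte"].isin(BIOMASS_ANALYTES)) & (df["value"] < 0)]
    for _, row in negb.iterrows():
        issues.append(
            ValidationIssue(
                "warning",
                f"negative biomass {row['analyte']}={row['value']} "
                f"({row['treatment']}/{row['replicate']}/{row['phase']}); treated as missing",
                sample_id=str(row["sample_id"]),
                analyte=str(row["analyte"]),
            )
        )

    # replication
    counts = (
        df.groupby(["treatment", "phase"])["replicate"].nunique().unstack(fill_value=0)
    )
    for treatment, row in counts.iterrows():
        for phase in row.index:
            n = int(row[phase])
            if 0 < n < min_replicates:
                issues.append(
                    ValidationIssue(
                        "error",
                        f"insufficient replication: {treatment} has {n} replicate(s) "
                        f"in phase {phase} (need >= {min_replicates})",
                    )
                )

    # analyte coverage: flag analytes missing from one phase but present in the other
    excluded: list[str] = []
    by_phase = {ph: set(df.loc[df["phase"] == ph, "analyte"]) for ph in PHASES if ph in set(df["phase"])}
    if len(by_phase) == 2:
        for analyte in sorted(set.union(*by_phase.values()) - set.intersection(*by_phase.values())):
            if analyte in ENZYMES:
                # pre-incubation enzyme panels are optional in this design
                continue
            excluded.append(analyte)
            issues.append(
                ValidationIssue(
                    "warning",
                    f"analyte {analyte} present in only one phase; excluded from paired derivations",
                    analyte=analyte,
                )
            )

    n_records = int(df[["treatment", "replicate", "phase"]].drop_duplicates().shape[0])
    passed = not any(i.severity == "error" for i in issues)
    return ValidationReport(passed=passed, n_records=n_records, issues=issues, excluded_analytes=excluded)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_long_csv(path: str | Path | io.TextIOBase) -> IncubationDataset:
    """Read the long-format measurement CSV (and a sibling ``*.titration.csv``
    if present when given a path)."""
    df = pd.read_csv(path, float_precision="round_trip")
    titration = None
    if isinstance(path, (str, Path)):
        tpath = Path(path).with_suffix(".titration.csv")
        if tpath.exists():
            titration = pd.read_csv(tpath, float_precision="round_trip")
    if titration is None:
        return IncubationDataset(measurements=df)
    return IncubationDataset(measurements=df, titration=titration)


def write_long_csv(dataset: IncubationDataset, path: str | Path) -> None:
    """Write measurements (and titration, if any) next to each other.

    Relies on shortest-round-trip float repr so that a write→read cycle
    reproduces values bit-exactly.
    """
    path = Path(path)
    dataset.measurements.to_csv(path, index=False)
    if len(dataset.titration):
        dataset.titration.to_csv(path.with_suffix(".titration.csv"), index=False)


def read_wide_csv(path: str | Path) -> IncubationDataset:
    """Read a wide per-sample CSV: columns treatment, replicate, phase plus
    one column per analyte (internal units assumed; documented in the README).
    """
    wide = pd.read_csv(path, float_precision="round_trip")
    required = {"treatment", "replicate", "phase"}
    if not required <= set(wide.columns):
        raise ValueError(f"wide CSV must contain columns {sorted(required)}")
    value_cols = [c for c in wide.columns if c not in required]
    unknown = [c for c in value_cols if c not in ANALYTE_UNITS]
    if unknown:
        raise ValueError(f"unknown analyte columns: {unknown}")
    long = wide.melt(
        id_vars=["treatment", "replicate", "phase"], var_name="analyte", value_name="value"
    ).dropna(subset=["value"])
    long["unit"] = long["analyte"].map(ANALYTE_UNITS)
    long["sample_id"] = (
        long["treatment"].astype(str) + "-" + long["replicate"].astype(str) + "-" + long["phase"]
    )
    return IncubationDataset(measurements=long[_MEASUREMENT_COLUMNS])


def records_to_dataset(
    records: Iterable[SampleRecord],
    panels: Mapping[tuple[str, int, str], EnzymePanel] | None = None,
    biomass: Mapping[tuple[str, int, str], BiomassPools] | None = None,
) -> IncubationDataset:
    """Assemble typed records (plus optional per-sample enzyme panels and
    biomass pools keyed by (treatment, replicate, phase)) into a dataset."""
    rows: list[dict] = []

    def push(treatment: str, replicate: int, phase: str, analyte: str, value: float) -> None:
        rows.append(
            {
                "sample_id": f"{treatment}-{replicate}-{phase}",
                "treatment": treatment,
                "replicate": replicate,
                "phase": phase,
                "analyte": analyte,
                "value": float(value),
                "unit": ANALYTE_UNITS[analyte],
            }
        )

    for r in records:
        for analyte in POOL_ANALYTES + ("ph", "moisture_fraction", "soil_dry_mass"):
            push(r.treatment, r.replicate_id, r.phase, analyte, getattr(r, analyte))
    for key, panel in (panels or {}).items():
        t, rep, ph = canonical_treatment(key[0]), key[1], key[2]
        for e, v in panel.as_dict().items():
            push(t, rep, ph, e, v)
    for key, pools in (biomass or {}).items():
        t, rep, ph = canonical_treatment(key[0]), key[1], key[2]
        for a in BIOMASS_ANALYTES:
            push(t, rep, ph, a, getattr(pools, a))
    return IncubationDataset(measurements=pd.DataFrame(rows, columns=_MEASUREMENT_COLUMNS))
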