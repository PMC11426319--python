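"""End-to-end report assembly: validation → derivations → stoichiometry →
statistics, with per-stage CSV outputs and a JSON run manifest.

Identical configuration + input produce byte-identical outputs; the manifest
records every constant and flag so a run can be replayed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .experiment_model import (
    ENZYMES,
    IncubationDataset,
    StoichConstants,
    read_long_csv,
    validate_dataset,
)
from .biogeochem import derive_replicates, summarize_treatments
from .stoichiometry import treatment_stoichiometry
from .stats_battery import (
    DEFAULT_PCA_GROUPS,
    anova_tukey,
    pca_summary,
    pearson_by_group,
    residual_normality,
    significance_stars,
)

logger = logging.getLogger("soilstoich")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything that determines a pipeline run."""

    input_path: str | Path | None = None
    output_dir: str | Path = "stoich_results"
    k_ec: float = 0.45
    k_en: float = 0.54
    k_p: float = 0.4
    cue_max: float = 0.6
    kx: float = 0.5
    alpha: float = 0.05
    regression_kind: str = "ols"       # homeostasis regression
    intercept_scale: str = "ln"        # normalization-constant scale
    welch: bool = False                # limitation t-test variant
    per_day_qco2: bool = False
    posthoc: str = "tukey"
    pca_variable_set: str = "post"     # post-incubation variables only
    seed: int = 0

    def constants(self) -> StoichConstants:
        return StoichConstants(cue_max=self.cue_max, kx=self.kx)


@dataclass
class ReportBundle:
    output_dir: Path
    manifest: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


#: Variables entering the ANOVA battery from post-incubation data.
_ANOVA_VARIABLES = (
    "ph", "cmic", "nmic", "pmic", "doc", "don", "dop", "nh4", "no3", "hpo4",
)


def _display_round(df: pd.DataFrame) -> pd.DataFrame:
    """Report-table rounding: integers for large pools, 1 decimal for tens,
    2 decimals for ratios and small pools. Raw CSVs keep full precision."""

    def r(v):
        if isinstance(v, (int, float, np.floating)) and np.isfinite(v):
            a = abs(v)
            if a >= 100:
                return round(float(v))
            if a >= 10:
                return round(float(v), 1)
            return round(float(v), 2)
        return v

    return df.map(r)


def run_pipeline(config: RunConfig, dataset: IncubationDataset | None = None) -> ReportBundle:
    """Execute the full analysis and write per-stage CSVs plus a manifest.

    Stages degrade gracefully: missing analytes skip only the stages that
    need them, and every skipped stage is enumerated in the manifest.
    """
    if dataset is None:
        if config.input_path is None:
            raise ValueError("either a dataset or config.input_path is required")
        dataset = read_long_csv(config.input_path)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    skipped: list[dict] = []
    tables: dict[str, pd.DataFrame] = {}

    report = validate_dataset(dataset)
    if not report.passed:
        raise ValueError(f"input failed validation:\n{report}")
    for issue in report.issues:
        logger.warning("%s: %s", issue.severity, issue.message)

    analytes = dataset.analytes()
    has_enzymes = set(ENZYMES) <= analytes
    has_biomass = {"cmic", "nmic", "pmic"} <= analytes
    has_dissolved = {"doc", "don", "dop"} <= analytes

    # --- stage 1: deterministic derivations --------------------------------
    derived = derive_replicates(dataset, per_day_qco2=config.per_day_qco2)
    tables["derived_replicates"] = derived
    tables["treatment_summary"] = summarize_treatments(derived)

    # --- stage 2: stoichiometric engine ------------------------------------
    post = dataset.wide(phase="post")
    if has_enzymes and has_biomass and has_dissolved:
        stoich = treatment_stoichiometry(
            post,
            constants=config.constants(),
            regression_kind=config.regression_kind,
            alpha=config.alpha,
            welch=config.welch,
            intercept_scale=config.intercept_scale,
        )
        tables["stoich_replicates"] = stoich["replicates"]
        tables["ter"] = stoich["ter"]
        tables["cue"] = stoich["cue"]
        tables["homeostasis"] = stoich["homeostasis"]
        tables["limitation"] = stoich["limitation"]
        tables["stoich_constants"] = stoich["constants"]
    else:
        missing = [s for s, ok in (("enzymes", has_enzymes), ("biomass", has_biomass),
                                   ("dissolved organics", has_dissolved)) if not ok]
        skipped.append({"stage": "stoichiometry (TER/CUE/homeostasis)",
                        "reason": f"missing {', '.join(missing)}"})

    # --- stage 3: inferential battery ---------------------------------------
    anova_rows = []
    derived_vars = [c for c in ("co2_c_accum", "qco2", "net_nitrification") if c in derived.columns]
    merged = post.merge(derived, on=["treatment", "replicate"], how="left") if len(derived) else post
    for var in list(_ANOVA_VARIABLES) + derived_vars:
        if var not in merged.columns:
            continue
        sub = merged[["treatment", var]].dropna()
        if sub[var].nunique() <= 1 or sub.groupby("treatment").size().min() < 2:
            continue
        try:
            cmp_ = anova_tukey(sub[var], sub["treatment"], posthoc=config.posthoc,
                               alpha=config.alpha, variable=var)
        except ValueError:
            continue
        norm = residual_normality(sub[var], sub["treatment"])
        row = {"variable": var, "f": cmp_.f_stat, "p": cmp_.p_value,
               "stars": significance_stars(cmp_.p_value),
               "residual_normality_p": norm["p"]}
        row.update({f"letter_{t}": cmp_.letters.get(t, "") for t in cmp_.letters})
        anova_rows.append(row)
    if anova_rows:
        tables["anova"] = pd.DataFrame(anova_rows)
    else:
        skipped.append({"stage": "anova", "reason": "no variables with replication"})

    pca_vars = [v for v in _ANOVA_VARIABLES if v in post.columns] + \
        [e for e in ENZYMES if e in post.columns]  # SEA and qCO2 excluded by design
    pca_input = post[pca_vars].dropna(axis=1, how="any")
    if pca_input.shape[1] >= 2 and len(pca_input) >= 3:
        pca = pca_summary(pca_input)
        tables["pca_variance"] = pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(len(pca.eigenvalues))],
            "eigenvalue": pca.eigenvalues,
            "explained_fraction": pca.explained_fraction,
        })
        tables["pca_loadings"] = pca.loadings.reset_index(names="variable")
    else:
        skipped.append({"stage": "pca", "reason": "insufficient complete variables"})

    try:
        corr = pearson_by_group(merged, DEFAULT_PCA_GROUPS)
        for name, res in corr.items():
            tables[f"correlations_{name}_r"] = res["r"].reset_index(names="variable")
            tables[f"correlations_{name}_p"] = res["p"].reset_index(names="variable")
    except ValueError as exc:
        skipped.append({"stage": "grouped correlations", "reason": str(exc)})

    # --- write outputs -------------------------------------------------------
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", float_format="%.10g",
                  index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
    _display_round(tables["treatment_summary"].reset_index()).to_csv(
        outdir / "treatment_summary_display.csv", index=False)

    manifest = {
        "software": {"name": "soilstoich", "version": __version__},
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(config).items()},
        "n_records": report.n_records,
        "validation_warnings": [i.message for i in report.issues],
        "skipped_stages": skipped,
        "tables_written": sorted(tables.keys()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return ReportBundle(output_dir=outdir, manifest=manifest, tables=tables)
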