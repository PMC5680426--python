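"""End-to-end orchestration of the two analysis arms.

``run_macro_pipeline`` reproduces the comparative workflow: aggregate
literature LC50 records per species, check exposure-duration comparability,
put Grafen branch lengths on the supplied topology when it has none, and
compute phylogenetic-signal statistics for each configured taxonomic group.
``run_toxicity_pipeline`` reproduces the population workflow: fit the mixed
model for the concentration x population-type interaction on the full
mortality table, then estimate LC50 with a confidence interval separately
per population type from plain binomial GLMs.

Reports are written as CSV tables plus a machine-readable JSON twin and a
plain-text log; the report body is deterministic for a fixed configuration
and seed (no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .dose_response import (
    estimate_lc50,
    fit_binomial_glm,
    fit_glmm_laplace,
    load_mortality_csv,
)
from .signal import (
    aggregate_species,
    duration_effect_test,
    load_trait_csv,
    run_signal_suite,
)
from .tree import parse_newick

logger = logging.getLogger("evotox")

# the seven taxonomic analysis levels used by default, as (name, column, value);
# "all" keeps every species
DEFAULT_GROUP_DEFS = (
    ("all", None, None),
    ("macroinvertebrates", "group", "macroinvertebrate"),
    ("Chordata", "phylum", "Chordata"),
    ("Arthropoda", "phylum", "Arthropoda"),
    ("Mollusca", "phylum", "Mollusca"),
    ("fish", "class", "fish"),
    ("amphibians", "class", "amphibian"),
)


@dataclass
class AnalysisConfig:
    """Flat configuration for the pipeline; every field has a CLI flag."""

    tree_path: Optional[str] = None
    trait_path: Optional[str] = None
    mortality_path: Optional[str] = None
    trait_scale: str = "raw"
    n_perm: int = 999
    seed: int = 0
    rho: float = 1.0
    regrafen_after_prune: bool = False
    lc50_dose_scale: str = "chloride_mg_l"
    output_dir: str = "evotox_results"
    group_defs: tuple = DEFAULT_GROUP_DEFS

    def __post_init__(self):
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.trait_scale not in ("raw", "log10"):
            raise ValueError("trait_scale must be 'raw' or 'log10'")
        if self.lc50_dose_scale not in ("chloride_mg_l", "salt_g_l"):
            raise ValueError("lc50_dose_scale must be 'chloride_mg_l' or 'salt_g_l'")
        names = [g[0] for g in self.group_defs]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")

    @classmethod
    def from_file(cls, path, **overrides) -> "AnalysisConfig":
        """Read a flat ``key = value`` text config; overrides win over the file."""
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in {f.name for f in dataclasses.fields(cls)}:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = raw
        for key in ("n_perm", "seed"):
            if key in values:
                values[key] = int(values[key])
        if "rho" in values:
            values["rho"] = float(values["rho"])
        if "regrafen_after_prune" in values:
            values["regrafen_after_prune"] = values["regrafen_after_prune"].lower() in ("1", "true", "yes")
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _resolve_groups(config: AnalysisConfig, records: pd.DataFrame):
    groups = []
    for name, column, value in config.group_defs:
        if column is None:
            members = records["species"].unique().tolist()
        else:
            if column not in records.columns:
                raise ValueError(f"group {name!r} refers to missing column {column!r}")
            members = records.loc[records[column] == value, "species"].unique().tolist()
        groups.append((name, members))
    return groups


def run_macro_pipeline(config: AnalysisConfig) -> dict:
    """Phylogenetic-signal arm; returns the signal portion of the report."""
    if not config.tree_path or not config.trait_path:
        raise ValueError("macro pipeline needs tree_path and trait_path")
    tree = parse_newick(Path(config.tree_path).read_text())
    records = load_trait_csv(config.trait_path)
    species_values = aggregate_species(records)
    duration = duration_effect_test(records)
    overlap = set(species_values.index) & set(tree.tip_labels)
    if len(overlap) < 4:
        raise ValueError(
            f"only {len(overlap)} species shared between tree and trait table; need >= 4"
        )
    suite = run_signal_suite(
        species_values,
        tree,
        groups=_resolve_groups(config, records),
        n_perm=config.n_perm,
        seed=config.seed,
        trait_scale=config.trait_scale,
        regrafen_after_prune=config.regrafen_after_prune,
        rho=config.rho,
    )
    return {
        "signal_table": suite.table,
        "duration_test": {
            "f_stat": duration.f_stat,
            "df1": duration.df[0],
            "df2": duration.df[1],
            "p_value": duration.p_value,
            "group_sizes": {str(k): v for k, v in duration.group_sizes.items()},
        },
        "species_not_in_tree": suite.species_not_in_tree,
        "skipped_groups": [{"group": g, "n_usable": n} for g, n in suite.skipped_groups],
        "n_species_aggregated": int(len(species_values)),
        "trait_scale": config.trait_scale,
    }


def run_toxicity_pipeline(config: AnalysisConfig) -> dict:
    """Population arm: interaction test, then per-type LC50 estimates."""
    if not config.mortality_path:
        raise ValueError("toxicity pipeline needs mortality_path")
    table = load_mortality_csv(config.mortality_path)
    present = set(table["type"].unique())
    if present != {"roadside", "woodland"}:
        raise ValueError(f"mortality table must contain both population types, found {sorted(present)}")
    glmm = fit_glmm_laplace(table)
    lc50_rows = []
    for ptype in ("roadside", "woodland"):
        sub = table[table["type"] == ptype].reset_index(drop=True)
        fit = fit_binomial_glm(sub, predictors=("conc",), label=ptype)
        est = estimate_lc50(fit, population_label=ptype)
        lc50_rows.append(
            {
                "population_type": ptype,
                "lc50_mg_l": est.lc50,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_units": int(len(sub)),
            }
        )
    glmm_summary = {
        "fixed_effects": {
            name: {
                "estimate": float(row["estimate"]),
                "se": float(row["se"]),
                "z": float(row["z"]),
                "p": float(row["p"]),
            }
            for name, row in glmm.fixed_effects.iterrows()
        },
        "var_pond": glmm.var_pond,
        "var_unit": glmm.var_unit,
        "loglik": glmm.loglik,
        "aic": glmm.aic,
        "interaction_z": glmm.interaction_z,
        "interaction_p": glmm.interaction_p,
        "boundary": glmm.boundary,
        "converged": glmm.converged,
    }
    return {"lc50_table": pd.DataFrame(lc50_rows), "glmm_summary": glmm_summary}


def write_report(
    outdir,
    config: AnalysisConfig,
    macro: Optional[dict] = None,
    toxicity: Optional[dict] = None,
) -> dict:
    """Write CSV/JSON reports and a run log; returns the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "evotox_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "trait_scale": config.trait_scale,
        "rho": config.rho,
        "regrafen_after_prune": config.regrafen_after_prune,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "group_defs"
        },
    }
    report: dict = {"provenance": provenance}
    log_lines = [f"evotox {__version__}", f"seed={config.seed} n_perm={config.n_perm}"]
    if macro is not None:
        macro = dict(macro)
        table = macro.pop("signal_table")
        table.to_csv(outdir / "signal_results.csv", index=False)
        report["signal"] = {**macro, "results": table.to_dict(orient="records")}
        if macro["species_not_in_tree"]:
            log_lines.append(f"dropped species (not in tree): {macro['species_not_in_tree']}")
        for rec in macro["skipped_groups"]:
            log_lines.append(f"skipped group {rec['group']} (n={rec['n_usable']})")
        log_lines.append(f"trait scale: {macro['trait_scale']}")
    if toxicity is not None:
        toxicity = dict(toxicity)
        lc50 = toxicity.pop("lc50_table")
        lc50.to_csv(outdir / "lc50_results.csv", index=False)
        (outdir / "glmm_summary.json").write_text(
            json.dumps(toxicity["glmm_summary"], indent=2, sort_keys=True)
        )
        report["toxicity"] = {
            "lc50": lc50.to_dict(orient="records"),
            "glmm_summary": toxicity["glmm_summary"],
        }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
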