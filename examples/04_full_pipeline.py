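"""Both analysis arms end to end, from files on disk to a written report.

Writes a synthetic literature compilation (Newick tree + trait CSV) and a
synthetic mortality table, then runs the full pipeline: per-group
phylogenetic signal plus per-population-type LC50s and the mixed-model
interaction test, with everything saved under an output directory
(signal_results.csv, lc50_results.csv, glmm_summary.json, report.json,
run.log).
"""

import tempfile
from pathlib import Path

from evotox import AnalysisConfig, run_macro_pipeline, run_toxicity_pipeline, write_newick, write_report
from evotox.simulate import (
    MortalitySimConfig,
    simulate_mortality,
    simulate_trait_dataset,
    write_mortality_csv,
    write_trait_csv,
)

workdir = Path(tempfile.mkdtemp(prefix="evotox_example_"))
tree, records, _ = simulate_trait_dataset(55, lambda_true=1.0, seed=8)
(workdir / "tree.nwk").write_text(write_newick(tree) + "\n")
write_trait_csv(records, workdir / "traits.csv")
write_mortality_csv(simulate_mortality(MortalitySimConfig(seed=8)), workdir / "mortality.csv")

config = AnalysisConfig(
    tree_path=str(workdir / "tree.nwk"),
    trait_path=str(workdir / "traits.csv"),
    mortality_path=str(workdir / "mortality.csv"),
    trait_scale="log10",
    n_perm=199,
    seed=8,
    output_dir=str(workdir / "report"),
)
macro = run_macro_pipeline(config)
tox = run_toxicity_pipeline(config)
write_report(config.output_dir, config, macro=macro, toxicity=tox)

print("signal results by taxonomic group:")
cols = ["group", "n_species", "lambda_hat", "p_lambda", "k_stat", "p_k", "mantel_r", "mantel_p"]
print(macro["signal_table"][cols].round(3).to_string(index=False))
print()
d = macro["duration_test"]
print(f"duration check: F_{d['df1']},{d['df2']} = {d['f_stat']:.3f}, p = {d['p_value']:.3f}")
print()
print("LC50 by population type:")
print(tox["lc50_table"].round(1).to_string(index=False))
print()
g = tox["glmm_summary"]
print(f"GLMM interaction z = {g['interaction_z']:.3f}, p = {g['interaction_p']:.4g}")
print()
print(f"full report written under {config.output_dir}")
print("Groups with fewer than 4 usable species are skipped and recorded;")
print("small clades often show no detectable signal even when the full tree")
print("does, because within-clade trait variation is compressed.")
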