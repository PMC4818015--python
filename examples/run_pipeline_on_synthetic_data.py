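"""Full pipeline on a simulated tissue cohort with confounding eQTLs.

Generates a sibling-structured reference, a recombinant-inbred panel, and a
dataset with 4 cell-abundance QTLs plus 2 eQTL hotspots among the marker
genes; then runs the discovery pipeline with and without the marker
filtration step. Printed: the AUC against the simulated ground truth for
both variants and the markers removed by filtration — the removed genes are
mostly the planted hotspot targets, and the filtered run scores higher.
"""

from vocal.benchmark import (benchmark_config, make_benchmark_inputs,
                             run_and_score, simulate_dataset)
from vocal.simbench import SimulationConfig

inputs = make_benchmark_inputs(seed=5)
sim = SimulationConfig(n_iqtl=4, n_eqtl=2, n_strains=40, seed=5)
ds = simulate_dataset(sim, inputs)

auc_plain, _ = run_and_score(
    ds, benchmark_config(inputs, k=10, filtration=False, seed=5))
auc_filtered, result = run_and_score(
    ds, benchmark_config(inputs, k=10, filtration=True, seed=5))

targets = {g for h in ds.gt.hotspots for g in h.target_genes}
removed = {g for rec in result.iterations for g in rec.removed_genes}
print(f"AUC without filtration: {auc_plain:.3f}")
print(f"AUC with filtration:    {auc_filtered:.3f}")
print(f"markers removed: {len(removed)}, of which "
      f"{len(removed & targets)} are planted hotspot targets")
print("\nAUC scores each (cell type, locus) pair against the simulated truth;"
      "\nfiltration removes eQTL-confounded markers and recovers performance.")
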