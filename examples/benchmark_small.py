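"""A reduced sweep of the causal-architecture benchmark grid.

Runs the pipeline over a small grid of (number of abundance QTLs, number of
eQTL hotspots) at one replicate each and prints the AUC table. More causal
loci and more hotspots make the mapping problem harder, so AUC decreases
down and across the table.
"""

from vocal.benchmark import make_benchmark_inputs, run_benchmark

inputs = make_benchmark_inputs(seed=2, n_groups=4, m=800,
                               n_chromosomes=5, loci_per_chromosome=20)
table = run_benchmark(inputs, reps=1, seed=2, n_iqtl_grid=(2, 6),
                      n_eqtl_grid=(0, 2), n_strains=30, k=5,
                      filtration=False)
print(table.pivot(index="n_iqtl", columns="n_eqtl", values="auc").round(3))
print("\nRows: simulated abundance QTLs; columns: eQTL hotspots;"
      "\ncells: AUC of unfiltered discovery at that architecture.")
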