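"""End-to-end benchmark harness on fully synthetic data.

Builds a sibling-structured reference and a recombinant-inbred genotype
panel, simulates datasets over a grid of causal-architecture parameters,
runs the pipeline with and without its marker-filtration step, and scores
each run by AUC against the simulated ground truth.

Benchmark thresholds: the discovery thresholds used here (T_i = 5, T_e = 10
on -log10 p) are calibrated to this harness's cohort size; see the methods
note for the separation analysis behind them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .core_data import GeneExpressionMatrix, GenotypeMatrix, ReferenceMatrix
from .markers import init_marker_sets
from .pipeline import VocalConfig, VocalResult, run_vocal
from .simbench import (GroundTruth, SiblingMap, SimulationConfig,
                       build_gene_groups, child_seed,
                       generate_synthetic_reference, partition_cell_types,
                       sample_ground_truth, simulate_expression,
                       simulate_fractions, simulate_genotype_panel)

BENCH_T_I = 5.0
BENCH_T_E = 10.0

# the 15-combination causal-architecture grid
GRID_N_IQTL = (2, 4, 6, 8, 10)
GRID_N_EQTL = (0, 1, 2)


@dataclass
class BenchmarkInputs:
    """Fixed ingredients shared by all replicates of a benchmark."""

    ref: ReferenceMatrix  # full sibling-structured reference, with replicates
    grouping: dict[str, str]
    geno: GenotypeMatrix  # full strain panel

    @property
    def n_pairs(self) -> int:
        return len(set(self.grouping.values()))


def make_benchmark_inputs(seed: int | None = None, n_groups: int = 8,
                          genes_per_type: int = 40, m: int = 2000,
                          n_strains: int = 80, n_chromosomes: int = 20,
                          loci_per_chromosome: int = 25) -> BenchmarkInputs:
    ref, grouping = generate_synthetic_reference(
        n_groups=n_groups, genes_per_type=genes_per_type, m=m,
        seed=child_seed(seed, 11))
    geno = simulate_genotype_panel(
        n_strains=n_strains, n_chromosomes=n_chromosomes,
        loci_per_chromosome=loci_per_chromosome,
        seed=child_seed(seed, 13))
    return BenchmarkInputs(ref, grouping, geno)


@dataclass
class SyntheticDataset:
    expr: GeneExpressionMatrix
    geno: GenotypeMatrix  # restricted to the simulated cohort
    x_ref: ReferenceMatrix  # deconvolution side
    r_ref: ReferenceMatrix  # generation side
    gt: GroundTruth
    siblings: SiblingMap
    groups: list[list[str]]


def simulate_dataset(cfg: SimulationConfig, inputs: BenchmarkInputs,
                     marker_method: str = "cell_tagging",
                     pool_k: int = 10, psi: int | None = None) -> SyntheticDataset:
    """One synthetic dataset: partition, ground truth, fractions, expression.

    The hotspot target pool is derived the way the pipeline will see it:
    marker sets are initialized on the deconvolution reference, pooled, and
    clustered in the generation reference. ``pool_k`` is a data-generation
    convention and is deliberately independent of the k later used for
    analysis, so datasets stay identical across analysis variants.
    """
    r_ref, x_ref, siblings = partition_cell_types(
        inputs.ref, inputs.grouping, seed=child_seed(cfg.seed, 3))
    psi = 2 * inputs.n_pairs if psi is None else psi
    groups: list[list[str]] = []
    if cfg.n_eqtl > 0:
        coll = init_marker_sets(x_ref, marker_method, pool_k, psi,
                                seed=child_seed(cfg.seed, 5))
        groups = build_gene_groups(r_ref, coll.all_genes)
    gt = sample_ground_truth(replace(cfg, seed=child_seed(cfg.seed, 7)),
                             inputs.geno, r_ref, groups)
    gt.fractions = simulate_fractions(gt, inputs.geno, cfg.gamma_i)
    expr = simulate_expression(r_ref, gt.fractions, gt, inputs.geno,
                               replace(cfg, seed=child_seed(cfg.seed, 9)))
    cohort = inputs.geno.restrict_strains(gt.strains)
    return SyntheticDataset(expr, cohort, x_ref, r_ref, gt, siblings, groups)


def benchmark_config(inputs: BenchmarkInputs, k: int = 10,
                     filtration: bool = True, seed: int | None = None,
                     psi: int | None = None,
                     method: str = "cell_tagging") -> VocalConfig:
    return VocalConfig(method=method, k=k,
                       psi=2 * inputs.n_pairs if psi is None else psi,
                       t_i=BENCH_T_I, t_e=BENCH_T_E,
                       max_filtration_iters=1 if filtration else 0,
                       seed=seed)


def run_and_score(ds: SyntheticDataset, cfg: VocalConfig,
                  ld_collapse: bool = False) -> tuple[float, VocalResult]:
    from .simbench import evaluate_result

    result = run_vocal(ds.expr, ds.geno, ds.x_ref, cfg)
    auc = evaluate_result(result.associations, ds.gt, ds.siblings, mode="auc",
                          ld_collapse=ld_collapse, geno=ds.geno)
    return auc, result


def run_benchmark(inputs: BenchmarkInputs, reps: int = 5, seed: int = 0,
                  n_iqtl_grid=GRID_N_IQTL, n_eqtl_grid=GRID_N_EQTL,
                  gamma: float = 0.05, n_strains: int = 40, k: int = 10,
                  filtration: bool = True,
                  method: str = "cell_tagging") -> pd.DataFrame:
    """AUC over the causal-architecture grid; one row per (combination, rep)."""
    rows = []
    for n_i in n_iqtl_grid:
        for n_e in n_eqtl_grid:
            for rep in range(reps):
                ds_seed = [seed, n_i, n_e, rep]
                sim = SimulationConfig(n_iqtl=n_i, n_eqtl=n_e, gamma_i=gamma,
                                       gamma_e=gamma, n_strains=n_strains,
                                       seed=ds_seed)
                ds = simulate_dataset(sim, inputs, marker_method=method)
                cfg = benchmark_config(inputs, k=k, filtration=filtration,
                                       seed=ds_seed, method=method)
                auc, _ = run_and_score(ds, cfg)
                rows.append({"n_iqtl": n_i, "n_eqtl": n_e, "rep": rep,
                             "auc": auc})
    return pd.DataFrame(rows)
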