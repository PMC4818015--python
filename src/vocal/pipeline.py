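"""Orchestration of the five-step iQTL discovery loop.

Step 1 builds k disjoint marker sets from the reference; steps 2-4
deconvolve each set into immune traits, scan them genome-wide and combine
the k association maps with Fisher's method; step 5 removes marker genes
whose expression has a significant eQTL at a locus that is also a
significant immune-trait association, and the loop returns to step 2 until
no marker is removed (or an iteration cap is hit). The gene-level eQTL map
is computed once over the union of the initial markers and only
re-thresholded inside the loop.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .association import (AggregatedAssociations, AssociationMap, FdrResult,
                          build_association_map, compute_eqtl_map,
                          fisher_aggregate, permutation_fdr,
                          threshold_associations)
from .core_data import GeneExpressionMatrix, GenotypeMatrix, ReferenceMatrix, align_genes
from .deconvolution import PenaltyConfig, deconvolve_population
from .markers import (MarkerSetCollection, SignificanceSet,
                      compute_confounded_genes, filter_marker_sets,
                      init_marker_sets)

logger = logging.getLogger(__name__)


@dataclass
class VocalConfig:
    """Pipeline settings; thresholds are on the -log10 p scale."""

    method: str = "cell_tagging"
    k: int = 10
    psi: int = 62
    t_i: float = 5.0
    t_e: float = 10.0
    max_filtration_iters: int = 10
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    seed: int | None = None
    n_perm: int = 0
    facs_genes: list[str] | None = None

    @classmethod
    def synthetic_benchmark_preset(cls, n_cell_types: int, **overrides) -> "VocalConfig":
        """Full-scale benchmark preset: psi = 2n, T_i = 10, T_e = 40, one
        filtration pass."""
        base = cls(psi=2 * n_cell_types, t_i=10.0, t_e=40.0, max_filtration_iters=1)
        return replace(base, **overrides)

    @classmethod
    def real_data_preset(cls, **overrides) -> "VocalConfig":
        """Tissue-cohort preset: k = 10, T_i = 5, T_e = 10, iterate to
        convergence."""
        base = cls(method="cell_tagging_facs", k=10, t_i=5.0, t_e=10.0,
                   max_filtration_iters=1000)
        return replace(base, **overrides)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["penalty"] = self.penalty.__dict__.copy()
        return d


@dataclass
class IterationRecord:
    iteration: int
    removed: int
    removed_genes: list[str]
    evidence: list[tuple[str, str, str]]  # (gene, locus, cell type)


@dataclass
class VocalResult:
    associations: AggregatedAssociations
    iqtl_calls: SignificanceSet
    iterations: list[IterationRecord]
    markers: MarkerSetCollection
    traits: list  # ImmuneTraitMatrix per marker set, final iteration
    eqtl_map: AssociationMap | None = None
    fdr: FdrResult | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def write(self, outdir, geno: GenotypeMatrix | None = None,
              config: VocalConfig | None = None) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.associations.write(out / "associations.tsv", geno=geno)
        calls = pd.DataFrame(sorted(self.iqtl_calls.pairs),
                             columns=["cell_type", "locus"])
        with open(out / "iqtl_calls.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# -log10 p threshold: {self.iqtl_calls.threshold}\n")
            calls.to_csv(fh, sep="\t", index=False)
        for t in self.traits:
            t.write(out / f"traits_set{t.marker_set_index}.tsv")
        self.markers.write(out / "markers_final.tsv")
        with open(out / "iterations.json", "w", encoding="utf-8") as fh:
            json.dump([{"iteration": r.iteration, "removed": r.removed,
                        "removed_genes": r.removed_genes,
                        "evidence": r.evidence} for r in self.iterations], fh, indent=1)
        if self.fdr is not None:
            self.fdr.write(out / "fdr.tsv")
        if config is not None:
            with open(out / "run.json", "w", encoding="utf-8") as fh:
                json.dump({"config": config.to_dict(), "version": _version,
                           "iterations": self.n_iterations}, fh, indent=1, default=str)


class EmptyMarkerSetsError(RuntimeError):
    def __init__(self, iterations: list[IterationRecord]):
        super().__init__("all marker sets were emptied by filtration")
        self.iterations = iterations


def run_vocal(expr: GeneExpressionMatrix, geno: GenotypeMatrix,
              ref: ReferenceMatrix, cfg: VocalConfig,
              compute_fdr: bool | None = None) -> VocalResult:
    """Run the full pipeline on aligned inputs.

    All randomness (marker initialization, permutations) flows from
    ``cfg.seed``. With ``cfg.max_filtration_iters = 0`` no eQTL map is
    computed and the associations come from the initial marker sets alone.
    """
    expr, ref = align_genes(expr, ref)
    coll = init_marker_sets(ref, cfg.method, cfg.k, cfg.psi,
                            facs_genes=cfg.facs_genes, seed=cfg.seed)
    eqtl_map = None
    if cfg.max_filtration_iters > 0:
        pool = [g for g in coll.all_genes if g in set(expr.gene_ids)]
        eqtl_map = compute_eqtl_map(expr, geno, pool)

    iterations: list[IterationRecord] = []
    n_filtrations = 0
    while True:
        live = coll.nonempty_sets()
        if not live:
            raise EmptyMarkerSetsError(iterations)
        traits = [deconvolve_population(ref, expr, s, cfg.penalty) for s in live]
        maps = [build_association_map(t, geno) for t in traits]
        agg = fisher_aggregate(maps)
        w_i = threshold_associations(agg, cfg.t_i)
        if n_filtrations >= cfg.max_filtration_iters:
            break
        w_e = threshold_associations(eqtl_map, cfg.t_e)
        f_prime = compute_confounded_genes(w_i, w_e)
        present = f_prime & set(coll.all_genes)
        coll, removed = filter_marker_sets(coll, f_prime)
        evidence = _filtration_evidence(present, w_i, w_e)
        iterations.append(IterationRecord(len(iterations) + 1, removed,
                                          sorted(present), evidence))
        logger.info("filtration iteration %d removed %d marker(s)",
                    len(iterations), removed)
        if removed == 0:
            break
        n_filtrations += 1

    result = VocalResult(associations=agg, iqtl_calls=w_i, iterations=iterations,
                         markers=coll, traits=traits, eqtl_map=eqtl_map)
    want_fdr = cfg.n_perm > 0 if compute_fdr is None else compute_fdr
    if want_fdr:
        def rerun(perm_expr: GeneExpressionMatrix) -> AggregatedAssociations:
            sub = replace(cfg, n_perm=0)
            return run_vocal(perm_expr, geno, ref, sub).associations
        result.fdr = permutation_fdr(rerun, expr, cfg.n_perm, cfg.seed,
                                     thresholds=[cfg.t_i])
    return result


def _filtration_evidence(removed: set[str], w_i: SignificanceSet,
                         w_e: SignificanceSet) -> list[tuple[str, str, str]]:
    """(gene, locus, cell type) triples explaining each removal."""
    by_locus: dict[str, list[str]] = {}
    for c, v in w_i.pairs:
        by_locus.setdefault(v, []).append(c)
    out = []
    for g, v in w_e.pairs:
        if g in removed and v in by_locus:
            out.extend((g, v, c) for c in sorted(by_locus[v]))
    return sorted(out)
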