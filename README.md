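# vocal-iqtl

Mapping the genetic control of immune cell-type abundance from bulk tissue
expression — an implementation of the VoCAL (Variation in Cell Abundance
Loci) algorithm.

## The problem

Measuring the abundance of many immune cell types across a genotyped cohort
by cell sorting is laborious, so most genetic studies of immune composition
cover only a handful of cell types. Gene-expression deconvolution offers a
shortcut: the tissue expression of informative *marker genes* is modelled as
a mixture of known cell-type signatures,

    y^(s) = X · θ^(s),

where `X` holds reference signatures (genes × cell types) and `θ^(s)` the
unknown relative abundances in individual `s`. Solving this regression per
individual yields *immune traits* — the predicted abundance of each cell
type across the cohort — which can then be mapped genome-wide like any
quantitative trait. A locus whose alleles shift such a trait is an *iQTL*
(immune quantitative trait locus).

Two things make the naive version unreliable:

1. **Predicted traits are noisy.** The pipeline therefore draws *k* pairwise
   disjoint marker sets, repeats deconvolution and the genome scan with each,
   and combines the k association maps with Fisher's method,
   `a_{c,v} = P(χ²_{2k} ≥ −2 Σ_u ln p_u(c,v))`. Only signals reproducible
   across marker sets survive.
2. **eQTLs masquerade as iQTLs.** If a marker gene's expression is itself
   genetically controlled (an eQTL), deconvolution converts that expression
   shift into a spurious abundance shift at the same locus. The pipeline
   iteratively removes marker genes that have a significant eQTL at a locus
   that is also a significant immune-trait association, and re-runs until no
   marker is removed.

The association test is the two-level fixed-effect ANOVA `θ_c = d^(v)·β + ε`
on homozygous genotypes; deconvolution is an elastic net (`α = 0.05`,
`lambda.min.ratio = 0.2`) so that only a sparse subset of a large cell-type
panel is assigned abundance changes. A synthetic benchmark simulates
recombinant-inbred cohorts with planted iQTLs and eQTL hotspots and scores
discovery by AUC, using *sibling* cell types (related but not identical
signatures) for data generation and deconvolution so that evaluation is not
circular.

## Worked example

`examples/run_pipeline_on_synthetic_data.py` simulates a 40-strain cohort
with 4 abundance QTLs and 2 eQTL hotspots among the markers, then runs the
pipeline with and without filtration:

```
$ python examples/run_pipeline_on_synthetic_data.py
AUC without filtration: 0.856
AUC with filtration:    0.934
markers removed: 20, of which 20 are planted hotspot targets
```

AUC ranks every (cell type, locus) pair by its combined association p-value
against the simulated ground truth; 0.5 is chance, 1.0 is perfect. Here the
two eQTL hotspots depress the unfiltered score, the filtration step removes
exactly the 20 planted hotspot-target genes from the marker sets, and
performance recovers. The other examples cover the deconvolution step
(`deconvolve_mixture.py`), the genome scan and Fisher aggregation
(`genome_scan_and_aggregation.py`) and a reduced benchmark grid
(`benchmark_small.py`).

The same machinery is scriptable from the shell:

```bash
vocal simulate --n-iqtl 4 --n-eqtl 1 --seed 7 --out sim/
vocal run --expr sim/Y.tsv --geno sim/geno.tsv --geno-dialect tsv01 \
          --ref sim/X.tsv --replicate-map sim/X_replicates.tsv \
          --k 10 --psi 16 --t-i 5 --t-e 10 --max-filtration-iters 1 \
          --seed 7 --out run/
vocal evaluate --associations run/associations.tsv \
               --ground-truth sim/ground_truth.json \
               --siblings sim/siblings.tsv --out scores.tsv
```

`vocal run` also accepts real data: a GeneNetwork-style `.geno` file, a
log-scale expression TSV (optionally `--baseline <sample>` to subtract a
parental-strain profile), a reference signature TSV with an optional
replicate map, and a FACS marker list for the `cell_tagging_facs`
initialization.

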