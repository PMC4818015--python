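"""Genome-wide ANOVA scans, Fisher aggregation and permutation FDR.

An immune trait (or a gene's expression) is tested against every locus with
the two-level fixed-effect model theta = d * beta + eps, eps ~ N(0, sigma^2),
whose F-test on 1 and (n-2) degrees of freedom is the equal-variance
two-sample t-test between the allele groups. Heterozygous and no-call
genotypes are dropped per locus; degenerate tests (a group smaller than two,
or a constant trait) report p = 1 so downstream aggregation needs no special
cases. The k per-marker-set association maps are combined with Fisher's
method: a = P(chi2_{2k} >= -2 sum_u ln p_u).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ALLELE_A, ALLELE_B, GeneExpressionMatrix, GenotypeMatrix
from .deconvolution import ImmuneTraitMatrix
from .markers import SignificanceSet

P_FLOOR = 1e-300
_VAR_EPS = 1e-30


@dataclass
class AssociationMap:
    """Per-entity, per-locus ANOVA p-values (entities x loci)."""

    data: pd.DataFrame
    source_index: int | None = None

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) <= 0 or np.nanmax(vals) > 1):
            raise ValueError("association p-values must lie in (0, 1]")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class AggregatedAssociations:
    """Fisher-combined association p-values a_{c,v} over k maps."""

    data: pd.DataFrame
    k: int

    @property
    def cell_type_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.data.columns)

    def neg_log10(self) -> pd.DataFrame:
        return -np.log10(self.data.clip(lower=P_FLOOR))

    def write(self, path, geno: GenotypeMatrix | None = None) -> None:
        long = self.data.stack().rename("p").reset_index()
        long.columns = ["cell_type", "locus", "p"]
        long["neg_log10_p"] = -np.log10(long["p"].clip(lower=P_FLOOR))
        if geno is not None:
            info = {l.id: (l.chromosome, l.position) for l in geno.loci}
            long["chromosome"] = [info[v][0] for v in long["locus"]]
            long["position"] = [info[v][1] for v in long["locus"]]
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, k: int = 0) -> "AggregatedAssociations":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot(index="cell_type", columns="locus", values="p")
        return cls(wide, k=k)


@dataclass
class EffectRecord:
    locus_id: str
    beta: float  # allele_B group mean minus allele_A group mean
    sigma2: float  # pooled residual variance
    n_a: int
    n_b: int


def _scan_matrix(traits: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Vectorized per-locus two-group test.

    ``traits``: (n_entities, l) trait values; ``codes``: (l, q) genotype
    codes. Returns (n_entities, q) p-values.
    """
    a_mask = (codes == ALLELE_A).astype(float)
    b_mask = (codes == ALLELE_B).astype(float)
    n_a = a_mask.sum(axis=0)
    n_b = b_mask.sum(axis=0)
    s_a = traits @ a_mask
    s_b = traits @ b_mask
    sq = traits ** 2
    ss_a = sq @ a_mask
    ss_b = sq @ b_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_a = s_a / n_a
        mean_b = s_b / n_b
        rss = (ss_a - n_a * mean_a ** 2) + (ss_b - n_b * mean_b ** 2)
        df = n_a + n_b - 2
        sp2 = rss / df
        diff = mean_b - mean_a
        t = diff / np.sqrt(np.maximum(sp2, P_FLOOR) * (1 / n_a + 1 / n_b))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(diff) < 1e-300, 1.0, p)  # zero effect, incl. constant traits
    p = np.where(sp2 < _VAR_EPS, np.where(np.abs(diff) < 1e-12, 1.0, p), p)
    degenerate = (n_a < 2) | (n_b < 2)
    p[:, degenerate] = 1.0
    return np.clip(p, P_FLOOR, 1.0)


def anova_scan(trait: pd.Series, geno: GenotypeMatrix
               ) -> tuple[pd.Series, list[EffectRecord]]:
    """Scan one trait against every locus.

    ``trait`` is indexed by sample id; its samples must all be genotyped.
    Returns the per-locus p-values and the per-locus effect records.
    """
    missing = set(trait.index) - set(geno.strain_ids)
    if missing:
        raise ValueError(f"trait samples not genotyped: {sorted(missing)[:5]}")
    sub = geno.restrict_strains(list(trait.index))
    codes = sub.codes.to_numpy()
    t = trait.to_numpy(dtype=float)[None, :]
    p = _scan_matrix(t, codes)[0]
    records = []
    for j, v in enumerate(sub.locus_ids):
        a = t[0][codes[:, j] == ALLELE_A]
        b = t[0][codes[:, j] == ALLELE_B]
        beta = (b.mean() - a.mean()) if (a.size and b.size) else 0.0
        if a.size >= 2 and b.size >= 2:
            sigma2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) \
                / (a.size + b.size - 2)
        else:
            sigma2 = float("nan")
        records.append(EffectRecord(v, float(beta), float(sigma2), a.size, b.size))
    return pd.Series(p, index=sub.locus_ids), records


def build_association_map(traits: ImmuneTraitMatrix,
                          geno: GenotypeMatrix) -> AssociationMap:
    """One genome scan per cell-type trait row.

    Rows that are identically zero (cell types never picked up by the
    regularized deconvolution) yield p = 1 everywhere.
    """
    missing = set(traits.sample_ids) - set(geno.strain_ids)
    if missing:
        raise ValueError(f"trait samples not genotyped: {sorted(missing)[:5]}")
    sub = geno.restrict_strains(traits.sample_ids)
    t = traits.data.to_numpy(dtype=float)
    p = _scan_matrix(t, sub.codes.to_numpy())
    zero_rows = ~np.any(t, axis=1)
    p[zero_rows, :] = 1.0
    frame = pd.DataFrame(p, index=traits.cell_type_ids, columns=sub.locus_ids)
    return AssociationMap(frame, source_index=traits.marker_set_index)


def compute_eqtl_map(expr: GeneExpressionMatrix, geno: GenotypeMatrix,
                     genes: list[str]) -> AssociationMap:
    """ANOVA scan of each listed gene's expression row (the eQTL map).

    Computed once up front; the filtration loop only re-thresholds it.
    """
    genes = list(genes)
    missing = set(genes) - set(expr.gene_ids)
    if missing:
        raise ValueError(f"genes absent from expression data: {sorted(missing)[:5]}")
    sub = geno.restrict_strains(expr.sample_ids)
    if not genes:
        return AssociationMap(pd.DataFrame(index=pd.Index([], name="gene"),
                                           columns=sub.locus_ids, dtype=float))
    t = expr.data.loc[genes].to_numpy(dtype=float)
    p = _scan_matrix(t, sub.codes.to_numpy())
    return AssociationMap(pd.DataFrame(p, index=genes, columns=sub.locus_ids))


def fisher_aggregate(maps: list[AssociationMap]) -> AggregatedAssociations:
    """Combine k association maps into one p-value per (entity, locus).

    Entities missing from a map contribute p = 1 there (down-weighting pairs
    supported by only some maps); the locus universe must match exactly.
    """
    if not maps:
        raise ValueError("need at least one association map")
    loci = maps[0].locus_ids
    for m in maps[1:]:
        if m.locus_ids != loci:
            raise ValueError("association maps disagree on the locus universe")
    entities: list[str] = []
    for m in maps:
        for e in m.entity_ids:
            if e not in entities:
                entities.append(e)
    k = len(maps)
    stat = np.zeros((len(entities), len(loci)))
    for m in maps:
        p = m.data.reindex(index=entities).fillna(1.0).to_numpy(dtype=float)
        stat += -2.0 * np.log(np.clip(p, P_FLOOR, 1.0))
    a = stats.chi2.sf(stat, df=2 * k)
    a = np.clip(a, P_FLOOR, 1.0)
    return AggregatedAssociations(pd.DataFrame(a, index=entities, columns=loci), k=k)


def threshold_associations(assoc: AggregatedAssociations | AssociationMap,
                           t: float) -> SignificanceSet:
    """Pairs whose -log10 p meets the threshold t."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    data = assoc.data
    neglog = -np.log10(data.clip(lower=P_FLOOR).to_numpy(dtype=float))
    rows, cols = np.nonzero(neglog >= t)
    pairs = {(data.index[i], data.columns[j]) for i, j in zip(rows, cols)}
    return SignificanceSet(pairs=pairs, threshold=t)


def iqtl_intervals(calls: SignificanceSet, geno: GenotypeMatrix) -> pd.DataFrame:
    """Collapse significant loci into per-cell-type genomic intervals.

    An interval is a maximal run of contiguous significant loci on one
    chromosome (a convention; no linkage model is applied). Returns one row
    per (cell type, interval) with the bounding positions in Mbp and the
    number of loci it spans.
    """
    order = {l.id: i for i, l in enumerate(geno.loci)}
    rows = []
    for ct in sorted(calls.entities()):
        hits = sorted((v for e, v in calls.pairs if e == ct),
                      key=lambda v: order[v])
        run: list[str] = []
        for v in hits:
            if run and (order[v] != order[run[-1]] + 1
                        or geno.locus(v).chromosome
                        != geno.locus(run[-1]).chromosome):
                rows.append(_interval_row(ct, run, geno))
                run = []
            run.append(v)
        if run:
            rows.append(_interval_row(ct, run, geno))
    return pd.DataFrame(rows, columns=["cell_type", "chromosome", "start_mbp",
                                       "end_mbp", "n_loci", "loci"])


def _interval_row(ct, run, geno):
    first, last = geno.locus(run[0]), geno.locus(run[-1])
    return {"cell_type": ct, "chromosome": first.chromosome,
            "start_mbp": first.position, "end_mbp": last.position,
            "n_loci": len(run), "loci": ",".join(run)}


@dataclass
class FdrResult:
    table: pd.DataFrame  # threshold, n_real, mean_permuted, fdr, undefined

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def permutation_fdr(run, expr: GeneExpressionMatrix, n_perm: int,
                    seed: int | None, thresholds: list[float]) -> FdrResult:
    """Permutation-based FDR for the discovery counts of a pipeline.

    ``run`` maps an expression matrix to an :class:`AggregatedAssociations`.
    Strain labels of the expression matrix are permuted ``n_perm`` times with
    the genotypes fixed, the full pipeline is re-run on each, and
    FDR(t) = mean permuted discovery count at t / real discovery count at t.
    A real count of zero reports an undefined (NaN) FDR, not zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    real = run(expr)
    n_real = np.array([len(threshold_associations(real, t).pairs)
                       for t in thresholds], dtype=float)
    perm_counts = np.zeros((n_perm, len(thresholds)))
    cols = np.array(expr.sample_ids)
    for i in range(n_perm):
        shuffled = expr.data.copy()
        shuffled.columns = cols[rng.permutation(len(cols))]
        agg = run(GeneExpressionMatrix(shuffled))
        perm_counts[i] = [len(threshold_associations(agg, t).pairs)
                          for t in thresholds]
    mean_perm = perm_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_real > 0, mean_perm / np.maximum(n_real, 1e-300), np.nan)
    table = pd.DataFrame({"threshold": thresholds, "n_real": n_real,
                          "mean_permuted": mean_perm, "fdr": fdr,
                          "undefined": n_real == 0})
    return FdrResult(table)
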