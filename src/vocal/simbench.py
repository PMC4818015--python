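"""Synthetic-data generation and the AUC/FPR/TPR evaluation harness.

The simulator emulates a recombinant-inbred study: strains are homozygous
for one of two parental alleles at every locus, a handful of loci act as
cell-abundance QTLs (each shifting the fraction of one target cell type in
strains carrying the alternative allele), and optional eQTL hotspots shift
the expression of small groups of co-expressed genes. Tissue expression is
the fraction-weighted mixture of reference signatures plus the hotspot
offsets and Gaussian noise:

    y_{j,s} = sum_c theta_c^(s) r_{j,c} + phi_j^(s) + eps,   eps ~ N(0, sigma^2)

with theta^(s) starting from equal fractions 1/n, shifted by +-(1/n)*gamma_i
for the targeted cell type in alternative-allele strains and renormalized to
sum one, and phi_j^(s) = +-gamma_e for hotspot target genes in
alternative-allele strains.

To mimic the real-world mismatch between the cell types present in a tissue
and the reference used for deconvolution, cell types come in closely related
*sibling pairs*; one member generates the data, the other deconvolves it,
and ground-truth scoring links predictions to truth through the pairing.
A fully synthetic reference generator fabricates such sibling-structured
signatures so no external data are required.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .core_data import (ALLELE_A, ALLELE_B, GeneExpressionMatrix, GenotypeMatrix,
                        Locus, ReferenceMatrix)
from .markers import SignificanceSet

logger = logging.getLogger(__name__)

ACTIVATE = "activate"
REPRESS = "repress"


def child_seed(seed, tag: int):
    """Derive an independent, reproducible seed stream label."""
    if seed is None:
        return None
    if isinstance(seed, (list, tuple)):
        return [*(int(s) for s in seed), tag]
    return [int(seed), tag]

# co-expression grouping of the pooled markers: average-linkage tree cut at
# Pearson correlation 0.7 (distance 0.3); a usable group has > 10 genes
CORRELATION_CUTOFF = 0.7
MIN_GROUP_SIZE = 11
HOTSPOT_TARGETS = 10


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic dataset."""

    n_iqtl: int = 4
    n_eqtl: int = 1
    gamma_i: float = 0.05  # fractional iQTL effect; must stay below 1
    gamma_e: float = 0.05  # additive eQTL offset on the expression scale
    sigma2: float = 1e-4  # measurement noise variance
    n_strains: int = 60
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.gamma_i < 1:
            raise ValueError("gamma_i must lie in [0, 1) to keep fractions positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


@dataclass(frozen=True)
class Iqtl:
    locus: str
    cell_type: str  # data-generation cell type whose fraction it controls
    direction: str  # ACTIVATE or REPRESS


@dataclass(frozen=True)
class EqtlHotspot:
    locus: str
    target_genes: tuple[str, ...]
    direction: str


@dataclass
class GroundTruth:
    iqtls: list[Iqtl]
    hotspots: list[EqtlHotspot]
    strains: list[str]
    cell_types: list[str]  # data-generation cell types, fraction matrix columns
    fractions: pd.DataFrame | None = None  # strains x cell types

    def to_json(self, path) -> None:
        payload = {
            "iqtls": [asdict(q) for q in self.iqtls],
            "hotspots": [{"locus": h.locus, "target_genes": list(h.target_genes),
                          "direction": h.direction} for h in self.hotspots],
            "strains": self.strains,
            "cell_types": self.cell_types,
            "fractions": (None if self.fractions is None
                          else self.fractions.to_dict(orient="split")),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        fractions = None
        if d.get("fractions") is not None:
            fd = d["fractions"]
            fractions = pd.DataFrame(fd["data"], index=fd["index"], columns=fd["columns"])
        return cls(
            iqtls=[Iqtl(**q) for q in d["iqtls"]],
            hotspots=[EqtlHotspot(h["locus"], tuple(h["target_genes"]), h["direction"])
                      for h in d["hotspots"]],
            strains=d["strains"], cell_types=d["cell_types"], fractions=fractions)


@dataclass
class SiblingMap:
    """Bijection between data-generation and deconvolution cell types."""

    pairs: list[tuple[str, str]]  # (generation ct, deconvolution ct)

    def __post_init__(self) -> None:
        gen = [g for g, _ in self.pairs]
        dec = [d for _, d in self.pairs]
        if len(set(gen)) != len(gen) or len(set(dec)) != len(dec):
            raise ValueError("sibling map must be a bijection")

    def deconvolution_sibling(self, generation_ct: str) -> str:
        for g, d in self.pairs:
            if g == generation_ct:
                return d
        raise KeyError(generation_ct)

    def write(self, path) -> None:
        pd.DataFrame(self.pairs, columns=["generation", "deconvolution"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SiblingMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls([tuple(r) for r in df.itertuples(index=False)])


def partition_cell_types(ref: ReferenceMatrix, grouping: dict[str, str],
                         seed: int | None = None
                         ) -> tuple[ReferenceMatrix, ReferenceMatrix, SiblingMap]:
    """Split the reference into data-generation (R) and deconvolution (X) halves.

    ``grouping`` maps each cell type to its isolation group; from every group
    with at least two members, two distinct cell types are drawn uniformly
    and one is assigned to each side at random. Groups with fewer than two
    members are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for ct in ref.cell_type_ids:
        if ct in grouping:
            by_group.setdefault(grouping[ct], []).append(ct)
    pairs = []
    for group in sorted(by_group):
        members = by_group[group]
        if len(members) < 2:
            logger.warning("isolation group %s has %d member(s); dropped",
                           group, len(members))
            continue
        two = rng.choice(members, size=2, replace=False)
        if rng.random() < 0.5:
            two = two[::-1]
        pairs.append((str(two[0]), str(two[1])))
    if not pairs:
        raise ValueError("no isolation group contributes two cell types")
    r = ref.restrict_cell_types([g for g, _ in pairs])
    x = ref.restrict_cell_types([d for _, d in pairs])
    return r, x, SiblingMap(pairs)


def build_gene_groups(r: ReferenceMatrix, marker_pool: list[str]) -> list[list[str]]:
    """Co-expression groups of the pooled marker genes in the generation reference.

    Average-linkage hierarchical clustering on 1 - Pearson correlation of the
    genes' signature rows, cut at correlation 0.7; only sub-trees with more
    than 10 genes qualify as hotspot target groups.
    """
    pool = [g for g in dict.fromkeys(marker_pool) if g in set(r.gene_ids)]
    if len(pool) < 2:
        raise ValueError("marker pool too small to cluster")
    vals = r.collapse().data.loc[pool].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(vals)
    corr = np.nan_to_num(corr, nan=0.0)  # flat rows: treat as uncorrelated
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=1.0 - CORRELATION_CUTOFF,
                                criterion="distance")
    groups = [[pool[i] for i in np.flatnonzero(labels == lab)]
              for lab in np.unique(labels)]
    groups = [g for g in groups if len(g) >= MIN_GROUP_SIZE]
    if not groups:
        raise ValueError("no co-expression group exceeds 10 genes; "
                         "use a larger marker pool")
    return sorted(groups, key=lambda g: g[0])


def sample_ground_truth(cfg: SimulationConfig, geno: GenotypeMatrix,
                        r: ReferenceMatrix,
                        groups: list[list[str]] | None = None) -> GroundTruth:
    """Draw causal loci, their directions and targets, and the strain cohort."""
    rng = np.random.default_rng(cfg.seed)
    locus_ids = geno.locus_ids
    n_loci_needed = cfg.n_iqtl + cfg.n_eqtl
    if n_loci_needed > len(locus_ids):
        raise ValueError("more causal loci requested than loci available")
    if cfg.n_eqtl > 0 and not groups:
        raise ValueError("eQTL hotspots need co-expression gene groups")
    if cfg.n_strains > len(geno.strain_ids):
        raise ValueError("more strains requested than available")

    chosen = rng.choice(locus_ids, size=n_loci_needed, replace=False)
    iqtl_loci = [str(v) for v in chosen[:cfg.n_iqtl]]
    hotspot_loci = [str(v) for v in chosen[cfg.n_iqtl:]]
    cell_types = r.cell_type_ids
    iqtls = [Iqtl(v, str(rng.choice(cell_types)),
                  ACTIVATE if rng.random() < 0.5 else REPRESS)
             for v in iqtl_loci]
    hotspots = []
    for v in hotspot_loci:
        group = groups[rng.integers(len(groups))]
        targets = tuple(str(g) for g in rng.choice(group, size=HOTSPOT_TARGETS,
                                                   replace=False))
        hotspots.append(EqtlHotspot(v, targets,
                                    ACTIVATE if rng.random() < 0.5 else REPRESS))

    # strains must be homozygous at the causal iQTL loci; resample offenders
    strains = list(rng.choice(geno.strain_ids, size=cfg.n_strains, replace=False))
    leftovers = [s for s in geno.strain_ids if s not in set(strains)]
    rng.shuffle(leftovers)
    causal = iqtl_loci

    def ok(strain: str) -> bool:
        codes = geno.codes.loc[strain, causal].to_numpy() if causal else np.array([])
        return bool(np.all((codes == ALLELE_A) | (codes == ALLELE_B)))

    for i, s in enumerate(strains):
        while not ok(strains[i]) and leftovers:
            replacement = leftovers.pop()
            logger.info("strain %s not homozygous at a causal locus; "
                        "resampled to %s", strains[i], replacement)
            strains[i] = replacement
    return GroundTruth(iqtls=iqtls, hotspots=hotspots, strains=strains,
                       cell_types=list(cell_types))


def simulate_fractions(gt: GroundTruth, geno: GenotypeMatrix,
                       gamma_i: float) -> pd.DataFrame:
    """True cell-type fractions per strain (rows sum to one).

    Every strain starts at 1/n per cell type; for each cell-abundance QTL, a
    strain carrying the alternative allele gets +-(1/n)*gamma_i on the target
    cell type, then the row is renormalized.
    """
    n = len(gt.cell_types)
    frac = np.full((len(gt.strains), n), 1.0 / n)
    col = {c: i for i, c in enumerate(gt.cell_types)}
    for q in gt.iqtls:
        carrier = geno.codes.loc[gt.strains, q.locus].to_numpy() == ALLELE_B
        sign = 1.0 if q.direction == ACTIVATE else -1.0
        frac[carrier, col[q.cell_type]] += sign * gamma_i / n
    frac /= frac.sum(axis=1, keepdims=True)
    return pd.DataFrame(frac, index=gt.strains, columns=gt.cell_types)


def simulate_expression(r: ReferenceMatrix, fractions: pd.DataFrame,
                        gt: GroundTruth, geno: GenotypeMatrix,
                        cfg: SimulationConfig) -> GeneExpressionMatrix:
    """Mix signatures by the true fractions, add hotspot offsets and noise."""
    rc = r.collapse().data[gt.cell_types]
    y = rc.to_numpy(dtype=float) @ fractions.loc[gt.strains].to_numpy(dtype=float).T
    gene_row = {g: i for i, g in enumerate(rc.index)}
    for h in gt.hotspots:
        carrier = geno.codes.loc[gt.strains, h.locus].to_numpy() == ALLELE_B
        sign = 1.0 if h.direction == ACTIVATE else -1.0
        rows = [gene_row[g] for g in h.target_genes]
        y[np.ix_(rows, np.flatnonzero(carrier))] += sign * cfg.gamma_e
    if cfg.sigma2 > 0:
        rng = np.random.default_rng(child_seed(cfg.seed, 1))
        y = y + rng.normal(0.0, np.sqrt(cfg.sigma2), size=y.shape)
    return GeneExpressionMatrix(pd.DataFrame(y, index=rc.index, columns=gt.strains))


def generate_synthetic_reference(n_groups: int = 8, genes_per_type: int = 40,
                                 m: int = 2000, n_replicates: int = 3,
                                 separation: float = 1.0,
                                 sibling_correlation: float = 0.98,
                                 signature_overlap: float = 0.3,
                                 seed: int | None = None
                                 ) -> tuple[ReferenceMatrix, dict[str, str]]:
    """Fabricate a sibling-structured reference with per-cell-type marker blocks.

    2*n_groups cell types come in n_groups sibling pairs; the pair g shares a
    block of ``genes_per_type`` signature genes expressed ``separation`` units
    above baseline in that pair, and cross-expressed in every other pair at a
    random fraction up to ``signature_overlap`` of that (marker genes are
    rarely perfectly cell-type specific, so signatures correlate between cell
    types). The two siblings diverge by Gaussian noise calibrated so their
    profiles correlate at ~``sibling_correlation``; replicate columns add
    small jitter. Remaining genes sit at a common baseline. Returns the
    reference (with replicate annotations) and the cell-type ->
    isolation-group map.
    """
    if m < n_groups * genes_per_type:
        raise ValueError("m too small for the requested signature blocks")
    if not 0 < sibling_correlation <= 1:
        raise ValueError("sibling correlation must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(m)]
    baseline = rng.normal(4.0, 1.0, size=m)
    amplitude = separation * (1.0 + 0.2 * rng.uniform(-1, 1, size=m))

    # cross-expression of block g's genes in group g', scaled per gene by a
    # specificity factor (real marker genes range from highly specific to
    # promiscuous); group-level structure keeps block genes co-expressed
    cross = rng.uniform(0.0, signature_overlap, size=(n_groups, n_groups))
    np.fill_diagonal(cross, 0.0)
    specificity = rng.uniform(0.0, 2.0, size=m)
    blocks = np.zeros((m, n_groups))
    for g in range(n_groups):
        block = slice(g * genes_per_type, (g + 1) * genes_per_type)
        blocks[block, g] = amplitude[block]
    shared = (baseline[:, None] + blocks
              + (blocks * specificity[:, None]) @ cross)

    rho = sibling_correlation
    cols, rep_map, grouping = {}, {}, {}
    for g in range(n_groups):
        vs = shared[:, g].var()
        tau = 0.0 if rho >= 1.0 else np.sqrt(vs * (1.0 - rho) / rho)
        for side in ("a", "b"):
            ct = f"ct{g}{side}"
            grouping[ct] = f"grp{g}"
            profile = shared[:, g] + rng.normal(0.0, tau, size=m)
            for rep in range(n_replicates):
                col = f"{ct}_r{rep + 1}"
                cols[col] = profile + rng.normal(0.0, 0.1, size=m)
                rep_map[col] = ct
    data = pd.DataFrame(cols, index=genes)
    return ReferenceMatrix(data, rep_map), grouping


def simulate_genotype_panel(n_strains: int = 80, n_chromosomes: int = 20,
                            loci_per_chromosome: int = 25,
                            recomb_prob: float = 0.1,
                            seed: int | None = None) -> GenotypeMatrix:
    """Fabricate a recombinant-inbred genotype panel.

    Alleles follow a Markov chain along each chromosome: the first locus is a
    fair coin per strain and each subsequent locus flips allele with
    probability ``recomb_prob``, giving the long identical-by-descent runs
    typical of RI panels. All calls are homozygous.
    """
    rng = np.random.default_rng(seed)
    loci, columns = [], []
    codes = np.empty((n_strains, n_chromosomes * loci_per_chromosome), dtype=np.int8)
    j = 0
    for chrom in range(1, n_chromosomes + 1):
        state = rng.integers(0, 2, size=n_strains)
        for i in range(loci_per_chromosome):
            if i > 0:
                flip = rng.random(n_strains) < recomb_prob
                state = np.where(flip, 1 - state, state)
            locus_id = f"rs{chrom:02d}_{i:03d}"
            loci.append(Locus(locus_id, str(chrom), 5.0 + 4.0 * i))
            columns.append(locus_id)
            codes[:, j] = state
            j += 1
    strains = [f"BXS{i:03d}" for i in range(1, n_strains + 1)]
    return GenotypeMatrix(pd.DataFrame(codes, index=strains, columns=columns), loci)


def _positive_pairs(gt: GroundTruth, siblings: SiblingMap,
                    ld_collapse: bool, geno: GenotypeMatrix | None
                    ) -> set[tuple[str, str]]:
    if ld_collapse and geno is None:
        raise ValueError("ld_collapse requires the genotype matrix")
    positives = set()
    for q in gt.iqtls:
        dec_ct = siblings.deconvolution_sibling(q.cell_type)
        loci = [q.locus]
        if ld_collapse:
            sub = geno.codes.loc[gt.strains]
            ref_col = sub[q.locus].to_numpy()
            loci = [v for v in sub.columns
                    if np.array_equal(sub[v].to_numpy(), ref_col)]
        positives.update((dec_ct, v) for v in loci)
    return positives


def evaluate_result(result, gt: GroundTruth, siblings: SiblingMap,
                    mode: str = "auc", ld_collapse: bool = False,
                    geno: GenotypeMatrix | None = None):
    """Score predictions against the simulated ground truth.

    The label universe is every (deconvolution cell type, locus) pair; a pair
    is positive iff the locus is a simulated cell-abundance QTL whose target
    generation cell type is the sibling of that deconvolution cell type (with
    ``ld_collapse``, loci genotype-identical to the causal one over the used
    strains also count). ``mode='auc'`` ranks -log10 aggregated p-values
    (ties counted half); ``mode='fpr_tpr'`` scores a significance set.
    """
    try:
        mapped = {q.cell_type: siblings.deconvolution_sibling(q.cell_type)
                  for q in gt.iqtls}
    except KeyError as exc:
        raise ValueError(f"ground-truth cell type {exc} missing from sibling map")
    positives = _positive_pairs(gt, siblings, ld_collapse, geno)

    if mode == "auc":
        data = result.data
        bad = {c for c, _ in positives} - set(data.index)
        if bad:
            raise ValueError(f"expected deconvolution cell types absent from "
                             f"associations: {sorted(bad)}")
        scores = -np.log10(np.clip(data.to_numpy(dtype=float), 1e-300, 1.0)).ravel()
        labels = np.array([(c, v) in positives
                           for c in data.index for v in data.columns])
        return _rank_auc(scores, labels)
    if mode == "fpr_tpr":
        if not isinstance(result, SignificanceSet):
            raise TypeError("fpr_tpr mode expects a SignificanceSet")
        if geno is None:
            raise ValueError("fpr_tpr mode needs the genotype matrix for the "
                             "locus universe")
        universe_cts = {d for _, d in siblings.pairs}
        n_pos = len(positives)
        tp = len(result.pairs & positives)
        fp = len(result.pairs - positives)
        n_neg = len(universe_cts) * len(geno.locus_ids) - n_pos
        return (fp / n_neg if n_neg else 0.0, tp / n_pos if n_pos else 0.0)
    raise ValueError(f"unknown mode: {mode}")


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of scores for labels, ties counted half."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative pairs")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
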