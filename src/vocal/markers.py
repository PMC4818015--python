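"""Marker-set construction and eQTL-confounder filtration.

A marker set F^(u) is a subset of reference genes whose tissue expression
serves as the observations of the deconvolution regression. The algorithm
works with k pairwise-disjoint sets, built sequentially so each set draws
only from genes not claimed by earlier sets. The filtration step removes
genes whose expression is controlled by an eQTL coinciding with a putative
cell-abundance QTL, since such genes can fake an abundance signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ReferenceMatrix

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-12

METHODS = ("top_varying", "cell_tagging", "cell_tagging_facs", "random")


@dataclass
class MarkerSet:
    index: int  # u, 1-based
    genes: list[str]
    psi: int  # target size

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"marker set {self.index}: duplicate genes")
        if len(self.genes) > self.psi:
            raise ValueError(f"marker set {self.index}: {len(self.genes)} genes "
                             f"exceeds target size {self.psi}")


@dataclass
class MarkerSetCollection:
    sets: list[MarkerSet]
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.sets:
            overlap = seen & set(s.genes)
            if overlap:
                raise ValueError(f"marker sets are not disjoint: {sorted(overlap)[:5]}")
            seen |= set(s.genes)

    @property
    def all_genes(self) -> list[str]:
        return [g for s in self.sets for g in s.genes]

    def nonempty_sets(self) -> list[MarkerSet]:
        return [s for s in self.sets if s.genes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([(s.index, g) for s in self.sets for g in s.genes],
                            columns=["set", "gene"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, method: str = "unknown") -> "MarkerSetCollection":
        df = pd.read_csv(path, sep="\t", dtype={"set": int, "gene": str})
        sets = []
        for u, grp in df.groupby("set", sort=True):
            genes = list(grp["gene"])
            sets.append(MarkerSet(int(u), genes, psi=len(genes)))
        return cls(sets, method=method)


@dataclass
class SignificanceSet:
    """Pairs of (entity, locus) whose association beat a -log10 p threshold."""

    pairs: set[tuple[str, str]]
    threshold: float

    def loci(self) -> set[str]:
        return {v for _, v in self.pairs}

    def entities(self) -> set[str]:
        return {e for e, _ in self.pairs}


def cell_tagging_scores(ref: ReferenceMatrix) -> pd.DataFrame:
    """Score each gene's power to tag its top-expressing cell type.

    For every gene, cell types are ranked by mean expression; the score is the
    pooled-variance two-sample t-test p-value between the top cell type's
    replicates and the pooled replicates of the second- and third-ranked cell
    types. The score is attributed to the top cell type only.

    Without replicate annotations a scale-normalised separation score is used
    instead, mapped monotonically so that smaller still means better.

    Returns a DataFrame indexed by gene with columns ``cell_type`` and
    ``score`` (a p-value, or p-like quantity in the fallback).
    """
    cell_types = ref.cell_type_ids
    if len(cell_types) < 3:
        raise ValueError(f"cell tagging needs >=3 cell types, got {len(cell_types)}")
    means = ref.collapse().data[cell_types]
    order = np.argsort(-means.to_numpy(), axis=1, kind="stable")
    top = [cell_types[i] for i in order[:, 0]]

    if ref.has_replicates and all(len(ref.replicate_columns(c)) >= 2 for c in cell_types):
        scores = _replicate_t_scores(ref, means, order, cell_types)
    else:
        scores = _separation_scores(means, order)
    return pd.DataFrame({"cell_type": top, "score": scores}, index=means.index)


def _replicate_t_scores(ref, means, order, cell_types) -> np.ndarray:
    rep_cols = {c: ref.replicate_columns(c) for c in cell_types}
    data = ref.data
    n_genes = data.shape[0]
    scores = np.empty(n_genes)
    floored = 0
    for i in range(n_genes):
        top_c = cell_types[order[i, 0]]
        others = [cell_types[order[i, 1]], cell_types[order[i, 2]]]
        a = data.iloc[i][rep_cols[top_c]].to_numpy(dtype=float)
        b = np.concatenate([data.iloc[i][rep_cols[c]].to_numpy(dtype=float)
                            for c in others])
        scores[i], was_floored = _pooled_t_pvalue(a, b)
        floored += was_floored
    if floored:
        logger.warning("cell tagging: pooled variance floored at %g for %d genes",
                       VARIANCE_FLOOR, floored)
    return scores


def _pooled_t_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    diff = a.mean() - b.mean()
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    sp2 = ss / df
    floored = sp2 < VARIANCE_FLOOR
    sp2 = max(sp2, VARIANCE_FLOOR)
    if diff == 0.0:
        return 1.0, floored
    t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2.0 * stats.t.sf(abs(t), df), floored


def _separation_scores(means: pd.DataFrame, order: np.ndarray) -> np.ndarray:
    """No-replicate fallback: top minus mean(2nd, 3rd), over a robust scale."""
    vals = means.to_numpy()
    rows = np.arange(vals.shape[0])
    top = vals[rows, order[:, 0]]
    second = vals[rows, order[:, 1]]
    third = vals[rows, order[:, 2]]
    med = np.median(vals, axis=1, keepdims=True)
    mad = np.median(np.abs(vals - med), axis=1)
    scale = np.maximum(1.4826 * mad, np.sqrt(VARIANCE_FLOOR))
    sep = (top - 0.5 * (second + third)) / scale
    # monotone map to (0, 1]: larger separation -> smaller score
    return 1.0 / (1.0 + np.maximum(sep, 0.0))


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def init_marker_sets(ref: ReferenceMatrix, method: str, k: int, psi: int,
                     facs_genes: list[str] | None = None,
                     seed: int | None = None) -> MarkerSetCollection:
    """Build k pairwise-disjoint marker sets from the reference data.

    Sets are constructed one after the other, each drawing only from genes not
    used by earlier sets. See :data:`METHODS` for the available strategies.
    """
    if method not in METHODS:
        raise ValueError(f"unknown initialization method: {method}")
    if method == "cell_tagging_facs" and facs_genes is None:
        raise ValueError("cell_tagging_facs requires a facs_genes list")
    if method != "cell_tagging_facs" and facs_genes is not None:
        raise ValueError(f"facs_genes only applies to cell_tagging_facs, not {method}")

    universe = list(ref.gene_ids)
    pool = set(universe)
    rng = np.random.default_rng(seed)

    if method == "cell_tagging_facs":
        facs = [g for g in facs_genes if g in pool]
        needed = len(facs) + (k - 1) * psi
    else:
        needed = k * psi
    if needed > len(universe):
        raise ValueError(f"insufficient gene pool: need {needed}, have {len(universe)}")

    tag_table = (cell_tagging_scores(ref)
                 if method in ("cell_tagging", "cell_tagging_facs") else None)
    variances = (ref.collapse().data.var(axis=1, ddof=1)
                 if method == "top_varying" else None)

    sets: list[MarkerSet] = []
    for u in range(1, k + 1):
        if method == "cell_tagging_facs" and u == 1:
            genes = list(facs)
        elif method == "random":
            genes = sorted(rng.choice(sorted(pool), size=psi, replace=False).tolist())
        elif method == "top_varying":
            remaining = variances[variances.index.isin(pool)]
            ranked = remaining.sort_values(ascending=False, kind="stable")
            genes = list(ranked.index[:psi])
        else:  # cell_tagging
            genes = _cell_tagging_set(tag_table, pool, ref.cell_type_ids, psi)
        sets.append(MarkerSet(u, genes, psi=max(psi, len(genes))))
        pool -= set(genes)
    return MarkerSetCollection(sets, method=method, seed=seed)


def _cell_tagging_set(table: pd.DataFrame, pool: set[str],
                      cell_types: list[str], psi: int) -> list[str]:
    """Round-robin over cell types, best remaining tagging score first.

    Ties in score break lexicographically by gene id for reproducibility.
    """
    avail = table[table.index.isin(pool)]
    queues = {
        c: list(sub.sort_index(kind="stable")
                .sort_values("score", kind="stable").index)
        for c, sub in avail.groupby("cell_type")
    }
    chosen: list[str] = []
    taken: set[str] = set()
    while len(chosen) < psi:
        progressed = False
        for c in cell_types:
            if len(chosen) >= psi:
                break
            q = queues.get(c)
            while q:
                g = q.pop(0)
                if g not in taken:
                    chosen.append(g)
                    taken.add(g)
                    progressed = True
                    break
        if not progressed:
            break  # every cell type exhausted its candidates
    return chosen


def compute_confounded_genes(w_i: SignificanceSet,
                             w_e: SignificanceSet) -> set[str]:
    """Genes with a significant eQTL at a locus that is also a significant
    cell-abundance QTL for any immune trait."""
    iqtl_loci = w_i.loci()
    return {g for g, v in w_e.pairs if v in iqtl_loci}


def filter_marker_sets(coll: MarkerSetCollection,
                       f_prime: set[str]) -> tuple[MarkerSetCollection, int]:
    """Remove the confounded genes from every set; returns total removed."""
    new_sets, removed = [], 0
    for s in coll.sets:
        kept = [g for g in s.genes if g not in f_prime]
        removed += len(s.genes) - len(kept)
        if not kept and s.genes:
            logger.warning("marker set %d emptied by filtration", s.index)
        new_sets.append(MarkerSet(s.index, kept, psi=s.psi))
    return MarkerSetCollection(new_sets, method=coll.method, seed=coll.seed), removed
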