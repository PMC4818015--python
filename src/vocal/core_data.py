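"""Typed containers and I/O for expression, reference and genotype data.

All tabular files are tab-separated UTF-8 with a '.' decimal point, the first
column holding row identifiers and the first row column identifiers.
Genotypes additionally support the GeneNetwork-style ``.geno`` dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype codes: homozygous for either parental allele, heterozygous, or no call
ALLELE_A = 0  # e.g. the B6 allele in a BXD panel
ALLELE_B = 1  # e.g. the D2 allele
HETEROZYGOUS = 2
UNKNOWN = 3

_GENO_SYMBOLS = {"B": ALLELE_A, "D": ALLELE_B, "H": HETEROZYGOUS, "U": UNKNOWN}


class DataFormatError(ValueError):
    """Raised when an input file violates the expected tabular contract."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate {what}: {dups}")


@dataclass
class GeneExpressionMatrix:
    """Log-scale expression of genes (rows) across samples (columns)."""

    data: pd.DataFrame  # genes x samples

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise DataFormatError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


@dataclass
class ReferenceMatrix:
    """Expression signatures of isolated cell types (genes x columns).

    ``replicate_map`` maps a column id to its parent cell type; when present,
    several columns may belong to one cell type and :meth:`collapse` averages
    them into a single column per cell type.
    """

    data: pd.DataFrame  # genes x columns
    replicate_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "reference column ids")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise DataFormatError("reference matrix contains non-finite values")
        if self.replicate_map is not None:
            missing = set(self.replicate_map) - set(self.data.columns)
            if missing:
                raise DataFormatError(
                    f"replicate map references unknown columns: {sorted(missing)}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_type_ids(self) -> list[str]:
        """Unique cell types, in first-appearance column order."""
        if self.replicate_map is None:
            return list(self.data.columns)
        out: list[str] = []
        for col in self.data.columns:
            ct = self.replicate_map.get(col, col)
            if ct not in out:
                out.append(ct)
        return out

    @property
    def has_replicates(self) -> bool:
        return self.replicate_map is not None

    def replicate_columns(self, cell_type: str) -> list[str]:
        if self.replicate_map is None:
            return [cell_type] if cell_type in self.data.columns else []
        return [c for c in self.data.columns if self.replicate_map.get(c, c) == cell_type]

    def collapse(self) -> "ReferenceMatrix":
        """One column per cell type, replicates averaged."""
        if self.replicate_map is None:
            return self
        cols = {ct: self.data[self.replicate_columns(ct)].mean(axis=1)
                for ct in self.cell_type_ids}
        return ReferenceMatrix(pd.DataFrame(cols, index=self.data.index))

    def restrict_cell_types(self, cell_types) -> "ReferenceMatrix":
        keep = [c for c in self.data.columns
                if (self.replicate_map.get(c, c) if self.replicate_map else c) in set(cell_types)]
        rep = ({c: self.replicate_map[c] for c in keep if c in self.replicate_map}
               if self.replicate_map else None)
        return ReferenceMatrix(self.data[keep].copy(), rep)

    def write(self, path, replicate_map_path=None) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")
        if replicate_map_path is not None and self.replicate_map is not None:
            pd.Series(self.replicate_map, name="cell_type").rename_axis("column").to_csv(
                replicate_map_path, sep="\t")


@dataclass(frozen=True)
class Locus:
    id: str
    chromosome: str
    position: float  # physical position, Mbp

    def __post_init__(self) -> None:
        if self.position < 0:
            raise DataFormatError(f"locus {self.id}: negative position {self.position}")


def _chrom_key(chrom: str):
    # numeric chromosomes before lettered ones (X, Y, M), both in natural order
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, str(chrom))


@dataclass
class GenotypeMatrix:
    """Homozygous allele codes per strain per locus, with a genetic map."""

    codes: pd.DataFrame  # strains x loci, int8 codes
    loci: list[Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.codes.index, "strain ids")
        _check_unique(self.codes.columns, "locus ids")
        if len(self.loci) != self.codes.shape[1]:
            raise DataFormatError("locus records do not match genotype columns")
        vals = self.codes.to_numpy()
        bad = set(np.unique(vals)) - {ALLELE_A, ALLELE_B, HETEROZYGOUS, UNKNOWN}
        if bad:
            raise DataFormatError(f"invalid genotype codes: {sorted(bad)}")
        # keep loci sorted along the genome
        order = sorted(range(len(self.loci)),
                       key=lambda i: (_chrom_key(self.loci[i].chromosome),
                                      self.loci[i].position))
        if order != list(range(len(self.loci))):
            self.loci = [self.loci[i] for i in order]
            self.codes = self.codes.iloc[:, order]

    @property
    def strain_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.codes.columns)

    def locus(self, locus_id: str) -> Locus:
        return self.loci[self.locus_ids.index(locus_id)]

    def column(self, locus_id: str) -> np.ndarray:
        """The genotype vector d^(v) across strains for one locus."""
        return self.codes[locus_id].to_numpy()

    def restrict_strains(self, strains) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes.loc[list(strains)].copy(), list(self.loci))

    def write(self, path) -> None:
        """tsv01 dialect: locus/chrom/pos columns then one 0/1/H/NA code per strain."""
        sym = {ALLELE_A: "0", ALLELE_B: "1", HETEROZYGOUS: "H", UNKNOWN: "NA"}
        out = pd.DataFrame(
            {"locus": self.locus_ids,
             "chrom": [l.chromosome for l in self.loci],
             "pos": [l.position for l in self.loci]})
        body = self.codes.T.reset_index(drop=True).apply(lambda col: col.map(sym))
        body.columns = self.strain_ids
        pd.concat([out, body], axis=1).to_csv(path, sep="\t", index=False)


def _read_numeric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.size == 0:
        raise DataFormatError(f"{path}: no data columns found")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(num.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise DataFormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}")
    # re-parse through Python's correctly rounded float so that write+read
    # round-trips bit-exactly
    return df.map(float)


def read_expression_matrix(path, fmt: str = "tsv") -> GeneExpressionMatrix:
    """Read a genes x samples TSV; duplicate gene rows are mean-collapsed."""
    if fmt != "tsv":
        raise ValueError(f"unsupported format: {fmt}")
    df = _read_numeric_table(path)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("%s: collapsing duplicate gene rows by mean: %s", path, dups)
        df = df.groupby(level=0, sort=False).mean()
    return GeneExpressionMatrix(df)


def read_replicate_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: replicate map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_reference_matrix(path, replicate_map=None) -> ReferenceMatrix:
    df = _read_numeric_table(path)
    rep = read_replicate_map(replicate_map) if replicate_map is not None else None
    return ReferenceMatrix(df, rep)


def read_genotypes(path, dialect: str = "geno") -> GenotypeMatrix:
    """Read genotypes in the GeneNetwork ``geno`` dialect or the ``tsv01`` dialect."""
    if dialect == "geno":
        return _read_geno(path)
    if dialect == "tsv01":
        return _read_tsv01(path)
    raise ValueError(f"unknown genotype dialect: {dialect}")


def _read_geno(path) -> GenotypeMatrix:
    rows, loci, strains = [], [], None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("@"):
                continue
            fields = line.split("\t")
            if strains is None:
                if fields[0] != "Chr":
                    raise DataFormatError(f"{path}: expected header starting with 'Chr'")
                header = fields
                # position column: prefer physical Mb when present, else cM
                pos_col = header.index("Mb") if "Mb" in header else header.index("cM")
                first_strain = max(pos_col, header.index("Locus")) + 1
                strains = header[first_strain:]
                continue
            chrom, locus_id = fields[0], fields[1]
            loci.append(Locus(locus_id, chrom, float(fields[pos_col])))
            codes = []
            for sym in fields[first_strain:]:
                sym = sym.strip()
                if sym not in _GENO_SYMBOLS:
                    raise DataFormatError(f"{path}: unknown genotype symbol {sym!r} "
                                          f"at locus {locus_id}")

                codes.append(_GENO_SYMBOLS[sym])
            rows.append(codes)
    if strains is None:
        raise DataFormatError(f"{path}: no header found")
    codes = pd.DataFrame(np.asarray(rows, dtype=np.int8).T, index=strains,
                         columns=[l.id for l in loci])
    return GenotypeMatrix(codes, loci)


_TSV01_SYMBOLS = {"0": ALLELE_A, "1": ALLELE_B, "H": HETEROZYGOUS,
                  "NA": UNKNOWN, "U": UNKNOWN}


def _read_tsv01(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 4:
        raise DataFormatError(f"{path}: tsv01 needs locus/chrom/pos plus strain columns")
    strains = list(df.columns[3:])
    loci = [Locus(r[0], r[1], float(r[2])) for r in df.iloc[:, :3].itertuples(index=False)]
    body = df.iloc[:, 3:]
    codes = np.empty(body.shape, dtype=np.int8)
    for (i, j), sym in np.ndenumerate(body.to_numpy()):
        sym = str(sym).strip()
        if sym not in _TSV01_SYMBOLS:
            raise DataFormatError(f"{path}: unknown genotype symbol {sym!r} "
                                  f"at locus {loci[i].id}, strain {strains[j]}")
        codes[i, j] = _TSV01_SYMBOLS[sym]
    frame = pd.DataFrame(codes.T, index=strains, columns=[l.id for l in loci])
    return GenotypeMatrix(frame, loci)


def normalize_to_baseline(expr: GeneExpressionMatrix,
                          baseline_sample: str) -> GeneExpressionMatrix:
    """Subtract the baseline sample's profile from every sample and drop it.

    Intended for log-scale data, where subtraction is a log fold change
    relative to the baseline individual.
    """
    if baseline_sample not in expr.data.columns:
        raise KeyError(f"baseline sample {baseline_sample!r} not in expression matrix")
    base = expr.data[baseline_sample]
    out = expr.data.drop(columns=[baseline_sample]).sub(base, axis=0)
    return GeneExpressionMatrix(out)


def align_genes(expr: GeneExpressionMatrix,
                ref: ReferenceMatrix) -> tuple[GeneExpressionMatrix, ReferenceMatrix]:
    """Restrict both matrices to their shared genes, in a common order."""
    shared = [g for g in expr.gene_ids if g in set(ref.gene_ids)]
    if not shared:
        raise ValueError("expression and reference matrices share no genes")
    logger.info("aligned gene universe: %d shared genes", len(shared))
    return (GeneExpressionMatrix(expr.data.loc[shared].copy()),
            ReferenceMatrix(ref.data.loc[shared].copy(),
                            dict(ref.replicate_map) if ref.replicate_map else None))
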