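"""Readers and writers for the external formats consumed by the pipeline.

Coordinate conventions: VCF positions and all user-facing tables are 1-based
inclusive; interval arithmetic inside the package (gene/exon/promoter overlap,
FST windows) is 0-based half-open.  Conversion happens here, at the I/O
boundary, and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("xomap")

MISSING = -1  # missing allele code inside genotype arrays

#: fixed individual order used everywhere in the package
QUARTET_ROLES = ("father", "mother", "son", "daughter")


# ---------------------------------------------------------------------------
# VariantTable
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Biallelic-SNP genotypes for one quartet (father, mother, son, daughter).

    Attributes
    ----------
    samples : tuple of 4 str
        Sample names, in father/mother/son/daughter order.
    chrom, pos, ref, alt : arrays of length ``n_sites``
        ``pos`` is 1-based and strictly increasing within each chromosome.
    gt : int8 array, shape (n_sites, 4, 2)
        Unordered allele pairs over {0, 1}; ``MISSING`` (-1) marks missing.
    gq : int32 array, shape (n_sites, 4)
        Genotype quality per individual.
    tp : int32 array, shape (n_sites, 4), or None
        Phasing-confidence score; absent before phasing.
    """

    samples: tuple
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    gq: np.ndarray
    tp: np.ndarray | None = None

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.gt.shape != (self.n_sites, 4, 2):
            raise ValueError(f"gt shape {self.gt.shape} != ({self.n_sites}, 4, 2)")
        for name in self.chroms():
            p = self.pos[self.chrom == name]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {name}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def chroms(self) -> list:
        """Chromosome names in order of first appearance."""
        _, idx = np.unique(self.chrom, return_index=True)
        return [self.chrom[i] for i in np.sort(idx)]

    def for_chrom(self, name) -> "VariantTable":
        m = self.chrom == name
        return VariantTable(
            self.samples, self.chrom[m], self.pos[m], self.ref[m], self.alt[m],
            self.gt[m], self.gq[m], None if self.tp is None else self.tp[m],
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        for i, role in enumerate(QUARTET_ROLES):
            cols[f"{role}_a1"] = self.gt[:, i, 0]
            cols[f"{role}_a2"] = self.gt[:, i, 1]
            cols[f"{role}_gq"] = self.gq[:, i]
            if self.tp is not None:
                cols[f"{role}_tp"] = self.tp[:, i]
        return pd.DataFrame(cols)


def read_vcf_quartet(path, individual_ids) -> VariantTable:
    """Read a quartet VCF into a :class:`VariantTable`.

    ``individual_ids`` names the father, mother, son and daughter (in that
    order).  Indels, multiallelic records and malformed records are dropped
    (counts logged); a missing individual is fatal.
    """
    from cyvcf2 import VCF

    individual_ids = tuple(individual_ids)
    if len(individual_ids) != 4:
        raise ValueError("a quartet needs exactly 4 individual ids")
    vcf = VCF(str(path))
    absent = [s for s in individual_ids if s not in vcf.samples]
    if absent:
        raise ValueError(f"individuals {absent} not present in {path}")
    vcf.set_samples(list(individual_ids))
    order = [vcf.samples.index(s) for s in individual_ids]

    chrom, pos, ref, alt, gts, gqs, tps = [], [], [], [], [], [], []
    n_indel = n_multi = n_malformed = 0
    any_tp = False
    for var in vcf:
        try:
            if len(var.ALT) != 1 or not var.is_snp:
                if var.is_indel:
                    n_indel += 1
                else:
                    n_multi += 1
                continue
            g = np.array(var.genotypes, dtype=np.int64)[order, :2]
            g[g < 0] = MISSING
            gq = var.format("GQ")
            gq = (np.zeros(4) if gq is None
                  else np.nan_to_num(gq.astype(np.float64).reshape(-1)[order]))
            try:
                tp = var.format("TP")
            except KeyError:  # TP not declared in the header
                tp = None
            if tp is not None:
                any_tp = True
                tp = np.nan_to_num(tp.astype(np.float64).reshape(-1)[order])
            else:
                tp = np.zeros(4)
        except Exception:  # malformed record
            n_malformed += 1
            continue
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        gts.append(g.astype(np.int8))
        gqs.append(gq.astype(np.int32))
        tps.append(tp.astype(np.int32))

    if n_indel or n_multi or n_malformed:
        logger.info(
            "read_vcf_quartet(%s): dropped %d indels, %d multiallelic, "
            "%d malformed; retained %d SNPs", path, n_indel, n_multi,
            n_malformed, len(pos))
    n = len(pos)
    table = VariantTable(
        individual_ids,
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object),
        np.array(alt, dtype=object),
        np.array(gts, dtype=np.int8).reshape(n, 4, 2),
        np.array(gqs, dtype=np.int32).reshape(n, 4),
        np.array(tps, dtype=np.int32).reshape(n, 4) if any_tp else None,
    )
    return table


def write_quartet_vcf(table: VariantTable, path, contig_lengths=None) -> None:
    """Write a :class:`VariantTable` as an uncompressed VCF 4.2 file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=xomap\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in table.chroms():
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if table.tp is not None:
            fh.write('##FORMAT=<ID=TP,Number=1,Type=Integer,'
                     'Description="Phasing confidence">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        fmt = "GT:GQ:TP" if table.tp is not None else "GT:GQ"
        for i in range(table.n_sites):
            fields = [str(table.chrom[i]), str(table.pos[i]), ".",
                      str(table.ref[i]), str(table.alt[i]), ".", "PASS", ".",
                      fmt]
            for j in range(4):
                a, b = table.gt[i, j]
                gt = "./." if a == MISSING or b == MISSING else f"{a}/{b}"
                cell = f"{gt}:{table.gq[i, j]}"
                if table.tp is not None:
                    cell += f":{table.tp[i, j]}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Chromosome metadata
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeMeta:
    """Length, centromere position and sex flag for one chromosome."""

    name: str
    length_bp: int
    centromere_pos_bp: int | None = None
    is_sex_chromosome: bool = False

    def __post_init__(self):
        if self.centromere_pos_bp is not None:
            if not 0 < self.centromere_pos_bp < self.length_bp:
                raise ValueError(
                    f"{self.name}: centromere {self.centromere_pos_bp} outside "
                    f"(0, {self.length_bp})")

    @property
    def short_arm_bp(self) -> int | None:
        if self.centromere_pos_bp is None:
            return None
        return min(self.centromere_pos_bp, self.length_bp - self.centromere_pos_bp)

    @property
    def long_arm_bp(self) -> int | None:
        if self.centromere_pos_bp is None:
            return None
        return max(self.centromere_pos_bp, self.length_bp - self.centromere_pos_bp)


_TRUTHY = {"1", "true", "yes", "sex"}


def read_chrom_meta(path) -> list:
    """Read a chromosome-metadata TSV.

    Columns: ``name``, ``length_bp``, ``centromere_pos_bp`` (may be empty for
    chromosomes where the centromere could not be localized), ``is_sex_chromosome``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    metas = []
    for row in df.itertuples(index=False):
        cen = getattr(row, "centromere_pos_bp", None)
        cen = None if cen is None or pd.isna(cen) else int(cen)
        sex = getattr(row, "is_sex_chromosome", False)
        sex = str(sex).strip().lower() in _TRUTHY
        metas.append(ChromosomeMeta(str(row.name), int(row.length_bp), cen, sex))
    n_nocen = sum(m.centromere_pos_bp is None for m in metas)
    if n_nocen:
        logger.info("read_chrom_meta: %d chromosomes lack a centromere and are "
                    "excluded from centromere analyses", n_nocen)
    return metas


def write_chrom_meta(metas, path) -> None:
    pd.DataFrame(
        {"name": [m.name for m in metas],
         "length_bp": [m.length_bp for m in metas],
         "centromere_pos_bp": [m.centromere_pos_bp for m in metas],
         "is_sex_chromosome": [int(m.is_sex_chromosome) for m in metas]},
    ).to_csv(path, sep="\t", index=False)


def meta_dict(metas) -> dict:
    return {m.name: m for m in metas}


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotationSet:
    """Gene and exon intervals, 0-based half-open internally.

    ``genes`` columns: chrom, start, end, strand, gene_id.
    ``exons`` columns: chrom, start, end, gene_id (empty frame when the source
    carries no exon structure, e.g. plain BED genes).
    """

    genes: pd.DataFrame
    exons: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "gene_id"]))

    def __post_init__(self):
        if len(self.exons):
            spans = self.genes.set_index("gene_id")
            for row in self.exons.itertuples(index=False):
                g = spans.loc[row.gene_id]
                if row.start < g.start or row.end > g.end:
                    raise ValueError(f"exon outside gene span for {row.gene_id}")

    def promoters(self, chrom_lengths=None, promoter_bp: int = 2000) -> pd.DataFrame:
        """Strand-aware promoters: ``promoter_bp`` upstream of the TSS.

        Plus strand: [start - promoter_bp, start); minus strand: [end, end +
        promoter_bp).  Truncated at chromosome edges when lengths are given.
        """
        g = self.genes
        plus = g.strand != "-"
        start = np.where(plus, g.start - promoter_bp, g.end)
        end = np.where(plus, g.start, g.end + promoter_bp)
        start = np.maximum(start, 0)
        if chrom_lengths is not None:
            lim = g.chrom.map(chrom_lengths).to_numpy()
            end = np.minimum(end, lim)
        out = pd.DataFrame({"chrom": g.chrom, "start": start, "end": end,
                            "gene_id": g.gene_id})
        return out[out.end > out.start].reset_index(drop=True)

    def introns(self) -> pd.DataFrame:
        """Gene span minus exons, per gene."""
        rows = []
        for gid, ex in self.exons.groupby("gene_id"):
            g = self.genes[self.genes.gene_id == gid].iloc[0]
            ex = ex.sort_values("start")
            cursor = g.start
            for row in ex.itertuples(index=False):
                if row.start > cursor:
                    rows.append((g.chrom, cursor, row.start, gid))
                cursor = max(cursor, row.end)
            if cursor < g.end:
                rows.append((g.chrom, cursor, g.end, gid))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def read_bed_genes(path) -> GeneAnnotationSet:
    """Read genes from BED (>=3 columns; BED start is already 0-based)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = pd.DataFrame({
        "chrom": df[0].astype(str),
        "start": df[1].astype(int),
        "end": df[2].astype(int),
        "strand": df[5].astype(str) if df.shape[1] > 5 else "+",
        "gene_id": df[3].astype(str) if df.shape[1] > 3
                   else [f"gene{i}" for i in range(len(df))],
    })
    return GeneAnnotationSet(genes)


def _gff3_attr(attrs: str, *keys) -> str | None:
    for item in attrs.rstrip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            if k.strip() in keys:
                return v.strip()
    return None


def read_gff3(path) -> GeneAnnotationSet:
    """Read gene and exon features from GFF3 (1-based inclusive on disk)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"],
                     dtype={"chrom": str})
    g = df[df.type == "gene"].reset_index(drop=True)
    genes = pd.DataFrame({
        "chrom": g.chrom, "start": g.start - 1, "end": g.end,
        "strand": g.strand,
        "gene_id": [_gff3_attr(a, "ID", "gene_id") or f"gene{i}"
                    for i, a in enumerate(g["attributes"])],
    })
    e = df[df.type == "exon"].reset_index(drop=True)
    exons = pd.DataFrame({
        "chrom": e.chrom, "start": e.start - 1, "end": e.end,
        "gene_id": [_gff3_attr(a, "Parent", "gene_id") or ""
                    for a in e["attributes"]],
    })
    return GeneAnnotationSet(genes, exons)


def read_annotations(path) -> GeneAnnotationSet:
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return read_gff3(path)
    return read_bed_genes(path)


# ---------------------------------------------------------------------------
# FST windows
# ---------------------------------------------------------------------------

def read_fst_windows(path) -> pd.DataFrame:
    """Read a per-window FST TSV with columns chrom, start, end, fst.

    ``start`` is 1-based inclusive on disk and converted to 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.rename(columns=str.lower)
    out = df[["chrom", "start", "end", "fst"]].copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    return out
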