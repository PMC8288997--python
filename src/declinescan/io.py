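"""Core containers and file formats.

The pipeline's in-memory currency is :class:`GenotypeMatrix`: biallelic sites
x diploid individuals, with genotype codes, optional per-genotype allele
depths and per-site base/mapping qualities.  Coordinates are 0-based
half-open internally; VCF and GFF3 conversion happens at the I/O boundary
(both formats are 1-based inclusive on disk).

Genotype codes: 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.  Missing is
always a distinct code, never conflated with hom-ref.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

SITE_COLUMNS = ["scaffold", "pos", "ref", "alt", "qual", "mq"]


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes for a panel of individuals.

    Parameters
    ----------
    samples
        Individual identifiers, in column order of ``gt``.
    sites
        DataFrame with columns ``scaffold, pos (1-based), ref, alt, qual, mq``
        and optionally ``ancestral`` (the known ancestral base, recorded by
        the simulators).
    gt
        ``(n_sites, n_samples)`` int8 array of genotype codes.
    ad_ref, ad_alt
        Optional ``(n_sites, n_samples)`` read-depth arrays per allele.
    """

    samples: list[str]
    sites: pd.DataFrame
    gt: np.ndarray
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"gt shape {self.gt.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def has_depths(self) -> bool:
        return self.ad_ref is not None and self.ad_alt is not None

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.sites.copy(),
            self.gt.copy(),
            None if self.ad_ref is None else self.ad_ref.copy(),
            None if self.ad_alt is None else self.ad_alt.copy(),
        )

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Row-subset by boolean mask or integer index array."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.samples),
            self.sites.iloc[idx].reset_index(drop=True),
            self.gt[idx],
            None if self.ad_ref is None else self.ad_ref[idx],
            None if self.ad_alt is None else self.ad_alt[idx],
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        missing = [s for s in names if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            list(names),
            self.sites.copy(),
            self.gt[:, cols],
            None if self.ad_ref is None else self.ad_ref[:, cols],
            None if self.ad_alt is None else self.ad_alt[:, cols],
        )

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage as float, missing -> NaN."""
        d = self.gt.astype(float)
        d[self.gt == MISSING] = np.nan
        return d

    def total_depth(self) -> np.ndarray:
        """Per-site depth summed over samples (requires allele depths)."""
        if not self.has_depths:
            raise ValueError("genotype matrix carries no allele depths")
        return (self.ad_ref + self.ad_alt).sum(axis=1)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              scaffold_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 (GT:AD:DP per sample, MQ as INFO)."""
    path = Path(path)
    scaffolds = list(dict.fromkeys(gm.sites["scaffold"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=declinescan\n")
        for sc in scaffolds:
            if scaffold_lengths and sc in scaffold_lengths:
                fh.write(f"##contig=<ID={sc},length={scaffold_lengths[sc]}>\n")
            else:
                length = int(gm.sites.loc[gm.sites["scaffold"] == sc, "pos"].max()) + 1
                fh.write(f"##contig=<ID={sc},length={length}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        if "ancestral" in gm.sites.columns:
            fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        has_aa = "ancestral" in gm.sites.columns
        for i, row in enumerate(gm.sites.itertuples(index=False)):
            info = f"MQ={row.mq:g}"
            if has_aa:
                info += f";AA={row.ancestral}"
            cells = []
            for j in range(gm.n_samples):
                g = _GT_STR[int(gm.gt[i, j])]
                if gm.has_depths:
                    r, a = int(gm.ad_ref[i, j]), int(gm.ad_alt[i, j])
                    cells.append(f"{g}:{r},{a}:{r + a}")
                else:
                    cells.append(g)
            fmt = "GT:AD:DP" if gm.has_depths else "GT"
            fh.write(f"{row.scaffold}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t"
                     f"{row.qual:g}\t.\t{info}\t{fmt}\t" + "\t".join(cells) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (plain-text) VCF into a :class:`GenotypeMatrix` via pysam."""
    recs = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        gts, adr, ada = [], [], []
        any_ad = False
        for rec in vf:
            if len(rec.alts or ()) != 1:
                continue  # biallelic SNVs only
            row = {
                "scaffold": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "qual": rec.qual if rec.qual is not None else np.nan,
                "mq": float(rec.info.get("MQ", np.nan)),
            }
            if "AA" in rec.info:
                aa = rec.info["AA"]
                row["ancestral"] = aa if isinstance(aa, str) else aa[0]
            recs.append(row)
            grow, rrow, arow = [], [], []
            for s in samples:
                call = rec.samples[s]
                alleles = call.get("GT", (None, None))
                if alleles is None or None in alleles:
                    grow.append(MISSING)
                else:
                    grow.append(int(alleles[0]) + int(alleles[1]))
                ad = call.get("AD")
                if ad is not None and ad[0] is not None:
                    any_ad = True
                    rrow.append(int(ad[0]))
                    arow.append(int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0)
                else:
                    rrow.append(0)
                    arow.append(0)
            gts.append(grow)
            adr.append(rrow)
            ada.append(arow)
    sites = pd.DataFrame(recs, columns=SITE_COLUMNS + (["ancestral"] if recs and "ancestral" in recs[0] else []))
    gt = np.array(gts, dtype=np.int8) if gts else np.zeros((0, len(samples)), np.int8)
    return GenotypeMatrix(
        samples, sites, gt,
        np.array(adr) if any_ad else None,
        np.array(ada) if any_ad else None,
    )


# ---------------------------------------------------------------------------
# Sidecar tables: sample sheet, scaffold lengths
# ---------------------------------------------------------------------------

def write_sample_sheet(table: pd.DataFrame, path: str | Path) -> None:
    """Sample sheet TSV with columns sample, species, population."""
    table.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "species", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return df


def write_scaffold_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, n in lengths.items():
            fh.write(f"{name}\t{int(n)}\n")


def read_scaffold_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "length"])
    return dict(zip(df["scaffold"].astype(str), df["length"].astype(int)))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Gene models (minimal GFF3 subset: one CDS chain per gene)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding gene.

    ``exons`` are half-open genomic ``[start, end)`` intervals (0-based),
    listed in transcript orientation (5'->3'): for a minus-strand gene the
    first exon is the right-most in genome coordinates.  Total CDS length
    must be a multiple of 3; the reading frame is anchored at CDS start.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        ss = [s for s, _ in self.exons]
        ee = [e for _, e in self.exons]
        return min(ss), max(ee)

    def transcript_position(self, genomic_pos: int) -> int | None:
        """Map a 0-based genomic position to a 0-based CDS position, or None."""
        offset = 0
        for s, e in self.exons:
            if s <= genomic_pos < e:
                if self.strand == "+":
                    return offset + (genomic_pos - s)
                return offset + (e - 1 - genomic_pos)
            offset += e - s
        return None

    def genomic_position(self, cds_pos: int) -> int:
        """Inverse of :meth:`transcript_position`."""
        offset = 0
        for s, e in self.exons:
            if cds_pos < offset + (e - s):
                k = cds_pos - offset
                return s + k if self.strand == "+" else e - 1 - k
            offset += e - s
        raise IndexError(cds_pos)

    def cds_sequence(self, ref: Mapping[str, str]) -> str:
        """Spliced CDS in transcript orientation from a scaffold->sequence map."""
        seq = ref[self.scaffold]
        parts = []
        for s, e in self.exons:
            chunk = seq[s:e]
            if self.strand == "-":
                chunk = str(Seq(chunk).reverse_complement())
            parts.append(chunk)
        return "".join(parts)


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + CDS features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            fh.write(f"{g.scaffold}\tdeclinescan\tgene\t{lo + 1}\t{hi}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            phase = 0
            for s, e in g.exons:
                fh.write(f"{g.scaffold}\tdeclinescan\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t{phase}\tParent={g.gene_id}\n")
                phase = (3 - ((e - s) - phase) % 3) % 3


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the minimal GFF3 subset written by :func:`write_gene_models`."""
    rows = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["scaffold", "source", "type", "start", "end",
               "score", "strand", "phase", "attributes"],
        dtype={"scaffold": str},
    )
    cds = rows[rows["type"] == "CDS"]
    genes: dict[str, dict] = {}
    for r in cds.itertuples(index=False):
        attrs = dict(kv.split("=", 1) for kv in str(r.attributes).split(";") if "=" in kv)
        gid = attrs.get("Parent") or attrs.get("ID")
        if gid is None:
            raise ValueError(f"CDS feature without Parent/ID on {r.scaffold}:{r.start}")
        g = genes.setdefault(gid, {"scaffold": r.scaffold, "strand": r.strand, "exons": []})
        g["exons"].append((int(r.start) - 1, int(r.end)))
    out = []
    for gid, g in genes.items():
        exons = sorted(g["exons"])
        if g["strand"] == "-":
            exons = exons[::-1]
        out.append(GeneModel(gid, g["scaffold"], g["strand"], tuple(exons)))
    return out
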