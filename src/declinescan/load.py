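"""Deleterious-variant classification and genetic-load statistics.

Ancestral states follow a two-species rule: the allele homozygous in more
than half of the focal species' individuals AND fixed homozygous in the
sister species (the outgroup) is ancestral; sites failing either condition
are excluded with reasons counted.  Coding effects are classified against
single-transcript gene models in transcript orientation (reverse-complement
on the minus strand) with the standard genetic code; splice disruption is
a hit within the canonical 2-bp intronic donor/acceptor window.  Missense
severity uses the Grantham physicochemical distance, with scores >= 150
flagged deleterious.

The load statistic per individual and category is
ratio = 2*Hom / (2*Hom + Het) over derived genotypes: two derived copies
per homozygous site, one per heterozygous site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io import GeneModel, GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

GRANTHAM_DELETERIOUS_THRESHOLD = 150

EFFECT_CLASSES = ("synonymous", "missense", "nonsense", "splice_disrupting", "noncoding")
LOF_CLASSES = ("nonsense", "splice_disrupting")


# ===========================================================================
# Grantham distance
# ===========================================================================

# Grantham (1974) side-chain properties: composition c, polarity p, volume v
_GRANTHAM_PROPS = {
    "S": (1.42, 9.2, 32.0), "R": (0.65, 10.5, 124.0), "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61.0), "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0), "G": (0.74, 9.0, 3.0), "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0), "Y": (0.20, 6.2, 136.0), "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0), "Q": (0.89, 10.5, 85.0), "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0), "D": (1.38, 13.0, 54.0), "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0), "W": (0.13, 5.4, 170.0),
}
_GRANTHAM_ALPHA = 1.833
_GRANTHAM_BETA = 0.1018
_GRANTHAM_GAMMA = 0.000399
_GRANTHAM_RHO = 50.723

# the canonical published 190-pair matrix (upper triangle, row-major over the
# residue order below); Grantham's own table rounds a few cells differently
# from the recomputed formula, so the table is the authoritative lookup
_GRANTHAM_ORDER = "SRLPTAVGIFYCHQNKDEMW"
_GRANTHAM_UPPER = [
    110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177,
    102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101,
    98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61,
    38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147,
    58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128,
    64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148,
    109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88,
    135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184,
    21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61,
    22, 205, 100, 116, 158, 102, 177, 140, 28, 40,
    194, 83, 99, 143, 85, 160, 122, 36, 37,
    174, 154, 139, 202, 154, 170, 196, 215,
    24, 68, 32, 81, 40, 87, 115,
    46, 53, 61, 29, 101, 130,
    94, 23, 42, 142, 174,
    101, 56, 95, 110,
    45, 160, 181,
    126, 152,
    67,
]

_GRANTHAM_TABLE: dict[tuple[str, str], int] = {}
_k = 0
for _i, _a in enumerate(_GRANTHAM_ORDER):
    for _b in _GRANTHAM_ORDER[_i + 1:]:
        _GRANTHAM_TABLE[(_a, _b)] = _GRANTHAM_TABLE[(_b, _a)] = _GRANTHAM_UPPER[_k]
        _k += 1
del _i, _a, _b, _k


def grantham_formula(ref_aa: str, alt_aa: str) -> float:
    """Grantham distance recomputed from the published constants:
    D = rho * [alpha (c1-c2)^2 + beta (p1-p2)^2 + gamma (v1-v2)^2]^(1/2)."""
    try:
        c1, p1, v1 = _GRANTHAM_PROPS[ref_aa.upper()]
        c2, p2, v2 = _GRANTHAM_PROPS[alt_aa.upper()]
    except KeyError as exc:
        raise ValueError(f"non-standard residue: {exc.args[0]!r}") from None
    return _GRANTHAM_RHO * (
        _GRANTHAM_ALPHA * (c1 - c2) ** 2
        + _GRANTHAM_BETA * (p1 - p2) ** 2
        + _GRANTHAM_GAMMA * (v1 - v2) ** 2
    ) ** 0.5


def grantham_score(ref_aa: str, alt_aa: str) -> int:
    """Canonical Grantham score between two standard amino acids."""
    a, b = ref_aa.upper(), alt_aa.upper()
    if a not in _GRANTHAM_PROPS or b not in _GRANTHAM_PROPS:
        raise ValueError(f"non-standard residue in ({ref_aa!r}, {alt_aa!r})")
    if a == b:
        return 0
    return _GRANTHAM_TABLE[(a, b)]


def is_deleterious_grantham(score: float,
                            threshold: float = GRANTHAM_DELETERIOUS_THRESHOLD) -> bool:
    return score >= threshold


# ===========================================================================
# Ancestral-state assignment
# ===========================================================================

def assign_ancestral(gm_focal: GenotypeMatrix, gm_other: GenotypeMatrix,
                     count_mode: Literal["individuals", "chromosomes"] = "individuals",
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Two-species ancestral-state rule over shared sites.

    The ancestral allele must be (a) homozygous in > 50% of focal-species
    individuals (strict; with ``count_mode='chromosomes'`` the requirement
    is allele frequency > 50%) and (b) the fixed homozygous state of the
    other species.  Returns a table ``scaffold, pos, ancestral_is_ref,
    derived_allele`` for accepted sites and a dict of exclusion counts.
    """
    kf = pd.MultiIndex.from_frame(gm_focal.sites[["scaffold", "pos"]])
    ko = pd.MultiIndex.from_frame(gm_other.sites[["scaffold", "pos"]])
    common = kf.intersection(ko)
    i_f = kf.get_indexer(common)
    i_o = ko.get_indexer(common)
    rows = []
    excl = {"no_major_homozygote": 0, "outgroup_not_fixed_same": 0,
            "outgroup_all_missing": 0}
    n_focal = gm_focal.n_samples
    for row in range(len(common)):
        gf = gm_focal.gt[i_f[row]]
        go = gm_other.gt[i_o[row]]
        if count_mode == "individuals":
            n_hom_ref = int((gf == HOM_REF).sum())
            n_hom_alt = int((gf == HOM_ALT).sum())
            if n_hom_ref * 2 > n_focal:
                major = HOM_REF
            elif n_hom_alt * 2 > n_focal:
                major = HOM_ALT
            else:
                excl["no_major_homozygote"] += 1
                continue
        else:
            called = gf[gf != MISSING]
            if len(called) == 0:
                excl["no_major_homozygote"] += 1
                continue
            alt_freq = called.sum() / (2 * len(called))
            if alt_freq < 0.5:
                major = HOM_REF
            elif alt_freq > 0.5:
                major = HOM_ALT
            else:
                excl["no_major_homozygote"] += 1
                continue
        oc = go[go != MISSING]
        if len(oc) == 0:
            excl["outgroup_all_missing"] += 1
            continue
        if not (oc == major).all():
            excl["outgroup_not_fixed_same"] += 1
            continue
        sc, pos = common[row]
        site = gm_focal.sites.iloc[i_f[row]]
        ancestral_is_ref = major == HOM_REF
        rows.append({"scaffold": sc, "pos": pos,
                     "ancestral_is_ref": ancestral_is_ref,
                     "ancestral": site["ref"] if ancestral_is_ref else site["alt"],
                     "derived": site["alt"] if ancestral_is_ref else site["ref"]})
    table = pd.DataFrame(rows, columns=["scaffold", "pos", "ancestral_is_ref",
                                        "ancestral", "derived"])
    return table, excl


# ===========================================================================
# Effect classification
# ===========================================================================

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class AnnotatedVariant:
    scaffold: str
    pos: int                 # 1-based
    ref: str
    alt: str
    gene_id: str | None
    effect: str
    ref_aa: str | None = None
    alt_aa: str | None = None
    grantham: int | None = None
    deleterious_gs: bool = False

    def __post_init__(self) -> None:
        if (self.grantham is not None) != (self.effect == "missense"):
            raise ValueError("grantham score present iff missense")
        if self.deleterious_gs and (self.grantham or 0) < GRANTHAM_DELETERIOUS_THRESHOLD:
            raise ValueError("deleterious_gs requires grantham >= 150")


def _intron_windows(gene: GeneModel, splice_window: int) -> list[tuple[int, int]]:
    """Intronic donor/acceptor windows (0-based half-open genomic)."""
    windows = []
    genomic = sorted(gene.exons)
    for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
        windows.append((e1, min(e1 + splice_window, s2)))       # after left exon
        windows.append((max(s2 - splice_window, e1), s2))       # before right exon
    return windows


def classify_effect(scaffold: str, pos: int, ref: str, alt: str,
                    gene: GeneModel, ref_seqs: Mapping[str, str],
                    splice_window: int = 2) -> AnnotatedVariant:
    """Classify a SNV against one gene model.

    ``pos`` is 1-based; the reference base at the site must match ``ref``.
    Codon reconstruction is in transcript orientation (reverse-complement on
    the minus strand) with the standard genetic code.
    """
    if scaffold != gene.scaffold:
        raise ValueError(f"variant on {scaffold} but gene on {gene.scaffold}")
    seq = ref_seqs[scaffold]
    g0 = pos - 1
    if seq[g0].upper() != ref.upper():
        raise ValueError(f"reference mismatch at {scaffold}:{pos}: "
                         f"sequence has {seq[g0]!r}, variant says {ref!r}")
    cds_pos = gene.transcript_position(g0)
    if cds_pos is None:
        for lo, hi in _intron_windows(gene, splice_window):
            if lo <= g0 < hi:
                return AnnotatedVariant(scaffold, pos, ref, alt, gene.gene_id,
                                        "splice_disrupting")
        return AnnotatedVariant(scaffold, pos, ref, alt, gene.gene_id, "noncoding")
    cds = gene.cds_sequence(ref_seqs)
    codon_i = cds_pos // 3
    within = cds_pos % 3
    codon = cds[3 * codon_i: 3 * codon_i + 3]
    if len(codon) < 3:
        raise ValueError(f"incomplete codon at CDS end of {gene.gene_id}")
    alt_t = alt.upper() if gene.strand == "+" else alt.upper().translate(_COMPLEMENT)
    alt_codon = codon[:within] + alt_t + codon[within + 1:]
    ref_aa = str(Seq(codon).translate(table=standard_dna_table))
    alt_aa = str(Seq(alt_codon).translate(table=standard_dna_table))
    if alt_aa == "*" and ref_aa != "*":
        return AnnotatedVariant(scaffold, pos, ref, alt, gene.gene_id, "nonsense",
                                ref_aa, alt_aa)
    if alt_aa == ref_aa:
        return AnnotatedVariant(scaffold, pos, ref, alt, gene.gene_id, "synonymous",
                                ref_aa, alt_aa)
    if ref_aa == "*":
        # stop-loss: grouped with the LOF class (no Grantham score exists)
        return AnnotatedVariant(scaffold, pos, ref, alt, gene.gene_id, "nonsense",
                                ref_aa, alt_aa)
    gs = grantham_score(ref_aa, alt_aa)
    return AnnotatedVariant(scaffold, pos, ref, alt, gene.gene_id, "missense",
                            ref_aa, alt_aa, gs,
                            gs >= GRANTHAM_DELETERIOUS_THRESHOLD)


def annotate_variants(gm: GenotypeMatrix, genes: Sequence[GeneModel],
                      ref_seqs: Mapping[str, str],
                      splice_window: int = 2) -> pd.DataFrame:
    """Classify every site that overlaps a gene footprint (+ splice windows).

    Returns one row per (site, gene) hit with the effect annotation;
    sites outside all gene footprints are labelled noncoding without a gene.
    """
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    rows = []
    for i, site in enumerate(gm.sites.itertuples(index=False)):
        g0 = int(site.pos) - 1
        hit = False
        for gene in by_scaffold.get(site.scaffold, ()):
            lo, hi = gene.span
            if lo - splice_window <= g0 < hi + splice_window:
                av = classify_effect(site.scaffold, int(site.pos), site.ref,
                                     site.alt, gene, ref_seqs, splice_window)
                rows.append({"site_index": i, **av.__dict__})
                hit = True
        if not hit:
            rows.append({"site_index": i, "scaffold": site.scaffold,
                         "pos": int(site.pos), "ref": site.ref, "alt": site.alt,
                         "gene_id": None, "effect": "noncoding", "ref_aa": None,
                         "alt_aa": None, "grantham": None, "deleterious_gs": False})
    return pd.DataFrame(rows)


# ===========================================================================
# Load statistics
# ===========================================================================

def load_ratio(gm: GenotypeMatrix, site_index: Sequence[int],
               derived_is_alt: Sequence[bool]) -> pd.DataFrame:
    """Per-individual load ratio 2*Hom/(2*Hom + Het) over a site category.

    ``site_index`` selects rows of ``gm``; ``derived_is_alt`` gives, for
    each selected site, whether the derived allele is ALT.  The ratio is
    None (NaN) when an individual carries no derived allele at any site.
    """
    idx = np.asarray(site_index, int)
    dia = np.asarray(derived_is_alt, bool)
    if len(idx) != len(dia):
        raise ValueError("site_index and derived_is_alt must align")
    gt = gm.gt[idx]
    hom_derived = np.where(dia[:, None], gt == HOM_ALT, gt == HOM_REF)
    het = gt == HET
    n_hom = hom_derived.sum(axis=0)
    n_het = het.sum(axis=0)
    denom = 2 * n_hom + n_het
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, 2 * n_hom / np.maximum(denom, 1), np.nan)
    return pd.DataFrame({
        "individual": gm.samples,
        "n_hom_derived": n_hom.astype(int),
        "n_het_derived": n_het.astype(int),
        "ratio": ratio,
    })


def hom_deleterious_genes_in_roh(gm: GenotypeMatrix, annotated: pd.DataFrame,
                                 roh_segments: pd.DataFrame,
                                 derived_map: pd.DataFrame,
                                 classes: Sequence[str] = ("nonsense",
                                                           "splice_disrupting"),
                                 require_deleterious_gs: bool = False,
                                 ) -> pd.DataFrame:
    """Per individual: distinct genes with a homozygous-derived deleterious
    variant lying inside one of that individual's ROHs.

    ``annotated`` is the output of :func:`annotate_variants`;
    ``derived_map`` the accepted-site table of :func:`assign_ancestral`
    (its ``ancestral_is_ref`` defines the derived genotype code).
    """
    dkey = pd.MultiIndex.from_frame(derived_map[["scaffold", "pos"]])
    sel = annotated["effect"].isin(classes)
    if require_deleterious_gs:
        sel |= annotated["deleterious_gs"].fillna(False).astype(bool)
    cand = annotated[sel & annotated["gene_id"].notna()]
    counts = {}
    for ind in gm.samples:
        k = gm.samples.index(ind)
        segs = roh_segments[roh_segments["individual"] == ind]
        genes: set[str] = set()
        for r in cand.itertuples(index=False):
            loc = dkey.get_indexer([(r.scaffold, r.pos)])[0]
            if loc < 0:
                continue  # no derived-state call at this site
            anc_is_ref = bool(derived_map["ancestral_is_ref"].iloc[loc])
            hom_derived_code = HOM_ALT if anc_is_ref else HOM_REF
            if gm.gt[int(r.site_index), k] != hom_derived_code:
                continue
            g0 = r.pos - 1
            inside = ((segs["scaffold"] == r.scaffold)
                      & (segs["start"] <= g0) & (g0 < segs["end"])).any()
            if inside:
                genes.add(r.gene_id)
        counts[ind] = len(genes)
    return pd.DataFrame({"individual": list(counts), "n_genes": list(counts.values())})


def af_difference_filter(gm: GenotypeMatrix, site_index: Sequence[int],
                         samples_a: Sequence[str], samples_b: Sequence[str],
                         derived_is_alt: Sequence[bool],
                         threshold: float = 0.2) -> tuple[np.ndarray, int]:
    """Keep sites with |derived-allele-frequency difference| strictly > 0.2.

    Frequencies are computed from non-missing genotypes only; sites where a
    population is entirely missing are skipped and counted.  Returns
    ``(kept boolean mask over site_index, n_skipped)``.
    """
    idx = np.asarray(site_index, int)
    dia = np.asarray(derived_is_alt, bool)
    cols_a = [gm.samples.index(s) for s in samples_a]
    cols_b = [gm.samples.index(s) for s in samples_b]
    keep = np.zeros(len(idx), bool)
    skipped = 0
    for r, (i, alt_is_derived) in enumerate(zip(idx, dia)):
        def freq(cols):
            g = gm.gt[i, cols]
            g = g[g != MISSING]
            if len(g) == 0:
                return None
            f_alt = g.sum() / (2 * len(g))
            return f_alt if alt_is_derived else 1.0 - f_alt

        fa, fb = freq(cols_a), freq(cols_b)
        if fa is None or fb is None:
            skipped += 1
            continue
        keep[r] = abs(fa - fb) > threshold
    return keep, skipped
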