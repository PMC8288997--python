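"""Ancestral polarization by the two-species rule, effect classification,
Grantham severity, load ratios, ROH-intersected gene counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import declinescan as ds
from conftest import build_gm
from declinescan.load import _GRANTHAM_ORDER


# ---------------------------------------------------------------------------
# ancestral assignment
# ---------------------------------------------------------------------------

def test_ancestral_majority_hom_plus_fixed_outgroup():
    focal = build_gm(np.array([[0, 0, 0, 1]], np.int8))   # 3/4 hom-ref
    other = build_gm(np.array([[0, 0]], np.int8))         # fixed hom-ref
    table, excl = ds.assign_ancestral(focal, other)
    assert len(table) == 1
    assert bool(table["ancestral_is_ref"].iloc[0])
    assert table["derived"].iloc[0] == "T"
    assert sum(excl.values()) == 0


def test_ancestral_outgroup_disagrees_excluded():
    focal = build_gm(np.array([[0, 0, 0, 1]], np.int8))
    other = build_gm(np.array([[2, 2]], np.int8))         # fixed for ALT
    table, excl = ds.assign_ancestral(focal, other)
    assert len(table) == 0
    assert excl["outgroup_not_fixed_same"] == 1


def test_ancestral_exact_half_excluded():
    focal = build_gm(np.array([[0, 0, 1, 1]], np.int8))   # exactly 50% hom-ref
    other = build_gm(np.array([[0, 0]], np.int8))
    table, excl = ds.assign_ancestral(focal, other)
    assert len(table) == 0
    assert excl["no_major_homozygote"] == 1


def test_ancestral_chromosome_mode_counts_alleles():
    # 2 hom-ref + 2 het: 6/8 REF alleles > 50%, but only 50% of individuals
    focal = build_gm(np.array([[0, 0, 1, 1]], np.int8))
    other = build_gm(np.array([[0, 0]], np.int8))
    table, _ = ds.assign_ancestral(focal, other, count_mode="chromosomes")
    assert len(table) == 1 and bool(table["ancestral_is_ref"].iloc[0])


def test_ancestral_hom_alt_majority():
    focal = build_gm(np.array([[2, 2, 2, 1]], np.int8))
    other = build_gm(np.array([[2, 2]], np.int8))
    table, _ = ds.assign_ancestral(focal, other)
    assert not bool(table["ancestral_is_ref"].iloc[0])
    assert table["derived"].iloc[0] == "A"


# ---------------------------------------------------------------------------
# effect classification (direct genetic-code cases)
# ---------------------------------------------------------------------------

@pytest.fixture
def plus_gene():
    # one exon, CDS = ATG CGA GAT AAA, plus strand, starts at genomic 10
    gene = ds.GeneModel("g1", "sc", "+", ((10, 22),))
    ref = {"sc": "N" * 10 + "ATGCGAGATAAA" + "N" * 10}
    return gene, ref


def test_nonsense_cga_to_tga(plus_gene):
    gene, ref = plus_gene
    av = ds.classify_effect("sc", 14, "C", "T", gene, ref)  # CGA -> TGA
    assert av.effect == "nonsense"
    assert (av.ref_aa, av.alt_aa) == ("R", "*")


def test_missense_gat_to_gaa(plus_gene):
    gene, ref = plus_gene
    av = ds.classify_effect("sc", 19, "T", "A", gene, ref)  # GAT -> GAA
    assert av.effect == "missense"
    assert (av.ref_aa, av.alt_aa) == ("D", "E")
    assert av.grantham == ds.grantham_score("D", "E")


def test_synonymous_third_position(plus_gene):
    gene, ref = plus_gene
    av = ds.classify_effect("sc", 16, "A", "G", gene, ref)  # CGA -> CGG (Arg)
    assert av.effect == "synonymous"


def test_splice_window_classification():
    # two exons with a 30 bp intron; +1 intronic base is splice-disrupting
    gene = ds.GeneModel("g2", "sc", "+", ((10, 16), (46, 52)))
    seq = list("N" * 70)
    seq[10:16] = "ATGAAA"
    seq[16:18] = "GT"
    seq[44:46] = "AG"
    seq[46:52] = "GGGTAA"
    ref = {"sc": "".join(seq)}
    av = ds.classify_effect("sc", 17, "G", "A", gene, ref)
    assert av.effect == "splice_disrupting"
    av2 = ds.classify_effect("sc", 30, ref["sc"][29], "A" if ref["sc"][29] != "A" else "C",
                             gene, ref)
    assert av2.effect == "noncoding"


def test_reference_mismatch_raises(plus_gene):
    gene, ref = plus_gene
    with pytest.raises(ValueError, match="mismatch"):
        ds.classify_effect("sc", 14, "G", "T", gene, ref)


def test_minus_strand_equivalence():
    """A minus-strand gene classifies like its plus-strand equivalent."""
    genes, ref, planted = ds.simulate_gene_models(
        4, 25, [("nonsense", 4), ("synonymous", 4)], seed=21)
    by_id = {g.gene_id: g for g in genes}
    minus_hits = 0
    for r in planted.itertuples(index=False):
        gene = by_id[r.gene_id]
        av = ds.classify_effect(r.scaffold, r.pos, r.ref, r.alt, gene, ref)
        assert av.effect == r.true_effect
        if gene.strand == "-":
            minus_hits += 1
    assert minus_hits > 0


# ---------------------------------------------------------------------------
# Grantham
# ---------------------------------------------------------------------------

def test_grantham_identical_residues_zero():
    for aa in _GRANTHAM_ORDER:
        assert ds.grantham_score(aa, aa) == 0


def test_grantham_symmetry_and_positivity():
    for a in _GRANTHAM_ORDER:
        for b in _GRANTHAM_ORDER:
            if a != b:
                s = ds.grantham_score(a, b)
                assert s == ds.grantham_score(b, a)
                assert s > 0


def test_grantham_known_pairs():
    assert ds.grantham_score("L", "I") == 5
    assert ds.grantham_score("C", "W") == 215
    assert ds.is_deleterious_grantham(ds.grantham_score("C", "W"))
    assert not ds.is_deleterious_grantham(ds.grantham_score("L", "I"))


def test_grantham_table_consistent_with_published_formula():
    """Every pair agrees with the recomputed physicochemical distance within
    one rounding unit, except the two cells where the original published
    table departs from its own formula (Asp-Trp and Glu-Asn)."""
    known_departures = {frozenset("DW"), frozenset("EN")}
    for i, a in enumerate(_GRANTHAM_ORDER):
        for b in _GRANTHAM_ORDER[i + 1:]:
            diff = abs(ds.grantham_formula(a, b) - ds.grantham_score(a, b))
            if frozenset((a, b)) in known_departures:
                assert diff <= 11
            else:
                assert diff <= 1.0, (a, b, diff)


def test_grantham_formula_example_leu_ile():
    assert round(ds.grantham_formula("L", "I")) == 5


def test_grantham_nonstandard_residue_rejected():
    with pytest.raises(ValueError, match="residue"):
        ds.grantham_score("B", "A")


# ---------------------------------------------------------------------------
# load ratio
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_hom,n_het,expected", [
    (3, 2, 0.75), (4, 0, 1.0), (0, 5, 0.0),
])
def test_load_ratio_worked_examples(n_hom, n_het, expected):
    n = n_hom + n_het
    gt = np.array([[2]] * n_hom + [[1]] * n_het, np.int8)
    gm = build_gm(gt)
    out = ds.load_ratio(gm, list(range(n)), [True] * n)
    assert out["ratio"].iloc[0] == pytest.approx(expected)


def test_load_ratio_no_derived_alleles_is_nan():
    gm = build_gm(np.zeros((4, 1), np.int8))
    out = ds.load_ratio(gm, list(range(4)), [True] * 4)
    assert np.isnan(out["ratio"].iloc[0])


def test_load_ratio_site_order_invariant():
    rng = np.random.default_rng(22)
    gt = rng.choice([0, 1, 2], size=(40, 3)).astype(np.int8)
    gm = build_gm(gt)
    idx = np.arange(40)
    a = ds.load_ratio(gm, idx, [True] * 40)
    perm = rng.permutation(idx)
    b = ds.load_ratio(gm, perm, [True] * 40)
    assert np.allclose(a["ratio"], b["ratio"], equal_nan=True)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 30), st.integers(1, 30), st.integers(1, 10))
def test_load_ratio_monotone_in_homozygotes(n_hom, n_het, extra):
    def ratio(h, e):
        gt = np.array([[2]] * h + [[1]] * e, np.int8)
        gm = build_gm(gt) if h + e else None
        return ds.load_ratio(gm, list(range(h + e)), [True] * (h + e))["ratio"].iloc[0]

    assert ratio(n_hom + extra, n_het) >= ratio(n_hom, n_het)


# ---------------------------------------------------------------------------
# genes-in-ROH and AF-difference filter
# ---------------------------------------------------------------------------

def _roh_frame(ind, scaffold, start, end):
    return pd.DataFrame([{"individual": ind, "scaffold": scaffold,
                          "start": start, "end": end, "n_snps": 50,
                          "n_het": 0, "length_bp": end - start,
                          "length_cM": (end - start) / 1e6}])


def _annotated(scaffold, pos, gene, effect, site_index=0):
    return pd.DataFrame([{
        "site_index": site_index, "scaffold": scaffold, "pos": pos,
        "ref": "A", "alt": "T", "gene_id": gene, "effect": effect,
        "ref_aa": None, "alt_aa": None, "grantham": None,
        "deleterious_gs": False,
    }])


def _derived_map(scaffold, pos):
    return pd.DataFrame([{"scaffold": scaffold, "pos": pos,
                          "ancestral_is_ref": True, "ancestral": "A",
                          "derived": "T"}])


def test_hom_lof_inside_roh_counts_one():
    gm = build_gm(np.array([[2]], np.int8), positions=[500_000])
    out = ds.hom_deleterious_genes_in_roh(
        gm, _annotated("s1", 500_000, "geneA", "nonsense"),
        _roh_frame("i0", "s1", 0, 2_000_000), _derived_map("s1", 500_000))
    assert out.loc[out["individual"] == "i0", "n_genes"].iloc[0] == 1


def test_het_variant_does_not_count():
    gm = build_gm(np.array([[1]], np.int8), positions=[500_000])
    out = ds.hom_deleterious_genes_in_roh(
        gm, _annotated("s1", 500_000, "geneA", "nonsense"),
        _roh_frame("i0", "s1", 0, 2_000_000), _derived_map("s1", 500_000))
    assert out["n_genes"].iloc[0] == 0


def test_two_variants_one_gene_count_distinct():
    gm = build_gm(np.array([[2], [2]], np.int8), positions=[400_000, 600_000])
    ann = pd.concat([
        _annotated("s1", 400_000, "geneA", "nonsense", site_index=0),
        _annotated("s1", 600_000, "geneA", "splice_disrupting", site_index=1),
    ], ignore_index=True)
    dmap = pd.concat([_derived_map("s1", 400_000), _derived_map("s1", 600_000)],
                     ignore_index=True)
    out = ds.hom_deleterious_genes_in_roh(
        gm, ann, _roh_frame("i0", "s1", 0, 2_000_000), dmap)
    assert out["n_genes"].iloc[0] == 1


@pytest.mark.parametrize("fa_gt,fb_gt,kept", [
    # f_a = 0.5, f_b = 0.2 -> |diff| 0.3 kept
    ([1, 1], [0, 1, 0, 0, 0], True),
    # f_a = 0.5, f_b = 0.4 -> dropped
    ([1, 1], [1, 1, 1, 1, 0], False),
])
def test_af_difference_examples(fa_gt, fb_gt, kept):
    gt = np.array([fa_gt + fb_gt], np.int8)
    samples = [f"a{i}" for i in range(len(fa_gt))] + \
              [f"b{i}" for i in range(len(fb_gt))]
    gm = build_gm(gt, samples=samples)
    keep, skipped = ds.af_difference_filter(
        gm, [0], [s for s in samples if s.startswith("a")],
        [s for s in samples if s.startswith("b")], [True])
    assert keep[0] == kept and skipped == 0


def test_af_difference_exact_boundary_dropped():
    # f_a = 0.5 (one het of 1), f_b = 6/20 = 0.3 -> diff 0.2: strict > drops it
    gt = np.array([[1] + [1, 1, 1, 1, 1, 1, 0, 0, 0, 0]], np.int8)
    samples = ["a0"] + [f"b{i}" for i in range(10)]
    gm = build_gm(gt, samples=samples)
    keep, _ = ds.af_difference_filter(gm, [0], ["a0"], samples[1:], [True],
                                      threshold=0.2)
    assert not keep[0]


def test_af_difference_all_missing_population_skipped():
    gt = np.array([[1, -1, -1]], np.int8)
    gm = build_gm(gt, samples=["a0", "b0", "b1"])
    keep, skipped = ds.af_difference_filter(gm, [0], ["a0"], ["b0", "b1"],
                                            [True])
    assert skipped == 1 and not keep[0]
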