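"""Consequence annotation: codon arithmetic, knockout rule, gene-list cross-refs."""

import numpy as np
import pytest
from Bio.Seq import Seq

from evotrace.diffcall import apply_variants
from evotrace.effects import (
    annotate,
    annotate_all,
    call_knockouts,
    crossref_gene_sets,
    reference_interrupted,
)
from evotrace.io import GeneFeature, GenomeRecord, Variant
from tests.conftest import random_sequence

_STOPS = {"TAA", "TAG", "TGA"}


def _rand_cds(rng, n_codons):
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _gene_on(rng, cds, strand="+", flank=120):
    body = cds if strand == "+" else str(Seq(cds).reverse_complement())
    seq = random_sequence(rng, flank) + body + random_sequence(rng, flank)
    ref = GenomeRecord(id="r", sequence=seq)
    feat = GeneFeature("r", flank, flank + len(cds), strand, locus_tag="bX",
                       gene="genX")
    return ref, feat


def test_silent_third_position_snp(rng):
    # CTT and CTC both encode Leu
    cds = "ATG" + "CTT" * 30 + "TAA"
    ref, feat = _gene_on(rng, cds)
    pos = feat.start + 3 + 2  # third position of codon 2
    v = Variant("s", "r", pos, "T", "C", "snp")
    call = annotate(v, [feat], ref)[0]
    assert call.effect == "silent"
    assert call.codon_affected == 2


def test_is_insertion_at_codon_12_of_183_is_knockout(rng):
    cds = _rand_cds(rng, 184)  # 183 residues + stop
    ref, feat = _gene_on(rng, cds)
    v = Variant("s", "r", feat.start + 11 * 3, "", "ACGT" * 330, "is_insertion")
    call = annotate(v, [feat], ref)[0]
    assert call.effect == "is_insertion_in_gene"
    assert (call.codon_affected, call.total_codons) == (12, 183)
    assert call.fraction_lost == pytest.approx(172 / 183)
    assert call.knockout


def test_late_frameshift_at_586_of_598_is_not_knockout(rng):
    cds = _rand_cds(rng, 599)
    ref, feat = _gene_on(rng, cds)
    pos = feat.start + 585 * 3 + 1
    v = Variant("s", "r", pos, ref.sequence[pos], "", "deletion")
    call = annotate(v, [feat], ref)[0]
    assert call.effect == "frameshift"
    assert (call.codon_affected, call.total_codons) == (586, 598)
    assert call.fraction_lost == pytest.approx(13 / 598)
    assert not call.knockout


def test_start_codon_change_is_its_own_class(rng):
    cds = _rand_cds(rng, 100)
    ref, feat = _gene_on(rng, cds)
    v = Variant("s", "r", feat.start + 2, "G", "A", "snp")  # ATG -> ATA
    call = annotate(v, [feat], ref)[0]
    assert call.effect == "start_codon_change"
    assert not call.knockout


def test_gene_fully_inside_large_deletion(rng):
    cds = _rand_cds(rng, 80)
    ref, feat = _gene_on(rng, cds, flank=500)
    v = Variant("s", "r", 100, ref.sequence[100:1000], "", "large_deletion")
    calls = annotate(v, [feat], ref)
    assert any(c.effect == "gene_deleted" and c.knockout for c in calls)


def test_intergenic_upstream_flag(rng):
    cds = _rand_cds(rng, 60)
    ref, feat = _gene_on(rng, cds, flank=200)
    v_up = Variant("s", "r", feat.start - 20, ref.sequence[feat.start - 20],
                   "A" if ref.sequence[feat.start - 20] != "A" else "C", "snp")
    call = annotate(v_up, [feat], ref)[0]
    assert call.effect == "intergenic_upstream"
    assert call.gene == feat.locus_tag
    v_far = Variant("s", "r", 10, ref.sequence[10],
                    "A" if ref.sequence[10] != "A" else "C", "snp")
    call_far = annotate(v_far, [feat], ref)[0]
    assert call_far.effect == "intergenic_other"
    assert feat.locus_tag in call_far.flank_genes


@pytest.mark.parametrize("strand", ["+", "-"])
def test_effect_classes_agree_with_apply_and_translate(rng, strand):
    """Literal oracle: mutate the genome, translate, compare proteins."""
    n_checked = 0
    for _ in range(150):
        n_codons = int(rng.integers(50, 150))
        cds = _rand_cds(rng, n_codons)
        ref, feat = _gene_on(rng, cds, strand=strand)
        pos = int(rng.integers(feat.start, feat.end))
        old = ref.sequence[pos]
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        v = Variant("s", "r", pos, old, new, "snp")
        call = annotate(v, [feat], ref)[0]

        mutated = apply_variants(ref, [v])
        nt = mutated[feat.start : feat.end]
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        p_ref = str(Seq(cds).translate(table=11))
        p_mut = str(Seq(nt).translate(table=11))
        first_diff = next(
            (i for i, (a, b) in enumerate(zip(p_ref, p_mut)) if a != b), None)
        starts = ("ATG", "GTG", "TTG")
        if first_diff == 0 and cds[:3] in starts:
            expected = "silent" if nt[:3] in starts else "start_codon_change"
        elif first_diff is None:
            expected = "silent"
        elif p_mut[first_diff] == "*":
            expected = "nonsense_truncation"
        else:
            expected = "missense"
        assert call.effect == expected, (cds, pos, strand)
        if expected not in ("silent", "start_codon_change"):
            assert call.codon_affected == first_diff + 1
        n_checked += 1
    assert n_checked == 150


def test_frameshift_agrees_with_translate_oracle(rng):
    for _ in range(60):
        n_codons = int(rng.integers(40, 120))
        cds = _rand_cds(rng, n_codons)
        ref, feat = _gene_on(rng, cds)
        pos = int(rng.integers(feat.start + 3, feat.end - 6))
        v = Variant("s", "r", pos, ref.sequence[pos], "", "deletion")
        call = annotate(v, [feat], ref)[0]
        assert call.effect == "frameshift"
        assert abs(v.delta) % 3 == 1


def test_fraction_lost_bounds_and_knockout_monotonicity(rng):
    cds = _rand_cds(rng, 200)
    ref, feat = _gene_on(rng, cds)
    calls = []
    for codon in (5, 50, 150, 195):
        pos = feat.start + (codon - 1) * 3
        v = Variant("s", "r", pos, ref.sequence[pos], "", "deletion")
        calls.append(annotate(v, [feat], ref)[0])
    for c in calls:
        assert 0.0 <= c.fraction_lost <= 1.0
    ko_strict = call_knockouts(calls, [], [feat], loss_threshold=0.5)
    ko_default = call_knockouts(calls, [], [feat], loss_threshold=0.10)
    ko_loose = call_knockouts(calls, [], [feat], loss_threshold=0.01)
    assert ko_strict <= ko_default <= ko_loose


def test_knockout_arithmetic_deletion_plus_frameshift(rng):
    genes = []
    seq_parts = [random_sequence(rng, 200)]
    offset = 200
    for i in range(11):
        cds = _rand_cds(rng, 60)
        genes.append(GeneFeature("r", offset, offset + len(cds), "+",
                                 locus_tag=f"b{i:03d}"))
        seq_parts.append(cds)
        seq_parts.append(random_sequence(rng, 100))
        offset += len(cds) + 100
    ref = GenomeRecord(id="r", sequence="".join(seq_parts))
    # one deletion spanning the first 10 genes entirely
    del_end = genes[9].end + 50
    deletion = Variant("s", "r", 150, ref.sequence[150:del_end], "",
                       "large_deletion")
    # plus an early frameshift in the 11th
    pos = genes[10].start + 10
    fs = Variant("s", "r", pos, ref.sequence[pos], "", "deletion")
    calls = annotate_all([fs], genes, ref)
    knockouts = call_knockouts(calls, [deletion], genes)
    assert len(knockouts) == 11


def test_no_variants_means_no_knockouts(rng):
    cds = _rand_cds(rng, 60)
    ref, feat = _gene_on(rng, cds)
    assert call_knockouts([], [], [feat]) == set()


def test_reference_interrupted_genes_reported_separately(rng):
    cds = _rand_cds(rng, 60)
    ref, feat = _gene_on(rng, cds)
    feat.interrupted_in_reference = True
    pos = feat.start + 10
    v = Variant("s", "r", pos, ref.sequence[pos], "", "deletion")
    calls = annotate(v, [feat], ref)
    assert call_knockouts(calls, [], [feat]) == set()
    assert reference_interrupted([feat]) == {feat.locus_tag}


def test_simulated_knockouts_match_ledger_expectation(tiny_ancestor, tiny_lineage,
                                                      is_reference):
    """Knockout set equals genes lost to planted deletions and truncations."""
    from evotrace.diffcall import align_genomes
    from evotrace.mobilome import reclassify_is_insertions

    ancestor, features = tiny_ancestor
    genome, truth = tiny_lineage
    result = align_genomes(ancestor, genome)
    variants = reclassify_is_insertions(result.variants, [is_reference])
    calls = annotate_all(variants, features, ancestor)
    large = [v for v in variants if v.event_class == "large_deletion"]
    knockouts = call_knockouts(calls, large, features)

    cds = [f for f in features if f.kind == "CDS"]
    expected = set()
    for ev in truth.visible_events():
        if ev.event_class in ("large_deletion", "element_excision"):
            for f in cds:
                if f.start >= ev.ancestor_start and f.end <= ev.ancestor_end:
                    expected.add(f.locus_tag)
    # ledger-driven truncations are a subset; deletion-contained genes must match
    assert expected <= knockouts


def test_crossref_counts_and_input_invariance(rng):
    cds = _rand_cds(rng, 60)
    ref, feat = _gene_on(rng, cds)
    pos = feat.start + 9
    v = Variant("s", "r", pos, ref.sequence[pos],
                "A" if ref.sequence[pos] != "A" else "C", "snp")
    calls = annotate(v, [feat], ref)
    res1 = crossref_gene_sets(calls, {"essential": ["bX", "bY"]})
    assert res1.summary.loc[0, "intragenic_hits"] == 1
    res2 = crossref_gene_sets(calls, {"essential": ["bY", "bX", "bX"]})
    assert res1.summary.loc[0, "intragenic_hits"] == res2.summary.loc[0, "intragenic_hits"]
    empty = crossref_gene_sets(calls, {"none": []})
    assert empty.summary.loc[0, "intragenic_hits"] == 0
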