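"""Deletion junction characterization, fusions, and scaffold circularization."""

import numpy as np
import pytest
from Bio.Seq import Seq

from evotrace.io import GeneFeature, GenomeRecord
from evotrace.junctions import (
    characterize_deletion,
    circularize,
    classify_deletion,
    detect_fusion,
    microhomology,
)
from evotrace.mobilome import ISCopy
from tests.conftest import random_sequence


def _brute_force_mh(seq, s, e):
    """Width of the contiguous run of equivalent placements containing (s, e)."""
    base = seq[:s] + seq[e:]
    in_run = lambda j: 0 <= s + j and e + j <= len(seq) and seq[: s + j] + seq[e + j :] == base
    lo = hi = 0
    while in_run(lo - 1):
        lo -= 1
    while in_run(hi + 1):
        hi += 1
    return hi - lo


def test_blunt_junction_has_zero_microhomology():
    ref = GenomeRecord(id="r", sequence="AACCTTGGCATGCAAGGTTCC")
    # flanks around [8, 13) share no bases: left ...GGC | ATGCA | AGGTT...
    mh, mh_seq, placement = microhomology(ref, 8, 13)
    assert mh == _brute_force_mh(ref.sequence, 8, 13)
    if mh == 0:
        assert mh_seq == ""
        assert placement == (8, 9)


def test_microhomology_matches_brute_force_on_random_instances(rng):
    for _ in range(800):
        n = int(rng.integers(30, 120))
        seq = random_sequence(rng, n)
        s = int(rng.integers(0, n - 2))
        e = int(rng.integers(s + 1, n))
        ref = GenomeRecord(id="r", sequence=seq)
        mh, _, _ = microhomology(ref, s, e)
        assert mh == _brute_force_mh(seq, s, e), (seq, s, e)


def test_every_placement_yields_identical_sequence(rng):
    for _ in range(200):
        n = int(rng.integers(40, 100))
        seq = random_sequence(rng, n)
        s = int(rng.integers(2, n - 10))
        e = int(rng.integers(s + 2, n - 2))
        ref = GenomeRecord(id="r", sequence=seq)
        mh, _, (lo, hi) = microhomology(ref, s, e)
        results = {seq[: s + j] + seq[e + j :]
                   for j in range(lo - s, hi - s)}
        assert len(results) == 1


def test_planted_12bp_microhomology_recovered(rng):
    seq = list(random_sequence(rng, 4000))
    tract = list("GCTAAGATTGCA")
    s, e = 1000, 2600
    seq[s : s + 12] = tract
    seq[e : e + 12] = tract
    ref = GenomeRecord(id="r", sequence="".join(seq))
    dj = characterize_deletion(ref, s, e)
    assert dj.mh_length >= 12
    assert "GCTAAGATTGCA" in dj.mh_sequence


def test_wraparound_microhomology_on_circular_genome(rng):
    seq = random_sequence(rng, 500)
    ref = GenomeRecord(id="r", sequence=seq, circular=True)
    mh, _, _ = microhomology(ref, 0, 20)  # flank comparison wraps the origin
    assert mh >= 0


# -- fusions ----------------------------------------------------------------


def _rand_cds(rng, n_codons):
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in stops:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


@pytest.fixture()
def fusion_setup(rng):
    """Two + strand CDSs sharing a 12-bp tract: codons 149-152 of the first
    equal codons 80-83 of the second (the AKIA-style signature)."""
    g5 = _rand_cds(rng, 353)   # 352 residues
    g3 = _rand_cds(rng, 339)   # 338 codons + stop -> 337... see assertion below
    tract = "GCTAAGATTGCA"
    g5 = g5[: 148 * 3] + tract + g5[152 * 3 :]
    g3 = g3[: 79 * 3] + tract + g3[83 * 3 :]
    # pin the tract-bordering bases so the shared region is exactly 12 bp
    g5 = g5[: 148 * 3 - 1] + "C" + g5[148 * 3 :]
    g3 = g3[: 79 * 3 - 1] + "T" + g3[79 * 3 :]
    g5 = g5[: 152 * 3] + "A" + g5[152 * 3 + 1 :]
    g3 = g3[: 83 * 3] + "G" + g3[83 * 3 + 1 :]
    spacer = random_sequence(rng, 5000)
    seq = random_sequence(rng, 500) + g5 + spacer + g3 + random_sequence(rng, 500)
    s5, s3 = 500, 500 + len(g5) + 5000
    ref = GenomeRecord(id="r", sequence=seq)
    feats = [
        GeneFeature("r", s5, s5 + len(g5), "+", gene="genA", locus_tag="b1"),
        GeneFeature("r", s3, s3 + len(g3), "+", gene="genB", locus_tag="b2"),
    ]
    return ref, feats, s5, s3, len(g3)


def test_in_frame_fusion_residue_arithmetic(fusion_setup):
    ref, feats, s5, s3, len3 = fusion_setup
    dj = characterize_deletion(ref, s5 + 148 * 3, s3 + 79 * 3)
    assert dj.mh_length >= 12
    fusion = detect_fusion(feats, dj, ref)
    assert fusion is not None
    assert fusion.retained5 == (1, 152)
    assert fusion.retained3 == (80, len3 // 3 - 1)
    assert fusion.in_frame
    # the translated fusion carries exactly one copy of the shared tract
    assert fusion.fusion_length == 152 + (len3 // 3 - 1) - 80 + 1 - 4


def test_out_of_frame_deletion_is_not_in_frame(fusion_setup):
    ref, feats, s5, s3, _ = fusion_setup
    dj = characterize_deletion(ref, s5 + 148 * 3 + 1, s3 + 79 * 3)
    fusion = detect_fusion(feats, dj, ref)
    if fusion is not None:
        assert not fusion.in_frame


def test_intergenic_deletion_yields_no_fusion(fusion_setup):
    ref, feats, s5, s3, _ = fusion_setup
    dj = characterize_deletion(ref, 10, 200)  # upstream of both genes
    assert detect_fusion(feats, dj, ref) is None


def test_minus_strand_fusion_detected(rng):
    g5 = _rand_cds(rng, 200)
    g3 = _rand_cds(rng, 150)
    seq = (random_sequence(rng, 300)
           + str(Seq(g3).reverse_complement())
           + random_sequence(rng, 2000)
           + str(Seq(g5).reverse_complement())
           + random_sequence(rng, 300))
    s3 = 300
    s5 = 300 + len(g3) + 2000
    ref = GenomeRecord(id="r", sequence=seq)
    feats = [
        GeneFeature("r", s3, s3 + len(g3), "-", gene="minB", locus_tag="b2"),
        GeneFeature("r", s5, s5 + len(g5), "-", gene="minA", locus_tag="b1"),
    ]
    # cut 90 codons into gene3 (from its 3' genomic end) and 60 into gene5
    ds = s3 + 90 * 3
    de = s5 + (200 - 60) * 3
    dj = characterize_deletion(ref, ds, de)
    fusion = detect_fusion(feats, dj, ref)
    assert fusion is not None
    assert fusion.gene5.gene == "minA"
    assert fusion.gene3.gene == "minB"


# -- classification ---------------------------------------------------------


def test_precise_element_excision_classification(rng):
    seq = random_sequence(rng, 10000)
    ref = GenomeRecord(id="r", sequence=seq)
    feats = [GeneFeature("r", 3000, 6000, "+", kind="prophage", locus_tag="el1")]
    dj = characterize_deletion(ref, 3000, 6000)
    assert classify_deletion(dj, feats, []) == "precise_element_excision"


def test_is_flank_recombination_classification(rng):
    seq = random_sequence(rng, 10000)
    ref = GenomeRecord(id="r", sequence=seq)
    copy = ISCopy(family="IS", seq_id="r", start=4000, end=5300, strand="+",
                  identity=1.0, coverage=1.0)
    dj = characterize_deletion(ref, 5301, 7000)  # breakpoint abuts the IS end
    assert classify_deletion(dj, [], [copy]) == "is_flank_recombination"


def test_microhomology_vs_blunt_threshold(rng):
    seq = list(random_sequence(rng, 6000))
    tract = list("ACGTACGTACGT")
    seq[1000:1012] = tract
    seq[3000:3012] = tract
    ref = GenomeRecord(id="r", sequence="".join(seq))
    dj = characterize_deletion(ref, 1000, 3000)
    assert dj.mh_length >= 12
    assert classify_deletion(dj, [], []) == "microhomology"
    blunt = characterize_deletion(ref, 4000, 4500)
    if blunt.mh_length < 5:
        assert classify_deletion(blunt, [], []) == "blunt"


def test_simulator_planted_microhomology_deletion(tiny_ancestor):
    """Deletions recombining a planted repeat pair report the planted length."""
    from evotrace.pipeline import fixture_params
    from evotrace.simulate import evolve_lineage

    ancestor, features = tiny_ancestor
    params = fixture_params("tiny", 1)
    params.p_event_class = {"snp": 0.0, "small_indel": 0.0, "is_insertion": 0.0,
                            "large_deletion": 1.0, "element_excision": 0.0}
    params.change_rate = 0.02
    _, truth = evolve_lineage(ancestor, features, params, params.days_total, seed=2)
    planted = [ev for ev in truth.visible_events()
               if ev.planted_microhomology_length > 0]
    assert planted, "no repeat-pair deletion planted"
    for ev in planted:
        dj = characterize_deletion(ancestor, ev.ancestor_start, ev.ancestor_end)
        assert dj.mh_length >= ev.planted_microhomology_length


# -- circularization --------------------------------------------------------


def test_scaffold_without_terminal_repeat_is_unchanged(rng):
    scaffold = GenomeRecord(id="s", sequence=random_sequence(rng, 3000))
    out, repeat = circularize(scaffold)
    assert repeat < 100
    assert not out.circular
    assert out.sequence == scaffold.sequence


def test_613bp_terminal_repeat_circularized(rng):
    repeat = random_sequence(rng, 613)
    core = random_sequence(rng, 20000)
    scaffold = GenomeRecord(id="s", sequence=repeat + core + repeat)
    out, length = circularize(scaffold)
    assert length == 613
    assert out.circular
    assert len(out) == len(core) + 613


def test_planted_250bp_terminal_repeat(rng):
    repeat = random_sequence(rng, 250)
    core = random_sequence(rng, 5000)
    scaffold = GenomeRecord(id="s", sequence=repeat + core + repeat)
    out, length = circularize(scaffold)
    assert length == 250
    assert len(out) == len(scaffold) - 250


def test_circularize_is_rotation_invariant(rng):
    repeat = random_sequence(rng, 200)
    core = random_sequence(rng, 4000)
    circ, _ = circularize(GenomeRecord(id="s", sequence=repeat + core + repeat))
    # linearize at an arbitrary origin with a fresh terminal repeat, re-circularize
    rotated = circ.sequence[1234:] + circ.sequence[:1234]
    relinear = GenomeRecord(id="s2", sequence=rotated + rotated[:200])
    circ2, length2 = circularize(relinear)
    assert length2 == 200
    assert len(circ2) == len(circ)
    assert circ2.sequence in circ.sequence + circ.sequence  # same rotation class
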