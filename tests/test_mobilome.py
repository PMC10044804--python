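"""IS detection, composite flagging, TSDs, consensus, allele profiling."""

import numpy as np
import pytest

from evotrace.io import GeneFeature, GenomeRecord
from evotrace.mobilome import (
    ISCopy,
    build_consensus,
    classify_against_alleles,
    extract_tsd,
    find_is_copies,
    flag_composite,
)
from evotrace.simulate import synthetic_is_element
from tests.conftest import random_sequence

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(_COMP)[::-1]


@pytest.fixture(scope="module")
def element():
    return synthetic_is_element()


def _plant(rng, element, n_fwd, n_rev, genome_len=40000, mutate_idx=(),
           mutation_rate=0.02):
    """Random genome with IS copies planted at known, well-separated sites."""
    seq = list(random_sequence(rng, genome_len))
    sites = np.sort(rng.choice(
        np.arange(2000, genome_len - 2000 - len(element), 3000),
        size=n_fwd + n_rev, replace=False))
    truth = []
    for i, s in enumerate(sites):
        body = element if i < n_fwd else _revcomp(element)
        if i in mutate_idx:
            body = list(body)
            for j in rng.choice(len(body), size=int(mutation_rate * len(body)),
                                replace=False):
                body[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[body[j]]
            body = "".join(body)
        seq[s : s + len(element)] = body
        truth.append((int(s), int(s) + len(element), "+" if i < n_fwd else "-"))
    return GenomeRecord(id="g", sequence="".join(seq)), truth


def test_no_planted_copies_gives_empty_list(rng, element):
    genome = GenomeRecord(id="g", sequence=random_sequence(rng, 20000))
    assert find_is_copies(genome, GenomeRecord(id="IS", sequence=element)) == []


def test_planted_copies_found_with_strands(rng, element):
    genome, truth = _plant(rng, element, n_fwd=3, n_rev=2, mutate_idx=(1,))
    copies = find_is_copies(genome, GenomeRecord(id="IS", sequence=element))
    assert len(copies) == 5
    found = [(c.start, c.end, c.strand) for c in copies]
    for t in truth:
        assert t in found
    mutated = [c for c in copies if c.identity < 1.0]
    assert len(mutated) == 1
    assert mutated[0].identity >= 0.95


def test_scan_is_strand_symmetric(rng, element):
    genome, _ = _plant(rng, element, n_fwd=2, n_rev=1, genome_len=20000)
    mirror = GenomeRecord(id="g", sequence=_revcomp(genome.sequence))
    fwd = find_is_copies(genome, GenomeRecord(id="IS", sequence=element))
    rev = find_is_copies(mirror, GenomeRecord(id="IS", sequence=element))
    L = len(genome)
    mirrored = sorted((L - c.end, L - c.start,
                       "+" if c.strand == "-" else "-") for c in rev)
    assert mirrored == sorted((c.start, c.end, c.strand) for c in fwd)


def test_copy_spanning_circular_origin_is_found(rng, element):
    seq = random_sequence(rng, 20000)
    half = len(element) // 2
    seq = element[half:] + seq[len(element):] + element[:half]
    genome = GenomeRecord(id="g", sequence=seq, circular=True)
    copies = find_is_copies(genome, GenomeRecord(id="IS", sequence=element))
    assert any(c.end > len(genome) or c.start + len(c) > len(genome)
               or c.start > len(genome) - len(element) for c in copies)


# -- composite flagging -----------------------------------------------------


def _copy(start, end, family="IS"):
    return ISCopy(family=family, seq_id="g", start=start, end=end, strand="+",
                  identity=1.0, coverage=1.0)


def test_pair_flanking_a_cds_is_composite():
    copies = [_copy(1000, 2300), _copy(11300, 12600)]
    features = [GeneFeature("g", 5000, 6000, "+", locus_tag="tetA")]
    flag_composite(copies, features)
    assert all(c.in_composite for c in copies)


def test_pair_without_cargo_cds_stays_isolated():
    copies = [_copy(1000, 2300), _copy(11300, 12600)]
    flag_composite(copies, features=[])
    assert not any(c.in_composite for c in copies)


def test_single_copy_is_isolated():
    copies = [_copy(1000, 2300)]
    features = [GeneFeature("g", 5000, 6000, "+", locus_tag="x")]
    flag_composite(copies, features)
    assert not copies[0].in_composite


def test_distant_pair_exceeding_max_cargo_is_isolated():
    copies = [_copy(1000, 2300), _copy(30000, 31300)]
    features = [GeneFeature("g", 5000, 6000, "+", locus_tag="x")]
    flag_composite(copies, features, max_cargo=15000)
    assert not any(c.in_composite for c in copies)


def test_17_copies_with_one_composite_pair_leaves_15_isolated():
    """Tn10-style bookkeeping: total minus composite-flagged ends."""
    copies = [_copy(1000, 2300), _copy(8000, 9300)]  # the transposon ends
    copies += [_copy(20000 + 10000 * i, 21300 + 10000 * i) for i in range(15)]
    features = [GeneFeature("g", 4000, 5000, "+", locus_tag="tetA")]
    flag_composite(copies, features)
    assert len(copies) == 17
    assert sum(c.in_composite for c in copies) == 2
    assert sum(not c.in_composite for c in copies) == 15


# -- TSDs -------------------------------------------------------------------


def test_planted_tsd_extracted(rng, element):
    target = "GCTTAGCAT"
    flank1, flank2 = random_sequence(rng, 3000), random_sequence(rng, 3000)
    seq = flank1 + target + element + target + flank2
    genome = GenomeRecord(id="g", sequence=seq)
    copy = _copy(3009, 3009 + len(element))
    left, right, match, site = extract_tsd(genome, copy)
    assert (left, right, match, site) == (target, target, True, target)


def test_mutated_right_flank_breaks_tsd_match(rng, element):
    target = "GCTTAGCAT"
    seq = random_sequence(rng, 2000) + target + element + "ACTTAGCAT" + random_sequence(rng, 2000)
    genome = GenomeRecord(id="g", sequence=seq)
    copy = _copy(2009, 2009 + len(element))
    _, _, match, site = extract_tsd(genome, copy)
    assert not match
    assert site == ""


def test_tsd_length_parameter_pass_through(rng, element):
    target = "ACGT"
    seq = random_sequence(rng, 1000) + target + element + target + random_sequence(rng, 1000)
    genome = GenomeRecord(id="g", sequence=seq)
    copy = _copy(1004, 1004 + len(element))
    left, right, match, _ = extract_tsd(genome, copy, tsd_length=4)
    assert len(left) == len(right) == 4
    assert match


def test_flank_past_linear_end_flags_no_tsd(element):
    genome = GenomeRecord(id="g", sequence=element + "ACGTACGTA")
    copy = _copy(0, len(element))
    left, right, match, _ = extract_tsd(genome, copy)
    assert (left, right, match) == ("", "", False)


# -- consensus --------------------------------------------------------------


def test_identical_sites_give_literal_consensus():
    motif = build_consensus(["GCTTAGCAT"] * 8)
    assert motif.iupac == "GCTTAGCAT"
    assert motif.n_sites == 8


def test_two_base_position_gets_degenerate_code():
    motif = build_consensus(["ACT", "GCT"])
    assert motif.iupac == "RCT"


def test_counts_sum_to_n_sites():
    sites = ["ACT", "GCT", "TCT", "ACT"]
    motif = build_consensus(sites)
    for tally in motif.counts:
        assert sum(tally.values()) == len(sites)


def test_threshold_extremes_and_monotonicity(rng):
    sites = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(20)]
    minimal = build_consensus(sites, freq_threshold=1e-9)
    # at threshold -> 0, the minimal IUPAC cover of every observed base
    for j, letter in enumerate(minimal.iupac):
        observed = {s[j] for s in sites}
        from evotrace.mobilome import IUPAC
        assert IUPAC[frozenset(observed)] == letter
    strict = build_consensus(sites, freq_threshold=1.0)
    assert all(c in "ACGTN" for c in strict.iupac)

    def included_sets(motif, thr):
        n = motif.n_sites
        return [frozenset(b for b in "ACGT" if tally[b] / n >= thr)
                for tally in motif.counts]

    thresholds = (1e-9, 0.1, 0.25, 0.5, 0.75, 1.0)
    sets_by_thr = [included_sets(build_consensus(sites, t), t) for t in thresholds]
    for prev, cur in zip(sets_by_thr, sets_by_thr[1:]):
        for a, b in zip(prev, cur):
            assert b <= a  # raising the threshold never widens a position


def test_width_mismatch_rejected():
    with pytest.raises(ValueError, match="width"):
        build_consensus(["ACGT", "ACG"])


def test_degenerate_pwm_consensus_from_simulated_insertions(tiny_params):
    """Pooled planted target sites reproduce the PWM's IUPAC footprint."""
    from evotrace.pipeline import fixture_params
    from evotrace.simulate import generate_ancestor, evolve_lineage

    params = fixture_params("tiny", 3)
    params.p_event_class = {"snp": 0.0, "small_indel": 0.0, "is_insertion": 1.0,
                            "large_deletion": 0.0, "element_excision": 0.0}
    ancestor, features = generate_ancestor(params)
    sites = []
    for seed in range(12):
        _, truth = evolve_lineage(ancestor, features, params,
                                  params.days_total, seed=seed)
        sites.extend(ev.planted_tsd for ev in truth.visible_events()
                     if ev.event_class == "is_insertion")
    assert len(sites) >= 100
    motif = build_consensus(sites, freq_threshold=0.25)
    # strong literal positions of the planted model must come through
    assert motif.iupac[2] == "C"
    assert motif.iupac[3] == "T"
    assert motif.iupac[0] in ("Y", "C", "T")
    assert motif.iupac[1] in ("R", "A", "G")


# -- allele profiling -------------------------------------------------------


def _mutate(seq, rng, positions):
    out = list(seq)
    for i in positions:
        out[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[i]]
    return "".join(out)


def test_copy_identical_to_allele_a(rng, element):
    allele_a = element
    allele_b = _mutate(element, rng, rng.choice(len(element), 19, replace=False))
    profile = classify_against_alleles(allele_a, allele_a, allele_b)
    assert len(profile.positions) == 19
    assert all(call == "A" for *_rest, call in profile.positions)
    assert profile.coding_changes == []


def test_mosaic_copy_partitions_calls(rng, element):
    allele_a = element
    diff_pos = np.sort(rng.choice(len(element), 18, replace=False))
    allele_b = _mutate(element, rng, diff_pos)
    third = len(element) // 3
    mosaic = allele_a[:third] + allele_b[third:]
    profile = classify_against_alleles(mosaic, allele_a, allele_b)
    for off, _a, _b, _obs, call in profile.positions:
        assert call == ("A" if off < third else "B")


def test_short_copy_rejected(element):
    with pytest.raises(ValueError, match="90%"):
        classify_against_alleles(element[: len(element) // 2], element, element)
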