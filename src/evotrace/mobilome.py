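"""Insertion-sequence (IS) detection, target-site duplications and consensus.

A cut-and-paste IS element duplicates a short target word on insertion,
leaving identical direct repeats on both flanks (9 bp for IS10-family
elements).  This module locates IS copies in a genome by seeding k-mer
matches against a reference element and polishing with banded edit-distance
alignment, separates composite-transposon ends from isolated copies,
extracts and validates target-site duplications (TSDs), builds the
degenerate IUPAC consensus of the insertion targets, and profiles copies
against two reference alleles to classify hybrid elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from evotrace.io import GenomeRecord

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


#: minimal IUPAC code for each base set
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N", frozenset(): "N",
}


@dataclass
class ISCopy:
    """A located insertion-sequence copy."""

    family: str
    seq_id: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    tsd_left: str = ""
    tsd_right: str = ""
    tsd_match: bool = False
    target_site: str = ""
    in_composite: bool = False

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusMotif:
    """Per-position base tallies and the degenerate IUPAC consensus."""

    width: int
    counts: list  # one dict {base: count} per position
    iupac: str
    n_sites: int


@dataclass
class DiagnosticProfile:
    """Allele calls at every position where two reference alleles differ."""

    positions: list  # (offset, alleleA base, alleleB base, observed, call)
    coding_changes: list  # residue substitutions vs the better-matching allele

    def calls(self) -> str:
        return "".join(c for *_x, c in self.positions)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def find_is_copies(
    genome: GenomeRecord,
    is_reference: GenomeRecord,
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
    k: int = 15,
) -> list:
    """Locate copies of a reference IS element in a genome.

    k-mer seeds from both strands of the element are clustered into
    candidate intervals, each candidate is polished by infix edit-distance
    alignment of the full element, and overlapping candidates are
    deduplicated keeping the highest identity.  Identity is computed over
    the aligned span; coverage (aligned span / element length) is reported
    separately.  Circular genomes are scanned across the origin.
    """
    is_seq = is_reference.sequence
    if len(is_seq) < 2 * k:
        raise ValueError("IS reference must be at least 2k long")
    gseq = genome.sequence
    L = len(gseq)
    ext = len(is_seq) - 1 if genome.circular else 0
    scan = gseq + gseq[:ext]

    seeds = {}
    for strand, seq in (("+", is_seq), ("-", _revcomp(is_seq))):
        for i in range(len(seq) - k + 1):
            seeds.setdefault(seq[i : i + k], []).append(strand)
    hits = {"+": [], "-": []}
    for i in range(len(scan) - k + 1):
        for strand in seeds.get(scan[i : i + k], ()):
            hits[strand].append(i)

    candidates = []
    merge_gap = max(2 * k, len(is_seq) // 8)
    for strand, positions in hits.items():
        if not positions:
            continue
        positions = sorted(set(positions))
        cluster = [positions[0]]
        clusters = []
        for p in positions[1:]:
            if p - cluster[-1] <= merge_gap:
                cluster.append(p)
            else:
                clusters.append(cluster)
                cluster = [p]
        clusters.append(cluster)
        query = is_seq if strand == "+" else _revcomp(is_seq)
        for cl in clusters:
            w0 = max(0, cl[0] - len(is_seq) // 4)
            w1 = min(len(scan), cl[-1] + k + len(is_seq) // 4)
            window = scan[w0:w1]
            aln = edlib.align(query, window, task="locations", mode="HW")
            if aln["editDistance"] < 0 or not aln["locations"]:
                continue
            loc = aln["locations"][0]
            span = loc[1] - loc[0] + 1
            identity = 1.0 - aln["editDistance"] / max(span, 1)
            coverage = min(1.0, span / len(is_seq))
            if identity < min_identity or coverage < min_coverage:
                continue
            start = w0 + loc[0]
            end = w0 + loc[1] + 1
            if genome.circular and start >= L:
                start, end = start - L, end - L
            candidates.append(
                ISCopy(
                    family=is_reference.id, seq_id=genome.id,
                    start=start, end=end, strand=strand,
                    identity=identity, coverage=coverage,
                )
            )

    # deduplicate overlapping candidates, best identity first
    candidates.sort(key=lambda c: (-c.identity, c.start))
    kept: list[ISCopy] = []
    for c in candidates:
        if any(min(c.end, o.end) - max(c.start, o.start) > len(is_seq) // 2
               for o in kept):
            continue
        kept.append(c)
    kept.sort(key=lambda c: c.start)
    return kept


def flag_composite(
    copies: list,
    features: list | None = None,
    max_cargo: int = 15000,
) -> list:
    """Mark composite-transposon ends among a genome's IS copies.

    Two same-family copies whose inner gap is at most ``max_cargo`` and
    whose cargo segment contains at least one annotated CDS (when features
    are supplied) are flagged ``in_composite``; everything else counts as
    isolated.  Returns the same list, flags set.
    """
    ordered = sorted(copies, key=lambda c: c.start)
    for left, right in zip(ordered, ordered[1:]):
        if left.family != right.family or left.in_composite:
            continue
        gap_start, gap_end = left.end, right.start
        if gap_end - gap_start > max_cargo or gap_end <= gap_start:
            continue
        if features is not None:
            has_cds = any(
                f.kind == "CDS" and f.seq_id == left.seq_id
                and f.start >= gap_start and f.end <= gap_end
                for f in features
            )
            if not has_cds:
                continue
        left.in_composite = right.in_composite = True
    return ordered


def extract_tsd(
    genome: GenomeRecord, copy: ISCopy, tsd_length: int = 9
) -> tuple:
    """Flanking direct repeats of an IS copy.

    Returns ``(tsd_left, tsd_right, tsd_match, target_site)`` and records
    them on the copy.  ``target_site`` is the duplicated word (set when the
    flanks match).  On a linear genome a flank running past the sequence
    end yields empty flanks and ``tsd_match=False``.
    """
    seq = genome.sequence
    L = len(seq)
    if genome.circular:
        left = (seq * 2)[copy.start - tsd_length + L : copy.start + L]
        right = (seq + seq)[copy.end : copy.end + tsd_length]
    else:
        if copy.start - tsd_length < 0 or copy.end + tsd_length > L:
            copy.tsd_left = copy.tsd_right = ""
            copy.tsd_match = False
            copy.target_site = ""
            return "", "", False, ""
        left = seq[copy.start - tsd_length : copy.start]
        right = seq[copy.end : copy.end + tsd_length]
    match = left == right
    copy.tsd_left, copy.tsd_right = left, right
    copy.tsd_match = match
    copy.target_site = left if match else ""
    return left, right, match, copy.target_site


def build_consensus(target_sites: list, freq_threshold: float = 0.25) -> ConsensusMotif:
    """Degenerate IUPAC consensus over aligned target sites.

    At each position, bases reaching ``freq_threshold`` (ties included)
    enter the base set, encoded as the minimal IUPAC code covering exactly
    that set; an empty set (possible for thresholds above 0.25) encodes N.
    """
    if not target_sites:
        raise ValueError("need at least one target site")
    width = len(target_sites[0])
    if any(len(s) != width for s in target_sites):
        raise ValueError("target sites differ in width")
    n = len(target_sites)
    counts = []
    letters = []
    for j in range(width):
        tally = {b: 0 for b in "ACGT"}
        for s in target_sites:
            b = s[j].upper()
            if b in tally:
                tally[b] += 1
        counts.append(tally)
        included = frozenset(b for b in "ACGT" if tally[b] / n >= freq_threshold)
        letters.append(IUPAC[included])
    return ConsensusMotif(width=width, counts=counts, iupac="".join(letters), n_sites=n)


# ---------------------------------------------------------------------------
# allele profiling
# ---------------------------------------------------------------------------


def _project_onto(allele: str, copy_sequence: str) -> str:
    """Copy bases written in allele coordinates ('-' where copy has a gap)."""
    if copy_sequence == allele:
        return copy_sequence
    aln = edlib.align(copy_sequence, allele, task="path", mode="NW")
    import re

    out = []
    i = j = 0  # i: allele, j: copy
    for m in re.finditer(r"(\d+)([=XID])", aln["cigar"]):
        ln, op = int(m.group(1)), m.group(2)
        if op in "=X":
            out.append(copy_sequence[j : j + ln])
            i += ln
            j += ln
        elif op == "D":  # allele base absent from copy
            out.append("-" * ln)
            i += ln
        else:  # op == "I": extra copy bases, no allele coordinate
            j += ln
    return "".join(out)


def classify_against_alleles(
    copy_sequence: str, alleleA: str, alleleB: str
) -> DiagnosticProfile:
    """Profile an element copy against two same-length reference alleles.

    Diagnostic positions are exactly the loci where the alleles differ; at
    each, the copy is called A, B or neither.  Coding changes are residue
    substitutions in the element's longest ORF relative to the
    better-matching allele.
    """
    if len(alleleA) != len(alleleB):
        raise ValueError("alleles must have equal length (align them first)")
    if len(copy_sequence) < 0.9 * len(alleleA):
        raise ValueError("copy covers < 90% of the allele length")
    proj = _project_onto(alleleA, copy_sequence)
    positions = []
    for i, (a, b) in enumerate(zip(alleleA, alleleB)):
        if a == b:
            continue
        obs = proj[i]
        call = "A" if obs == a else "B" if obs == b else "neither"
        positions.append((i, a, b, obs, call))

    n_a = sum(1 for p in positions if p[4] == "A")
    n_b = sum(1 for p in positions if p[4] == "B")
    better = alleleA if n_a >= n_b else alleleB
    coding = _coding_changes(better, proj)
    return DiagnosticProfile(positions=positions, coding_changes=coding)


def _longest_orf(seq: str) -> tuple:
    """(start, end) of the longest forward-strand ATG..stop ORF; (0, 0) if none."""
    from Bio.Seq import Seq

    best = (0, 0)
    for frame in range(3):
        i = frame
        start = None
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in ("TAA", "TAG", "TGA"):
                if i + 3 - start > best[1] - best[0]:
                    best = (start, i + 3)
                start = None
            i += 3
    return best


def _coding_changes(allele: str, projected_copy: str) -> list:
    from Bio.Seq import Seq

    s, e = _longest_orf(allele)
    if e - s < 90:
        return []
    region = projected_copy[s:e]
    if "-" in region:  # indel in the ORF: residue numbering undefined
        return []
    ref_prot = str(Seq(allele[s:e]).translate(table=11))
    obs_prot = str(Seq(region).translate(table=11))
    return [
        f"{ra}{idx + 1}{oa}"
        for idx, (ra, oa) in enumerate(zip(ref_prot, obs_prot))
        if ra != oa
    ]


# ---------------------------------------------------------------------------
# variant reclassification
# ---------------------------------------------------------------------------


def reclassify_is_insertions(
    variants: list, is_references: list, min_identity: float = 0.90
) -> list:
    """Relabel insertion variants whose content matches an IS element.

    The anchored genome comparison emits long insertions as plain
    ``insertion`` events; this pass upgrades those matching a reference
    element (on either strand, at ``min_identity`` over the element) to
    ``is_insertion``.  Returns the same list with classes updated.
    """
    for v in variants:
        if v.event_class != "insertion":
            continue
        for ref in is_references:
            is_seq = ref.sequence
            if len(v.alt_allele) < 0.8 * len(is_seq):
                continue
            best = min(
                edlib.align(q, v.alt_allele, mode="HW")["editDistance"]
                for q in (is_seq, _revcomp(is_seq))
            )
            if best >= 0 and 1.0 - best / len(is_seq) >= min_identity:
                v.event_class = "is_insertion"
                v.note = (v.note + f" is_family={ref.id}").strip()
                break
    return variants
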