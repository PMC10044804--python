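"""Structural characterization of large deletions and scaffold ends.

Given a deletion interval on a reference genome, these operations measure
the junction microhomology (a short identical tract present at both
breakpoint flanks, the signature of recombination or alternate end-joining
repair), detect in-frame gene fusions created when both breakpoints fall
inside coding sequences, classify the junction (precise element excision,
IS-flank recombination, microhomology, blunt), and circularize linear
assembly scaffolds that carry identical terminal repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from evotrace.io import GenomeRecord, GeneFeature

#: NCBI translation table used for fusion ORF checks (bacterial).
TRANSLATION_TABLE = 11


@dataclass
class DeletionJunction:
    """A characterized deletion: interval, microhomology and category.

    ``placement_range`` is the half-open interval of equivalent
    ``del_start`` values (every placement yields the identical post-deletion
    sequence); the canonical breakpoint is the leftmost.
    """

    seq_id: str
    del_start: int
    del_end: int
    mh_length: int
    mh_sequence: str
    placement_range: tuple
    category: str = ""


@dataclass
class FusionCall:
    """An in-frame (or frame-broken) gene fusion across a deletion junction."""

    gene5: GeneFeature
    gene3: GeneFeature
    retained5: tuple  # residue range of the 5' partner, 1-based inclusive
    retained3: tuple  # residue range of the 3' partner, 1-based inclusive
    in_frame: bool
    fusion_length: int  # residues of the fused ORF (0 if out of frame)


def microhomology(
    reference: GenomeRecord, del_start: int, del_end: int, max_m: int = 5000
) -> tuple:
    """Microhomology shared by the two breakpoint flanks of a deletion.

    Returns ``(mh_length, mh_sequence, placement_range)``.  The length is
    the longest common suffix of the two prefixes ending at the breakpoints
    plus the longest common prefix of the two suffixes starting there,
    capped at ``max_m``; every ``del_start`` inside ``placement_range``
    (half-open) yields the same post-deletion sequence.  Index arithmetic
    wraps on circular genomes.
    """
    L = len(reference)
    if not (0 <= del_start < del_end <= (L if not reference.circular else 2 * L)):
        raise ValueError(f"invalid deletion interval [{del_start}, {del_end})")
    if del_end - del_start >= L:
        raise ValueError("deletion cannot span the whole genome")
    seq = reference.sequence

    if reference.circular:
        def at(i: int) -> str:
            return seq[i % L]
        lo_limit = -L  # scans are bounded by max_m and the genome size below
    else:
        def at(i: int) -> str:
            return seq[i]
        lo_limit = 0

    cap = min(max_m, L - (del_end - del_start))
    suffix = 0
    while (
        suffix < cap
        and del_start - 1 - suffix >= lo_limit
        and at(del_start - 1 - suffix) == at(del_end - 1 - suffix)
    ):
        suffix += 1
    prefix = 0
    while (
        prefix < cap - suffix
        and (reference.circular or del_end + prefix < L)
        and at(del_start + prefix) == at(del_end + prefix)
    ):
        prefix += 1

    mh_length = suffix + prefix
    start = del_start - suffix
    mh_sequence = "".join(at(i) for i in range(start, start + mh_length))
    placement_range = (start, start + mh_length + 1)  # valid del_start values
    return mh_length, mh_sequence, placement_range


def characterize_deletion(
    reference: GenomeRecord, del_start: int, del_end: int, max_m: int = 5000
) -> DeletionJunction:
    """Build a :class:`DeletionJunction` (canonical leftmost breakpoint)."""
    mh, mh_seq, placement = microhomology(reference, del_start, del_end, max_m)
    shift = del_start - placement[0]
    return DeletionJunction(
        seq_id=reference.id,
        del_start=del_start - shift,
        del_end=del_end - shift,
        mh_length=mh,
        mh_sequence=mh_seq,
        placement_range=placement,
    )


def _cds_containing(features: list, pos: int, seq_id: str) -> GeneFeature | None:
    for f in features:
        if f.kind == "CDS" and f.seq_id == seq_id and f.start < pos < f.end:
            return f
    return None


def detect_fusion(
    features: list, deletion: DeletionJunction, reference: GenomeRecord
) -> FusionCall | None:
    """Detect a gene fusion created by a deletion.

    Fires when both breakpoints fall strictly inside same-strand CDSs.
    Retained residue ranges use the placement that maximizes each partner's
    contribution (the homologous tract, present once in the fusion, is
    attributed to both partners — matching how fusion endpoints are
    conventionally reported).  The fused ORF is translated (bacterial code)
    to verify its stop structure when in frame.
    """
    mh = deletion.mh_length
    ls, le = deletion.del_start, deletion.del_end  # leftmost placement
    seq = reference.sequence

    # 5' partner keeps its start; 3' partner keeps its stop
    g_at_start = _cds_containing(features, ls + mh, deletion.seq_id) or _cds_containing(
        features, ls, deletion.seq_id
    )
    g_at_end = _cds_containing(features, le, deletion.seq_id) or _cds_containing(
        features, le + mh, deletion.seq_id
    )
    if g_at_start is None or g_at_end is None or g_at_start is g_at_end:
        return None
    if g_at_start.strand != g_at_end.strand:
        return None

    if g_at_start.strand == "+":
        gene5, gene3 = g_at_start, g_at_end
        n5 = (ls + mh - gene5.start) // 3  # complete codons, rightmost placement
        lost3 = (le - gene3.start) // 3  # complete codons lost, leftmost placement
        total3 = len(gene3) // 3 - 1  # excluding the stop codon
        retained5 = (1, n5)
        retained3 = (lost3 + 1, total3)
        in_frame = (ls - gene5.start) % 3 == (le - gene3.start) % 3
        fused_nt = seq[gene5.start : ls] + seq[le : gene3.end]
    else:
        gene5, gene3 = g_at_end, g_at_start
        n5 = (gene5.end - le) // 3
        lost3 = (gene3.end - (ls + mh)) // 3
        total3 = len(gene3) // 3 - 1
        retained5 = (1, n5)
        retained3 = (lost3 + 1, total3)
        in_frame = (gene5.end - le) % 3 == (gene3.end - ls) % 3
        fused_nt = str(
            Seq(seq[gene3.start : ls] + seq[le : gene5.end]).reverse_complement()
        )

    fusion_length = 0
    if in_frame:
        usable = len(fused_nt) - len(fused_nt) % 3
        prot = str(Seq(fused_nt[:usable]).translate(table=TRANSLATION_TABLE))
        stop = prot.find("*")
        fusion_length = len(prot) if stop < 0 else stop
        if 0 <= stop < len(prot) - 1:
            in_frame = False  # premature stop: not a productive fusion
    return FusionCall(
        gene5=gene5,
        gene3=gene3,
        retained5=retained5,
        retained3=retained3,
        in_frame=in_frame,
        fusion_length=fusion_length,
    )


def classify_deletion(
    deletion: DeletionJunction,
    features: list,
    is_copies: list | None = None,
    boundary_tolerance: int = 0,
    is_flank_tolerance: int = 3,
    min_mh: int = 5,
) -> str:
    """Assign a junction category to a characterized deletion.

    Priority: ``precise_element_excision`` (some equivalent placement
    matches an annotated prophage/mobile element's boundaries within
    ``boundary_tolerance``), then ``is_flank_recombination`` (a breakpoint
    abuts an IS copy boundary within ``is_flank_tolerance``), then
    ``microhomology`` (mh_length >= min_mh), else ``blunt``.
    The category is also written onto ``deletion.category``.
    """
    ls = deletion.del_start
    size = deletion.del_end - deletion.del_start
    lo, hi = deletion.placement_range
    placements = range(lo, hi)

    category = None
    for f in features:
        if f.kind not in ("prophage", "mobile_element"):
            continue
        if f.seq_id != deletion.seq_id:
            continue
        if abs(size - len(f)) > 2 * boundary_tolerance:
            continue
        for s in placements:
            if abs(s - f.start) <= boundary_tolerance and abs(
                s + size - f.end
            ) <= boundary_tolerance:
                category = "precise_element_excision"
                break
        if category:
            break

    if category is None and is_copies:
        bounds = []
        for c in is_copies:
            bounds.extend([c.start, c.end])
        for s in placements:
            for b in bounds:
                if min(abs(s - b), abs(s + size - b)) <= is_flank_tolerance:
                    category = "is_flank_recombination"
                    break
            if category:
                break

    if category is None:
        category = "microhomology" if deletion.mh_length >= min_mh else "blunt"
    deletion.category = category
    return category


def circularize(
    scaffold: GenomeRecord, min_repeat: int = 100
) -> tuple[GenomeRecord, int]:
    """Circularize a linear scaffold with identical terminal repeats.

    Finds the longest exact match between a prefix and a suffix (at most
    half the scaffold, so the copies do not overlap).  If it reaches
    ``min_repeat``, the right copy is removed and the record is marked
    circular; otherwise the scaffold is returned unchanged together with
    the repeat length found.
    """
    if scaffold.circular:
        return scaffold, 0
    s = scaffold.sequence
    n = len(s)
    # KMP failure function gives the longest border (prefix == suffix)
    fail = [0] * n
    j = 0
    for i in range(1, n):
        while j and s[i] != s[j]:
            j = fail[j - 1]
        if s[i] == s[j]:
            j += 1
        fail[i] = j
    border = fail[-1] if n else 0
    while border > n // 2:
        border = fail[border - 1]
    if n < 2 * min_repeat or border < min_repeat:
        return scaffold, border
    circ = GenomeRecord(
        id=scaffold.id,
        sequence=s[: n - border],
        circular=True,
        description=(scaffold.description + f" circularized terminal_repeat={border}").strip(),
    )
    return circ, border
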