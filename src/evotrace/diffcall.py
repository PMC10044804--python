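"""Variant recovery between two near-identical genomes by unique-k-mer anchoring.

The reference and query are anchored on k-mers that are unique in *both*
sequences (which suppresses mis-anchoring inside repeated insertion-sequence
copies), anchors are chained by longest collinear subsequence, and each
inter-anchor gap is resolved by an end-anchored unit-cost edit-script
alignment into SNP / insertion / deletion / substitution events.  All
emitted variants are left-normalized.  Gaps whose two sides are both larger
than ``max_gap`` and disagree are reported as unresolved regions, never
silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from evotrace.io import GenomeRecord, Variant

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class DivergenceError(ValueError):
    """Genomes share too few unique k-mers for anchored comparison."""


@dataclass
class AnchorChain:
    """Collinear (ref_pos, query_pos) anchor pairs of length k."""

    pairs: list
    k: int


@dataclass
class UnresolvedRegion:
    """A reference interval the anchored comparison could not resolve."""

    seq_id: str
    start: int
    end: int
    reason: str = "gap exceeds max_gap"


@dataclass
class GenomeDiff:
    """Full result of an anchored genome comparison."""

    variants: list
    unresolved: list
    chain: AnchorChain
    rotation: int = 0  # bases the query was rotated left (circular genomes)


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def _unique_kmers(seq: str, k: int, circular: bool) -> dict:
    """Positions of k-mers occurring exactly once (circularly if flagged)."""
    scan = seq + seq[: k - 1] if circular and len(seq) >= k else seq
    n = len(seq) if circular else len(seq) - k + 1
    counts: dict[str, int] = {}
    for i in range(max(n, 0)):
        km = scan[i : i + k]
        counts[km] = counts.get(km, 0) + 1
    pos = {}
    for i in range(max(n, 0)):
        km = scan[i : i + k]
        if counts[km] == 1:
            pos[km] = i
    return pos


def _lis_chain(pairs: list) -> list:
    """Longest strictly-increasing subsequence in query position.

    ``pairs`` must be sorted by reference position.  Ties are broken toward
    the smaller query position (deterministic patience sorting).
    """
    import bisect

    tails: list[int] = []  # query positions
    tails_idx: list[int] = []
    parent = [-1] * len(pairs)
    for i, (_r, q) in enumerate(pairs):
        j = bisect.bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        else:
            tails[j] = q
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.append(pairs[i])
        i = parent[i]
    out.reverse()
    return out


def _blocks_from_chain(chain: list, k: int, ref: str, query: str) -> list:
    """Merge chained anchors into maximal exact-match blocks.

    Returns (r_start, r_end, q_start, q_end) half-open intervals; each
    block satisfies ``ref[r_start:r_end] == query[q_start:q_end]``.
    """
    blocks = []
    for r, q in chain:
        if blocks:
            r0, r1, q0, q1 = blocks[-1]
            if r - r0 == q - q0 and (r <= r1 or ref[r1:r + k] == query[q1:q + k]):
                blocks[-1] = (r0, max(r1, r + k), q0, max(q1, q + k))
                continue
        blocks.append((r, r + k, q, q + k))
    # trim overlaps introduced by periodic sequence at block junctions
    trimmed = []
    for b in blocks:
        r0, r1, q0, q1 = b
        if trimmed:
            pr1, pq1 = trimmed[-1][1], trimmed[-1][3]
            ov = max(pr1 - r0, pq1 - q0, 0)
            r0, q0 = r0 + ov, q0 + ov
            if r0 >= r1:
                continue
        trimmed.append((r0, r1, q0, q1))
    return trimmed


# ---------------------------------------------------------------------------
# gap resolution
# ---------------------------------------------------------------------------


def _cigar_events(cigar: str, ref_seg: str, q_seg: str, r_off: int):
    """Convert an edlib NW cigar into (pos, ref, alt, kind) tuples."""
    out = []
    i = r_off
    j = 0
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op == "=":
            i += n
            j += n
        elif op == "X":
            ref_run = ref_seg[i - r_off : i - r_off + n]
            alt_run = q_seg[j : j + n]
            kind = "snp" if n == 1 else "substitution"
            out.append((i, ref_run, alt_run, kind))
            i += n
            j += n
        elif op == "D":  # consumes reference only
            out.append((i, ref_seg[i - r_off : i - r_off + n], "", "deletion"))
            i += n
        elif op == "I":  # consumes query only
            out.append((i, "", q_seg[j : j + n], "insertion"))
            j += n
        else:  # 'M' should not appear with task="path"
            raise ValueError(f"unexpected cigar op {op}")
    return out


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def _resolve_gap(ref_seg: str, q_seg: str, r_off: int, max_gap: int,
                 k: int = 15, depth: int = 0):
    """Resolve one inter-anchor gap; returns (events, unresolved_intervals).

    Shared flanks are trimmed first, so a structural indel with a
    microhomologous junction comes out as one event rather than an
    arbitrary traceback split.  Remaining cores are re-anchored locally
    (k-mers unique within the two segments, useful where genome-wide
    repeats such as IS copies suppressed primary anchors) and only small
    irreducible cores go to the unit-cost aligner.
    """
    if ref_seg == q_seg:
        return [], []
    p = _common_prefix_len(ref_seg, q_seg)
    s = _common_suffix_len(ref_seg[p:], q_seg[p:])
    ref_core = ref_seg[p : len(ref_seg) - s]
    q_core = q_seg[p : len(q_seg) - s]
    off = r_off + p
    if not ref_core and not q_core:
        return [], []
    if not q_core:
        return [(off, ref_core, "", "deletion")], []
    if not ref_core:
        return [(off, "", q_core, "insertion")], []

    small = min(len(ref_core), len(q_core))
    large = max(len(ref_core), len(q_core))

    # structurally asymmetric gap (one side dominated by an indel): prefer an
    # end-anchored representation (the indel flush against one gap boundary,
    # the residual differences aligned against the other), falling back to
    # locating the short side anywhere inside the long one; both avoid the
    # unit-cost traceback scattering the indel through the gap
    if large >= 2 * small + 20 and large <= 50 * max_gap and small > 0:
        thresh = max(2, small // 4)
        if len(q_core) > len(ref_core):
            long_seg, short_seg = q_core, ref_core
        else:
            long_seg, short_seg = ref_core, q_core
        n = len(short_seg)
        d_suf = edlib.align(short_seg, long_seg[-n:], mode="NW")["editDistance"]
        d_pre = edlib.align(short_seg, long_seg[:n], mode="NW")["editDistance"]
        if min(d_suf, d_pre) <= thresh:
            events, unresolved = [], []
            if len(q_core) > len(ref_core):  # insertion-dominant
                extra = q_core[: len(q_core) - n] if d_suf <= d_pre else q_core[n:]
                if d_suf <= d_pre:
                    events.append((off, "", extra, "insertion"))
                    ev, bad = _resolve_gap(ref_core, q_core[-n:], off, max_gap,
                                           k, depth + 1)
                else:
                    ev, bad = _resolve_gap(ref_core, q_core[:n], off, max_gap,
                                           k, depth + 1)
                    events.extend(ev)
                    events.append((off + len(ref_core), "", extra, "insertion"))
                    return events, unresolved + bad
                events.extend(ev)
                return events, unresolved + bad
            else:  # deletion-dominant
                extra_len = len(ref_core) - n
                if d_suf <= d_pre:
                    events.append((off, ref_core[:extra_len], "", "deletion"))
                    ev, bad = _resolve_gap(ref_core[extra_len:], q_core,
                                           off + extra_len, max_gap, k, depth + 1)
                    events.extend(ev)
                else:
                    ev, bad = _resolve_gap(ref_core[:n], q_core, off, max_gap,
                                           k, depth + 1)
                    events.extend(ev)
                    events.append((off + n, ref_core[n:], "", "deletion"))
                return events, bad
        # interior placement (e.g. new IS copy inside an existing one)
        if len(q_core) > len(ref_core):
            aln = edlib.align(ref_core, q_core, task="locations", mode="HW")
            if 0 <= aln["editDistance"] <= thresh:
                a, b = aln["locations"][0]
                events, unresolved = [], []
                if a > 0:
                    events.append((off, "", q_core[:a], "insertion"))
                ev, bad = _resolve_gap(ref_core, q_core[a : b + 1], off, max_gap,
                                       k, depth + 1)
                events.extend(ev)
                unresolved.extend(bad)
                if b + 1 < len(q_core):
                    events.append((off + len(ref_core), "", q_core[b + 1 :],
                                   "insertion"))
                return events, unresolved
        else:
            aln = edlib.align(q_core, ref_core, task="locations", mode="HW")
            if 0 <= aln["editDistance"] <= thresh:
                a, b = aln["locations"][0]
                events, unresolved = [], []
                if a > 0:
                    events.append((off, ref_core[:a], "", "deletion"))
                ev, bad = _resolve_gap(ref_core[a : b + 1], q_core, off + a,
                                       max_gap, k, depth + 1)
                events.extend(ev)
                unresolved.extend(bad)
                if b + 1 < len(ref_core):
                    events.append((off + b + 1, ref_core[b + 1 :], "", "deletion"))
                return events, unresolved

    if small <= 64 and large <= max_gap:
        aln = edlib.align(q_core, ref_core, task="path", mode="NW")
        return _cigar_events(aln["cigar"], ref_core, q_core, off), []

    # local re-anchoring inside the gap
    if depth < 12 and k >= 8:
        ref_u = _unique_kmers(ref_core, k, False)
        qry_u = _unique_kmers(q_core, k, False)
        pairs = sorted((ref_u[km], qry_u[km]) for km in set(ref_u) & set(qry_u))
        chain = _lis_chain(pairs)
        if chain:
            blocks = _blocks_from_chain(chain, k, ref_core, q_core)
            events, unresolved = [], []
            cr, cq = 0, 0
            for r0, r1, q0, q1 in blocks + [(len(ref_core), len(ref_core),
                                             len(q_core), len(q_core))]:
                ev, bad = _resolve_gap(ref_core[cr:r0], q_core[cq:q0], off + cr,
                                       max_gap, max(k // 2, 8), depth + 1)
                events.extend(ev)
                unresolved.extend(bad)
                cr, cq = r1, q1
            return events, unresolved
        if k > 8:
            return _resolve_gap(ref_core, q_core, off, max_gap, max(k // 2, 8),
                                depth + 1)

    if small > max_gap:
        return [], [(off, off + len(ref_core))]
    aln = edlib.align(q_core, ref_core, task="path", mode="NW")
    return _cigar_events(aln["cigar"], ref_core, q_core, off), []


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def align_genomes(
    reference: GenomeRecord,
    query: GenomeRecord,
    k: int = 21,
    max_gap: int = 5000,
    large_threshold: int = 50,
    min_shared_fraction: float = 0.9,
) -> GenomeDiff:
    """Anchored comparison of two near-identical genomes.

    Anchors are k-mers unique in both sequences; the longest collinear
    chain defines matched blocks and the gaps between them are aligned
    end-to-end.  For circular genomes the query is first rotated so the
    chain starts at the reference origin.  Deletions of at least
    ``large_threshold`` bp are classed ``large_deletion`` (structural
    characterization happens downstream).
    """
    ref_u = _unique_kmers(reference.sequence, k, reference.circular)
    qry_u = _unique_kmers(query.sequence, k, query.circular)
    shared = set(ref_u) & set(qry_u)
    denom = min(len(ref_u), len(qry_u))
    if denom == 0 or len(shared) / denom < min_shared_fraction:
        raise DivergenceError(
            f"genomes share {len(shared)} of {denom} unique {k}-mers "
            f"(< {min_shared_fraction:.0%}); use whole-genome alignment tooling"
        )

    rotation = 0
    qseq = query.sequence
    if reference.circular and query.circular:
        first = min(shared, key=lambda km: ref_u[km])
        rotation = (qry_u[first] - ref_u[first]) % len(qseq)
        if rotation:
            qseq = qseq[rotation:] + qseq[:rotation]
            qry_u = _unique_kmers(qseq, k, True)
            shared = set(ref_u) & set(qry_u)

    pairs = sorted((ref_u[km], qry_u[km]) for km in shared)
    # anchors whose occurrence wraps the origin complicate block arithmetic;
    # drop them (the flanking linear anchors cover the same information)
    L_r, L_q = len(reference.sequence), len(qseq)
    pairs = [(r, q) for r, q in pairs if r + k <= L_r and q + k <= L_q]
    chain = _lis_chain(pairs)
    if not chain:
        raise DivergenceError("no collinear anchor chain found")
    blocks = _blocks_from_chain(chain, k, reference.sequence, qseq)

    raw_events = []
    unresolved = []
    cursor_r, cursor_q = 0, 0
    for r0, r1, q0, q1 in blocks + [(L_r, L_r, L_q, L_q)]:
        ref_seg = reference.sequence[cursor_r:r0]
        q_seg = qseq[cursor_q:q0]
        events, bad = _resolve_gap(ref_seg, q_seg, cursor_r, max_gap)
        raw_events.extend(events)
        unresolved.extend(UnresolvedRegion(reference.id, b0, b1) for b0, b1 in bad)
        cursor_r, cursor_q = r1, q1

    variants = []
    for pos, ref_run, alt_run, kind in raw_events:
        if kind == "deletion" and len(ref_run) >= large_threshold:
            kind = "large_deletion"
        v = Variant(
            strain=query.id,
            seq_id=reference.id,
            pos=pos,
            ref_allele=ref_run,
            alt_allele=alt_run,
            event_class=kind,
        )
        variants.append(normalize_variant(v, reference))
    variants.sort(key=lambda v: (v.pos, v.event_class, v.alt_allele))
    return GenomeDiff(
        variants=variants,
        unresolved=unresolved,
        chain=AnchorChain(pairs=chain, k=k),
        rotation=rotation,
    )


def diff_genomes(
    reference: GenomeRecord,
    query: GenomeRecord,
    k: int = 21,
    max_gap: int = 5000,
    large_threshold: int = 50,
) -> list:
    """Variant list between reference and query (see :func:`align_genomes`)."""
    return align_genomes(reference, query, k=k, max_gap=max_gap,
                         large_threshold=large_threshold).variants


def normalize_variant(variant: Variant, reference: GenomeRecord) -> Variant:
    """Left-normalize a variant against its reference.

    Indels are shifted to their leftmost equivalent placement; common
    prefix/suffix bases of substitution alleles are trimmed (which may
    reduce a substitution to a SNP or a pure indel); pure homopolymer-run
    changes are annotated ``run_before -> run_after`` in the note
    (e.g. ``A8->A7``).
    """
    ref = reference.sequence
    v = variant
    if v.ref_allele and ref[v.pos : v.pos + len(v.ref_allele)] != v.ref_allele:
        raise ValueError(
            f"ref allele mismatch at {v.pos}: variant says {v.ref_allele[:20]!r}, "
            f"reference has {ref[v.pos : v.pos + len(v.ref_allele)][:20]!r}"
        )
    if v.event_class == "snp":
        return v

    pos, ra, aa = v.pos, v.ref_allele, v.alt_allele
    # trim shared suffix then prefix
    while ra and aa and ra[-1] == aa[-1]:
        ra, aa = ra[:-1], aa[:-1]
    while ra and aa and ra[0] == aa[0]:
        ra, aa = ra[1:], aa[1:]
        pos += 1
    cls = v.event_class
    if ra and aa:
        cls = "snp" if len(ra) == len(aa) == 1 else "substitution"
    elif not ra and not aa:  # degenerate: alleles were identical
        return v
    elif not aa:
        cls = "large_deletion" if v.event_class == "large_deletion" else "deletion"
    else:
        cls = v.event_class if v.event_class == "is_insertion" else "insertion"

    note = v.note
    if not ra and aa:  # pure insertion: rotate left while context matches
        while pos > 0 and ref[pos - 1] == aa[-1]:
            aa = ref[pos - 1] + aa[:-1]
            pos -= 1
    elif ra and not aa:  # pure deletion
        while pos > 0 and ref[pos - 1] == ra[-1]:
            ra = ref[pos - 1] + ra[:-1]
            pos -= 1

    if (ra and not aa) or (aa and not ra):
        allele = ra or aa
        b = allele[0]
        if allele == b * len(allele) and pos < len(ref) and ref[pos] == b:
            run = 0
            while pos + run < len(ref) and ref[pos + run] == b:
                run += 1
            after = run - len(allele) if ra else run + len(allele)
            note = f"{b}{run}->{b}{after}"

    return Variant(v.strain, v.seq_id, pos, ra, aa, cls,
                   max(len(ra), len(aa)), v.frequency, note)


@dataclass
class ComparisonResult:
    """Partition of two strains' variant sets into shared and specific."""

    shared: list
    a_only: list
    b_only: list


def compare_variant_sets(a: list, b: list) -> ComparisonResult:
    """Partition two normalized variant sets by identity key.

    The match key is (seq_id, pos, ref_allele, alt_allele, event_class);
    everything else is strain-specific.  Both sets must be called against
    the same reference sequence.
    """
    ids_a = {v.seq_id for v in a}
    ids_b = {v.seq_id for v in b}
    if ids_a and ids_b and ids_a != ids_b:
        raise ValueError(f"mixed reference ids: {sorted(ids_a)} vs {sorted(ids_b)}")
    by_key_a = {v.key: v for v in a}
    by_key_b = {v.key: v for v in b}
    shared = [by_key_a[kk] for kk in by_key_a if kk in by_key_b]
    a_only = [v for kk, v in by_key_a.items() if kk not in by_key_b]
    b_only = [v for kk, v in by_key_b.items() if kk not in by_key_a]
    return ComparisonResult(shared=shared, a_only=a_only, b_only=b_only)


def count_changes(variants: list) -> int:
    """Number of change events: one per event regardless of its length."""
    return len(variants)


def apply_variants(reference: GenomeRecord, variants: list) -> str:
    """Apply non-overlapping reference-frame variants; returns the edited sequence.

    The inverse of :func:`diff_genomes`: applying its output to the
    reference reconstructs the query (up to rotation for circular genomes).
    """
    seq = reference.sequence
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        if seq[v.pos : v.pos + len(v.ref_allele)] != v.ref_allele:
            raise ValueError(f"variant at {v.pos} inconsistent with reference")
        seq = seq[: v.pos] + v.alt_allele + seq[v.pos + len(v.ref_allele) :]
    return seq
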