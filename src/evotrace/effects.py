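"""Variant consequence annotation and knockout calling.

Each variant is mapped onto the annotated coding sequences: SNPs become
silent/missense/nonsense calls by codon arithmetic, indels whose length is
not a multiple of three become frameshifts, IS insertions inside genes are
flagged, genes wholly contained in large deletions are deleted, and
intergenic changes report their flanking genes with an upstream flag.  The
knockout rule is the >10%-of-residues-lost convention: a frameshift,
truncation or in-gene IS insertion removing more than ``loss_threshold`` of
the protein, or complete deletion of the gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from evotrace.io import GenomeRecord, GeneFeature, Variant

TRANSLATION_TABLE = 11

TRUNCATING_EFFECTS = frozenset(
    {"frameshift", "nonsense_truncation", "is_insertion_in_gene", "gene_deleted"}
)

_START_CODONS = {"ATG", "GTG", "TTG"}


@dataclass
class ConsequenceCall:
    """Predicted consequence of one variant on one gene (or region)."""

    variant: Variant
    gene: str | None
    effect: str
    codon_affected: int = 0
    total_codons: int = 0
    fraction_lost: float = 0.0
    knockout: bool = False
    substitution: str = ""
    flank_genes: tuple = ()
    note: str = ""


def _codon_index(cds: GeneFeature, genomic_pos: int) -> int:
    """1-based codon index of a genomic position within a CDS (strand-aware)."""
    if cds.strand == "+":
        off = genomic_pos - cds.start
    else:
        off = cds.end - 1 - genomic_pos
    return off // 3 + 1


def _total_codons(cds: GeneFeature) -> int:
    return max(len(cds) // 3 - 1, 1)  # protein residues, stop excluded


def _coding_sequence(cds: GeneFeature, reference: GenomeRecord) -> str:
    nt = reference.sequence[cds.start : cds.end]
    return str(Seq(nt).reverse_complement()) if cds.strand == "-" else nt


def _truncation_fraction(codon: int, total: int) -> float:
    return max(0.0, min(1.0, (total - codon + 1) / total))


def _snp_call(v: Variant, cds: GeneFeature, reference: GenomeRecord) -> ConsequenceCall:
    total = _total_codons(cds)
    ci = _codon_index(cds, v.pos)
    coding = _coding_sequence(cds, reference)
    off = (v.pos - cds.start) if cds.strand == "+" else (cds.end - 1 - v.pos)
    alt = v.alt_allele if cds.strand == "+" else str(Seq(v.alt_allele).complement())
    codon_start = (off // 3) * 3
    old_codon = coding[codon_start : codon_start + 3]
    new_codon = (
        old_codon[: off % 3] + alt + old_codon[off % 3 + 1 :]
    )
    if len(old_codon) < 3:  # malformed annotation tail
        return ConsequenceCall(v, cds.locus_tag, "missense", ci, total,
                               note="partial terminal codon")
    aa_old = str(Seq(old_codon).translate(table=TRANSLATION_TABLE))
    aa_new = str(Seq(new_codon).translate(table=TRANSLATION_TABLE))
    if ci == 1 and old_codon in _START_CODONS and new_codon != old_codon:
        if new_codon in _START_CODONS:
            # initiation still yields fMet: functionally silent at the start
            return ConsequenceCall(v, cds.locus_tag, "silent", 1, total,
                                   substitution=f"{old_codon}>{new_codon}",
                                   note="alternative start codon")
        return ConsequenceCall(v, cds.locus_tag, "start_codon_change", 1, total,
                               substitution=f"{old_codon}>{new_codon}")
    if aa_old == aa_new:
        return ConsequenceCall(v, cds.locus_tag, "silent", ci, total,
                               substitution=f"{aa_old}{ci}{aa_new}")
    if aa_new == "*":
        frac = _truncation_fraction(ci, total)
        return ConsequenceCall(v, cds.locus_tag, "nonsense_truncation", ci, total,
                               fraction_lost=frac, substitution=f"{aa_old}{ci}*")
    return ConsequenceCall(v, cds.locus_tag, "missense", ci, total,
                           substitution=f"{aa_old}{ci}{aa_new}")


def _indel_call(v: Variant, cds: GeneFeature, reference: GenomeRecord) -> ConsequenceCall:
    total = _total_codons(cds)
    d = len(v.ref_allele)
    if cds.strand == "+":
        first_changed = v.pos
    else:
        first_changed = v.pos + d - 1 if d else v.pos - 1
    first_changed = min(max(first_changed, cds.start), cds.end - 1)
    ci = _codon_index(cds, first_changed)
    if abs(v.delta) % 3 != 0:
        frac = _truncation_fraction(ci, total)
        return ConsequenceCall(v, cds.locus_tag, "frameshift", ci, total,
                               fraction_lost=frac)
    # in-frame indel: check for an introduced stop from the affected codon on
    mutated = (
        reference.sequence[cds.start : v.pos]
        + v.alt_allele
        + reference.sequence[v.pos + d : cds.end]
    )
    if cds.strand == "-":
        mutated = str(Seq(mutated).reverse_complement())
    usable = len(mutated) - len(mutated) % 3
    prot = str(Seq(mutated[:usable]).translate(table=TRANSLATION_TABLE))
    stop = prot.find("*")
    if 0 <= stop < len(prot) - 1:
        frac = _truncation_fraction(stop + 1, total)
        return ConsequenceCall(v, cds.locus_tag, "nonsense_truncation", stop + 1,
                               total, fraction_lost=frac, note="in-frame indel stop")
    return ConsequenceCall(v, cds.locus_tag, "missense", ci, total,
                           note="in-frame indel")


def _intergenic_call(v: Variant, features: list, upstream_window: int) -> ConsequenceCall:
    cds = [f for f in features if f.kind == "CDS" and f.seq_id == v.seq_id]
    left = max((f for f in cds if f.end <= v.pos), key=lambda f: f.end, default=None)
    right = min((f for f in cds if f.start > v.pos), key=lambda f: f.start, default=None)
    flanks = tuple(f.locus_tag for f in (left, right) if f is not None)
    arrows = " / ".join(
        (f"-{f.gene or f.locus_tag}->" if f.strand == "+" else f"<-{f.gene or f.locus_tag}-")
        for f in (left, right) if f is not None
    )
    upstream_of = None
    for f in (left, right):
        if f is None:
            continue
        if f.strand == "+" and f.start - upstream_window <= v.pos < f.start:
            upstream_of = f
        elif f.strand == "-" and f.end <= v.pos < f.end + upstream_window:
            upstream_of = f
    if upstream_of is not None:
        return ConsequenceCall(v, upstream_of.locus_tag, "intergenic_upstream",
                               flank_genes=flanks, note=arrows)
    return ConsequenceCall(v, None, "intergenic_other", flank_genes=flanks, note=arrows)


def annotate(
    variant: Variant,
    features: list,
    reference: GenomeRecord,
    upstream_window: int = 50,
) -> list:
    """Consequence calls for one normalized variant.

    Returns one call per affected gene (a large deletion yields one
    ``gene_deleted`` call per contained gene plus truncation calls for
    genes clipped at its edges) or a single intergenic call.  ``knockout``
    is set on truncating calls losing more than 10% of the residues.
    """
    cds = [f for f in features if f.kind == "CDS" and f.seq_id == variant.seq_id]
    span = len(variant.ref_allele)
    v_start, v_end = variant.pos, variant.pos + max(span, 0)
    calls: list[ConsequenceCall] = []

    if variant.event_class in ("large_deletion",) or (
        variant.event_class in ("deletion", "substitution") and span >= 50
    ):
        for f in cds:
            if f.start >= v_start and f.end <= v_end:
                calls.append(
                    ConsequenceCall(variant, f.locus_tag, "gene_deleted",
                                    _total_codons(f), _total_codons(f),
                                    fraction_lost=1.0)
                )
            elif f.start < v_end and f.end > v_start:  # clipped at a breakpoint
                total = _total_codons(f)
                bp = v_start if f.start < v_start else v_end - 1
                ci = _codon_index(f, min(max(bp, f.start), f.end - 1))
                if (f.strand == "+") == (f.start < v_start):
                    frac = _truncation_fraction(ci, total)  # 3' part lost
                else:
                    frac = min(1.0, ci / total)  # 5' part lost
                calls.append(
                    ConsequenceCall(variant, f.locus_tag, "nonsense_truncation",
                                    ci, total, fraction_lost=frac,
                                    note="partial deletion")
                )
        if not calls:
            calls.append(_intergenic_call(variant, features, upstream_window))
    elif variant.event_class == "is_insertion":
        host = next((f for f in cds if f.start < variant.pos < f.end), None)
        if host is None:
            calls.append(_intergenic_call(variant, features, upstream_window))
        else:
            total = _total_codons(host)
            ci = _codon_index(host, variant.pos if host.strand == "+" else variant.pos - 1)
            frac = _truncation_fraction(ci, total)
            calls.append(
                ConsequenceCall(variant, host.locus_tag, "is_insertion_in_gene",
                                ci, total, fraction_lost=frac)
            )
    elif variant.event_class == "snp":
        host = next((f for f in cds if f.start <= variant.pos < f.end), None)
        if host is None:
            calls.append(_intergenic_call(variant, features, upstream_window))
        else:
            calls.append(_snp_call(variant, host, reference))
    elif variant.event_class == "substitution":
        host = next((f for f in cds if f.start < v_end and f.end > v_start), None)
        if host is None:
            calls.append(_intergenic_call(variant, features, upstream_window))
        else:
            calls.append(_indel_call(variant, host, reference))
    else:  # insertion / deletion
        def _hits(f: GeneFeature) -> bool:
            if span == 0:  # pure insertion: a point between two bases
                return f.start < variant.pos < f.end
            return f.start < v_end and f.end > v_start
        host = next((f for f in cds if _hits(f)), None)
        if host is None:
            calls.append(_intergenic_call(variant, features, upstream_window))
        else:
            calls.append(_indel_call(variant, host, reference))

    for c in calls:
        if c.effect in TRUNCATING_EFFECTS and (
            c.effect == "gene_deleted" or c.fraction_lost > 0.10
        ):
            c.knockout = True
    return calls


def annotate_all(
    variants: list, features: list, reference: GenomeRecord,
    upstream_window: int = 50,
) -> list:
    """Annotate every variant; returns the concatenated calls."""
    out = []
    for v in variants:
        out.extend(annotate(v, features, reference, upstream_window))
    return out


def reference_interrupted(features: list) -> set:
    """Locus tags flagged as already interrupted in the reference strain."""
    return {f.locus_tag for f in features if f.interrupted_in_reference}


def call_knockouts(
    calls: list,
    large_deletions: list,
    features: list,
    loss_threshold: float = 0.10,
) -> set:
    """Knocked-out locus tags under the >10%-residues-lost rule.

    The union of (a) genes fully inside the given large deletions and
    (b) truncating calls (frameshift, nonsense truncation, in-gene IS
    insertion) losing more than ``loss_threshold`` of the protein.  Genes
    already interrupted in the reference are excluded (see
    :func:`reference_interrupted` to report them separately).
    """
    cds = [f for f in features if f.kind == "CDS"]
    out: set[str] = set()
    for d in large_deletions:
        d_start, d_end = d.pos, d.pos + len(d.ref_allele)
        for f in cds:
            if f.seq_id == d.seq_id and f.start >= d_start and f.end <= d_end:
                out.add(f.locus_tag)
    for c in calls:
        if c.gene is None:
            continue
        if c.effect == "gene_deleted" or (
            c.effect in TRUNCATING_EFFECTS and c.fraction_lost > loss_threshold
        ):
            out.add(c.gene)
    return out - reference_interrupted(features)


@dataclass
class CrossRefResult:
    summary: pd.DataFrame
    per_gene: dict


def crossref_gene_sets(calls: list, gene_lists: dict) -> CrossRefResult:
    """Cross-reference consequence calls against named gene lists.

    ``gene_lists`` maps a label (e.g. ``essential``, ``heat_shock``,
    ``low_tm``) to locus tags.  For each list the summary counts genes with
    intragenic hits and genes with intergenic-adjacent hits; ``per_gene``
    maps each listed gene to the calls touching it.  Unknown locus tags
    draw a warning, not an error; duplicates and ordering do not matter.
    """
    intragenic: dict[str, list] = {}
    adjacent: dict[str, list] = {}
    for c in calls:
        if c.effect.startswith("intergenic"):
            for g in c.flank_genes:
                adjacent.setdefault(g, []).append(c)
        elif c.gene:
            intragenic.setdefault(c.gene, []).append(c)

    known = set(intragenic) | set(adjacent)
    rows = []
    per_gene: dict[str, list] = {}
    for label, tags in gene_lists.items():
        tags = list(dict.fromkeys(tags))  # de-duplicate, order-stable
        n_intra = n_adj = 0
        for tag in tags:
            hits = intragenic.get(tag, []) + adjacent.get(tag, [])
            if hits:
                per_gene.setdefault(tag, [])
                for h in hits:
                    if h not in per_gene[tag]:
                        per_gene[tag].append(h)
            if tag in intragenic:
                n_intra += 1
            if tag in adjacent:
                n_adj += 1
        unknown = [t for t in tags if t not in known]
        if unknown and len(unknown) == len(tags):
            warnings.warn(f"gene list {label!r}: no listed locus_tag has any call")
        rows.append(
            {"list": label, "n_genes": len(tags),
             "intragenic_hits": n_intra, "intergenic_adjacent_hits": n_adj}
        )
    return CrossRefResult(summary=pd.DataFrame(rows), per_gene=per_gene)
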