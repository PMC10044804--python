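"""Readers and writers for every external format the pipeline touches,
plus the shared coordinate and allele conventions.

Coordinate convention
---------------------
Internal coordinates are 0-based, half-open, everywhere in the package.
File interfaces (GFF3, VCF, the TSV variant dialect) are 1-based inclusive.
Conversion happens here and only here, through :func:`to_internal` and
:func:`to_file`.

Allele convention
-----------------
Variants are stored in *pure indel* form: an insertion has an empty
``ref_allele`` and inserts immediately **before** reference base ``pos``;
a deletion has an empty ``alt_allele`` and removes ``length`` bases starting
at ``pos``.  VCF records carry a shared anchor base, which is stripped on
read and re-added on write.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOME_ALPHABET = frozenset("ACGTN")

EVENT_CLASSES = frozenset(
    {"snp", "insertion", "deletion", "substitution", "is_insertion", "large_deletion"}
)

FEATURE_KINDS = frozenset({"CDS", "mobile_element", "prophage", "other"})


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


def to_internal(pos_1based: int) -> int:
    """Convert a 1-based inclusive file position to a 0-based internal one."""
    return pos_1based - 1


def to_file(pos_0based: int) -> int:
    """Convert a 0-based internal position to a 1-based inclusive file one."""
    return pos_0based + 1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeRecord:
    """One genome sequence (chromosome, plasmid or scaffold).

    ``circular`` marks a closed molecule: scanning operations wrap the
    origin by virtual concatenation.  ``sequence`` is uppercase ACGTN.
    """

    id: str
    sequence: str
    circular: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"genome record {self.id!r}: empty sequence")
        bad = set(self.sequence) - GENOME_ALPHABET
        if bad:
            pos = next(i for i, b in enumerate(self.sequence) if b in bad)
            raise FormatError(
                f"genome record {self.id!r}: non-ACGTN character "
                f"{self.sequence[pos]!r} at position {to_file(pos)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """An annotated feature, 0-based half-open internally.

    ``interrupted_in_reference`` carries the "already interrupted in the
    wildtype" flag so knockout reports can set such genes aside.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    gene: str = ""
    locus_tag: str = ""
    product: str = ""
    interrupted_in_reference: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise FormatError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.locus_tag or self.gene!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.kind == "CDS" and self.strand not in "+-":
            raise FormatError(f"CDS {self.locus_tag!r}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Variant:
    """One normalized change against a named reference sequence.

    ``pos`` is the 0-based position of the first affected reference base;
    for a pure insertion it is the position of the base *after* the
    insertion point.  ``frequency`` is the fraction of the population
    carrying the change (1.0 for consensus assemblies).
    """

    strain: str
    seq_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    event_class: str
    length: int = 0
    frequency: float = 1.0
    note: str = ""

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise FormatError(f"unknown event_class {self.event_class!r}")
        if not 0.0 < self.frequency <= 1.0:
            raise FormatError(f"frequency {self.frequency} outside (0, 1]")
        if self.event_class == "snp" and not (
            len(self.ref_allele) == len(self.alt_allele) == 1
        ):
            raise FormatError("snp requires |ref| == |alt| == 1")
        if self.length == 0:
            self.length = max(len(self.ref_allele), len(self.alt_allele))

    @property
    def key(self) -> tuple:
        """Identity key used when comparing variant sets between strains."""
        return (self.seq_id, self.pos, self.ref_allele, self.alt_allele, self.event_class)

    @property
    def delta(self) -> int:
        """Signed length change this variant applies to the genome."""
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass
class TmRecord:
    """Melting temperature of one gene product, in degrees Celsius."""

    locus_tag: str
    tm: float

    def __post_init__(self) -> None:
        try:
            self.tm = float(self.tm)
        except (TypeError, ValueError):
            raise FormatError(f"{self.locus_tag}: non-numeric tm {self.tm!r}") from None
        if self.tm != self.tm or self.tm in (float("inf"), float("-inf")):
            raise FormatError(f"{self.locus_tag}: tm must be finite")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_genome(path, expect_circular: bool | None = None) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Circularity is taken from ``expect_circular`` when given, otherwise from
    a ``circular=true`` token in the FASTA header description.  Rejects
    empty files and non-ACGTN characters.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate genome id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if expect_circular is None:
            circular = "circular=true" in desc.lower().split()
        else:
            circular = expect_circular
        records.append(
            GenomeRecord(id=rec.id, sequence=str(rec.seq), circular=circular, description=desc)
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_genome(records: list[GenomeRecord], path) -> None:
    """Write genomes to FASTA, recording circularity in the description."""
    out = []
    for g in records:
        desc = g.description
        token = "circular=true" if g.circular else "circular=false"
        if "circular=" not in desc:
            desc = (desc + " " + token).strip()
        out.append(SeqRecord(Seq(g.sequence), id=g.id, description=desc))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_KIND_TO_GFF = {"CDS": "CDS", "mobile_element": "mobile_genetic_element",
                "prophage": "prophage", "other": "region"}
_GFF_TO_KIND = {v: k for k, v in _KIND_TO_GFF.items()}
_GFF_TO_KIND["mobile_element"] = "mobile_element"


def read_features(path, genomes: list[GenomeRecord] | None = None) -> list[GeneFeature]:
    """Read CDS / mobile-element / prophage features from a GFF3 file.

    Other feature types are ignored.  Attributes ``gene``, ``locus_tag``,
    ``product`` and ``interrupted_in_reference`` are mapped; coordinates are
    converted to the internal 0-based half-open convention.  When matching
    ``genomes`` are supplied, features beyond the sequence end are rejected.
    """
    import gffutils

    lengths = {g.id: len(g) for g in genomes} if genomes else {}
    feats: list[GeneFeature] = []
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    for f in db.all_features(order_by=("seqid", "start")):
        kind = _GFF_TO_KIND.get(f.featuretype)
        if kind is None:
            continue
        if f.end < f.start:
            raise FormatError(
                f"feature at {f.seqid}:{f.start}-{f.end}: end < start"
            )
        if f.seqid in lengths and f.end > lengths[f.seqid]:
            raise FormatError(
                f"feature at {f.seqid}:{f.start}-{f.end} extends beyond "
                f"sequence length {lengths[f.seqid]}"
            )

        def attr(name: str) -> str:
            vals = f.attributes.get(name, [])
            return vals[0] if vals else ""

        feats.append(
            GeneFeature(
                seq_id=f.seqid,
                start=to_internal(f.start),
                end=f.end,  # GFF3 1-based inclusive end == 0-based half-open end
                strand=f.strand if f.strand in "+-" else ".",
                kind=kind,
                gene=attr("gene"),
                locus_tag=attr("locus_tag"),
                product=attr("product"),
                interrupted_in_reference=attr("interrupted_in_reference").lower()
                == "true",
            )
        )
    return feats


def write_features(features: list[GeneFeature], path) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            attrs = [f"ID=feat{i}"]
            if f.gene:
                attrs.append(f"gene={f.gene}")
            if f.locus_tag:
                attrs.append(f"locus_tag={f.locus_tag}")
            if f.product:
                attrs.append(f"product={f.product}")
            if f.interrupted_in_reference:
                attrs.append("interrupted_in_reference=true")
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        "evotrace",
                        _KIND_TO_GFF[f.kind],
                        str(to_file(f.start)),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Variant tables (TSV dialect and restricted VCF 4.2)
# ---------------------------------------------------------------------------

_TSV_HEADER = ["strain", "seq_id", "pos", "ref", "alt", "class", "length", "frequency", "note"]


def read_variants(path) -> list[Variant]:
    """Read variants from the TSV dialect or a restricted VCF 4.2 file.

    The format is auto-detected from the first line.  VCF records are
    limited to SNPs and simple indels; anchor bases are stripped so that
    alleles follow the pure-indel convention.
    """
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("##fileformat=VCF"):
            return _read_vcf(fh, str(path))
        return _read_tsv(fh, str(path))


def _read_tsv(fh, name: str) -> list[Variant]:
    header = fh.readline().rstrip("\n").split("\t")
    if header != _TSV_HEADER:
        raise FormatError(f"{name}: expected header {'	'.join(_TSV_HEADER)!r}")
    out = []
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(_TSV_HEADER):
            raise FormatError(f"{name}:{lineno}: expected {len(_TSV_HEADER)} columns")
        strain, seq_id, pos, ref, alt, cls, length, freq, note = fields
        out.append(
            Variant(
                strain=strain,
                seq_id=seq_id,
                pos=to_internal(int(pos)),
                ref_allele=ref,
                alt_allele=alt,
                event_class=cls,
                length=int(length) if length else 0,
                frequency=float(freq) if freq else 1.0,
                note=note,
            )
        )
    return out


def _read_vcf(fh, name: str) -> list[Variant]:
    out = []
    for lineno, line in enumerate(fh, start=1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 8:
            raise FormatError(f"{name}:{lineno}: truncated VCF record")
        chrom, pos, _id, ref, alt, _qual, _filt, info = fields[:8]
        if "," in alt:
            raise FormatError(f"{name}:{lineno}: multi-allelic records unsupported")
        pos0 = to_internal(int(pos))
        freq = 1.0
        for kv in info.split(";"):
            if kv.startswith("AF="):
                freq = float(kv[3:])
        strain = ""
        for kv in info.split(";"):
            if kv.startswith("STRAIN="):
                strain = kv[7:]
        if len(ref) == 1 and len(alt) == 1:
            out.append(Variant(strain, chrom, pos0, ref, alt, "snp", 1, freq))
        elif len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
            # deletion: anchor base shared, deleted bases follow it
            out.append(
                Variant(strain, chrom, pos0 + 1, ref[1:], "", "deletion",
                        len(ref) - 1, freq)
            )
        elif len(alt) > 1 and len(ref) == 1 and alt[0] == ref[0]:
            # insertion before the base after the anchor
            out.append(
                Variant(strain, chrom, pos0 + 1, "", alt[1:], "insertion",
                        len(alt) - 1, freq)
            )
        else:
            raise FormatError(
                f"{name}:{lineno}: record {ref}->{alt} outside the SNP/indel subset"
            )
    return out


def write_variants(variants: list[Variant], path) -> None:
    """Write variants in the TSV dialect (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.strain,
                        v.seq_id,
                        str(to_file(v.pos)),
                        v.ref_allele,
                        v.alt_allele,
                        v.event_class,
                        str(v.length),
                        f"{v.frequency:g}",
                        v.note,
                    ]
                )
                + "\n"
            )


def write_vcf(variants: list[Variant], reference: GenomeRecord, path) -> None:
    """Write SNPs and simple indels as minimal VCF 4.2 with anchor bases."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference.id},length={len(reference)}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=STRAIN,Number=1,Type=String,Description="Strain">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"AF={v.frequency:g}"
            if v.strain:
                info += f";STRAIN={v.strain}"
            if v.event_class == "snp":
                pos, ref, alt = to_file(v.pos), v.ref_allele, v.alt_allele
            elif v.event_class in ("deletion", "large_deletion"):
                anchor = reference.sequence[v.pos - 1]
                pos, ref, alt = v.pos, anchor + v.ref_allele, anchor
            elif v.event_class in ("insertion", "is_insertion"):
                anchor = reference.sequence[v.pos - 1]
                pos, ref, alt = v.pos, anchor, anchor + v.alt_allele
            else:  # substitution: emit as explicit REF/ALT block
                pos, ref, alt = to_file(v.pos), v.ref_allele, v.alt_allele
            fh.write(
                f"{v.seq_id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# Melting-temperature table
# ---------------------------------------------------------------------------


def read_tm_table(path) -> list[TmRecord]:
    """Read a two-column TSV of locus_tag and melting temperature (deg C).

    A header line ``locus_tag<TAB>tm`` is accepted and skipped.  Duplicate
    locus tags and non-numeric temperatures are rejected.
    """
    out: list[TmRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            tag, tm = fields
            if lineno == 1 and tag == "locus_tag":
                continue
            if tag in seen:
                raise FormatError(f"{path}:{lineno}: duplicate locus_tag {tag!r}")
            seen.add(tag)
            try:
                tm_val = float(tm)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric tm {tm!r} for {tag}"
                ) from None
            out.append(TmRecord(locus_tag=tag, tm=tm_val))
    return out


def write_tm_table(records: list[TmRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_tag\ttm\n")
        for r in records:
            fh.write(f"{r.locus_tag}\t{r.tm:g}\n")
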