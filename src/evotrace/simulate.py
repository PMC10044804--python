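"""Serial-passage genome-evolution simulator with a complete ground-truth ledger.

The generator emulates the statistical structure of a long adaptive
laboratory evolution (ALE) experiment on a gene-dense circular bacterial
chromosome: SNPs drawn from a pyrimidine-collapsed spectrum dominated by
C:G->T:A transitions, small indels (including homopolymer-run changes),
cut-and-paste insertion-sequence (IS) transpositions that duplicate a 9-bp
target site chosen from a position-weight model, large deletions that
recombine between short pre-existing repeat pairs (junction microhomology),
and precise excision of an annotated prophage-like element.  Two sibling
lineages can share a common phase and then diverge, mirroring a mixed
evolving culture from which two isolates were picked.

Every applied event is recorded in both ancestor and evolved coordinate
frames; re-applying the ledger to the ancestor reproduces the evolved
genome byte-for-byte, which is the oracle all recovery tests rest on.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from evotrace.io import GenomeRecord, GeneFeature, Variant
from evotrace.evostats import SNP_CLASSES, COMPLEMENT

EVENT_CLASS_NAMES = ("snp", "small_indel", "is_insertion", "large_deletion", "element_excision")

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


class SimulationError(RuntimeError):
    """Raised when an event cannot be placed within the retry budget."""


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def synthetic_is_element(length: int = 1329, seed: int = 916) -> str:
    """Deterministic synthetic cut-and-paste IS element.

    Synthetic stand-in for a real insertion sequence: 22-bp inverted
    terminal repeats around a transposase-like ORF spanning most of the
    element, IS10-like in length.  Fixed content for a given seed.
    """
    rng = np.random.default_rng(seed)
    ir = "".join(rng.choice(list(_BASES), size=22))
    n_codons = (length - 2 * len(ir) - 6) // 3
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    core = "ATG" + "".join(codons) + "TAA"
    pad_len = length - 2 * len(ir) - len(core)
    pad = "".join(rng.choice(list(_BASES), size=pad_len)) if pad_len > 0 else ""
    return ir + core + pad + _revcomp(ir)


def default_target_pwm(tsd_length: int = 9) -> np.ndarray:
    """Position-weight matrix (tsd_length x 4, ACGT order) for IS target choice.

    Defaults encode a degenerate pyrimidine/purine preference of the
    YRCTNNRNN form: Y and R positions split 0.45/0.45 between their two
    bases, literal positions carry 0.85, N positions are uniform.
    """
    Y = [0.05, 0.45, 0.05, 0.45]
    R = [0.45, 0.05, 0.45, 0.05]
    N = [0.25, 0.25, 0.25, 0.25]
    C = [0.05, 0.85, 0.05, 0.05]
    T = [0.05, 0.05, 0.05, 0.85]
    rows = {"Y": Y, "R": R, "N": N, "C": C, "T": T}
    pattern = "YRCTNNRNN"
    if tsd_length == len(pattern):
        return np.array([rows[c] for c in pattern], dtype=float)
    return np.tile(np.array(N, dtype=float), (tsd_length, 1))


DEFAULT_SPECTRUM_WEIGHTS = {
    "C:G>T:A": 0.65,
    "C:G>A:T": 0.08,
    "C:G>G:C": 0.05,
    "T:A>C:G": 0.10,
    "T:A>A:T": 0.06,
    "T:A>G:C": 0.06,
}

DEFAULT_EVENT_CLASS_P = {
    "snp": 0.65,
    "small_indel": 0.25,
    "is_insertion": 0.07,
    "large_deletion": 0.02,
    "element_excision": 0.01,
}

DEFAULT_MICROHOMOLOGY_WEIGHTS = {0: 0.2, 3: 0.15, 6: 0.15, 9: 0.2, 12: 0.3}


@dataclass
class EvolutionParams:
    """Study-condition parameters of the simulated ALE experiment.

    Defaults follow the serial-passage regime being emulated: 1,256
    subcultures every 48 h (2,512 days) at ~0.092 observed changes per day,
    1:8 dilution per transfer, sibling divergence 400 days before the end,
    a SNP spectrum with weight 0.65 on C:G->T:A, 9-bp target-site
    duplications for IS insertions, and log-normally sized large deletions
    recombining over short microhomologous repeats.  The chromosome itself
    is scaled down (200 kb) so whole-experiment replicates stay cheap.
    """

    genome_length: int = 200_000
    gc_fraction: float = 0.508
    n_genes: int = 120
    gene_length_mean: int = 900
    change_rate: float = 0.092
    days_total: float = 2512.0
    divergence_day: float | None = None  # default: 400 days before the end
    dilution_factor: float = 8.0
    transfer_interval: float = 2.0
    spectrum_weights: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM_WEIGHTS))
    p_event_class: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_CLASS_P))
    indel_length_geometric_p: float = 0.7
    is_sequence: str = ""
    tsd_length: int = 9
    target_pwm: np.ndarray | None = None
    deletion_size_log_mean: float = math.log(1200.0)
    deletion_size_log_sd: float = 0.8
    microhomology_length_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_MICROHOMOLOGY_WEIGHTS)
    )
    n_repeat_pairs: int = 10
    prophage_length: int = 4_000
    cargo_length: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.divergence_day is None:
            self.divergence_day = max(0.0, self.days_total - 400.0)
        if not self.is_sequence:
            self.is_sequence = synthetic_is_element()
        if self.target_pwm is None:
            self.target_pwm = default_target_pwm(self.tsd_length)
        self.target_pwm = np.asarray(self.target_pwm, dtype=float)
        if self.target_pwm.shape != (self.tsd_length, 4):
            raise ValueError("target_pwm must have shape (tsd_length, 4)")
        for name, mapping in (
            ("spectrum_weights", self.spectrum_weights),
            ("p_event_class", self.p_event_class),
            ("microhomology_length_weights", self.microhomology_length_weights),
        ):
            total = sum(mapping.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
        if set(self.spectrum_weights) != set(SNP_CLASSES):
            raise ValueError("spectrum_weights must cover the 6 collapsed SNP classes")
        if set(self.p_event_class) != set(EVENT_CLASS_NAMES):
            raise ValueError("p_event_class must cover the 5 event classes")
        if self.genome_length < 10 * self.gene_length_mean:
            raise ValueError("genome_length must be >= 10 x gene_length_mean")
        if not 0 <= self.divergence_day <= self.days_total:
            raise ValueError("divergence_day must lie in [0, days_total]")


@dataclass
class AppliedEvent:
    """One mutation applied to a lineage, in both coordinate frames.

    ``apply_pos``/``removed``/``inserted`` describe the edit in the frame
    of the genome at the moment of application (this is what replay uses);
    ``ancestor_start/end`` give the affected interval of the ancestor;
    ``evolved_start/end`` track the event's footprint in the final genome,
    updated as later events shift coordinates.  Events wholly contained in
    a later deletion are flagged ``erased`` (invisible in the final genome).
    """

    event_class: str
    day_applied: float
    apply_pos: int
    removed: str
    inserted: str
    ancestor_start: int
    ancestor_end: int
    evolved_start: int
    evolved_end: int
    protect_start: int
    protect_end: int
    planted_microhomology_length: int = 0
    planted_tsd: str = ""
    shared: bool = False
    erased: bool = False

    @property
    def delta(self) -> int:
        return len(self.inserted) - len(self.removed)


@dataclass
class EvolutionGroundTruth:
    """Ledger of applied events for one evolved strain."""

    strain: str
    ancestor_id: str
    events: list[AppliedEvent] = field(default_factory=list)

    def replay(self, ancestor_sequence: str) -> str:
        """Re-apply the ledger chronologically; returns the evolved sequence."""
        seq = ancestor_sequence
        for ev in self.events:
            got = seq[ev.apply_pos : ev.apply_pos + len(ev.removed)]
            if got != ev.removed:
                raise SimulationError(
                    f"replay mismatch at {ev.apply_pos}: expected "
                    f"{ev.removed[:20]!r}..., found {got[:20]!r}..."
                )
            seq = seq[: ev.apply_pos] + ev.inserted + seq[ev.apply_pos + len(ev.removed) :]
        return seq

    def visible_events(self) -> list[AppliedEvent]:
        return [ev for ev in self.events if not ev.erased]

    def to_variants(self, ancestor: GenomeRecord, normalize: bool = True) -> list[Variant]:
        """Project visible events into ancestor-frame :class:`Variant` rows."""
        out = []
        for ev in self.visible_events():
            v = event_to_variant(ev, self.strain, ancestor, normalize)
            if v is not None:
                out.append(v)
        return out

    def length_delta(self) -> int:
        return sum(ev.delta for ev in self.events)


def event_to_variant(
    ev: AppliedEvent, strain: str, ancestor: GenomeRecord, normalize: bool = True
) -> Variant | None:
    """Ancestor-frame variant for one visible applied event.

    Returns None for events with no ancestral footprint (e.g. a deletion
    that exactly cancelled an earlier insertion).
    """
    from evotrace.diffcall import normalize_variant

    anc = ancestor.sequence
    a0, a1 = ev.ancestor_start, ev.ancestor_end
    if a0 < 0:
        return None
    if ev.event_class == "snp":
        v = Variant(strain, ancestor.id, a0, anc[a0], ev.inserted, "snp")
    elif ev.event_class == "is_insertion":
        v = Variant(strain, ancestor.id, a0, "", ev.inserted, "is_insertion",
                    note=f"tsd={ev.planted_tsd}")
    elif ev.event_class in ("large_deletion", "element_excision"):
        if a0 == a1:
            return None
        v = Variant(strain, ancestor.id, a0, anc[a0:a1], "", "large_deletion",
                    note=ev.event_class)
    elif len(ev.removed) == 0:
        v = Variant(strain, ancestor.id, a0, "", ev.inserted, "insertion")
    elif len(ev.inserted) == 0:
        if a0 == a1:
            return None
        v = Variant(strain, ancestor.id, a0, anc[a0:a1], "", "deletion")
    else:
        v = Variant(strain, ancestor.id, a0, anc[a0:a1], ev.inserted, "substitution")
    return normalize_variant(v, ancestor) if normalize else v


def recoverable_variants(
    truth: EvolutionGroundTruth,
    ancestor: GenomeRecord,
    features: list,
    margin: int = 25,
    unresolved: list | None = None,
) -> list:
    """Truth variants for events outside repeated and unresolved regions.

    Excludes events whose ancestor footprint overlaps an annotated mobile
    element (where the absence of unique anchors makes placement ambiguous),
    events landing within ``margin`` of another IS-insertion event, and
    events inside caller-supplied unresolved reference intervals.  This is
    the denominator for recovery-rate checks.
    """
    repeats = [
        (f.start - margin, f.end + margin)
        for f in features
        if f.kind == "mobile_element"
    ]
    if unresolved:
        repeats.extend((u.start - margin, u.end + margin) for u in unresolved)
    visible = truth.visible_events()
    is_points = [e.ancestor_start for e in visible if e.event_class == "is_insertion"]
    out = []
    for ev in visible:
        a0 = ev.ancestor_start
        a1 = max(ev.ancestor_end, a0 + 1)
        if a0 < 0:
            continue
        if any(a1 > s and a0 < e for s, e in repeats):
            continue
        near_other_is = any(
            abs(a0 - pt) <= margin
            for pt in is_points
            if not (ev.event_class == "is_insertion" and pt == a0)
        )
        if near_other_is:
            continue
        v = event_to_variant(ev, truth.strain, ancestor)
        if v is not None:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Ancestor generation
# ---------------------------------------------------------------------------

_PLACEMENT_RETRIES = 2000


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def generate_ancestor(params: EvolutionParams) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Build a gene-dense circular ancestor genome with planted landmarks.

    The genome carries ``n_genes`` non-overlapping CDSs (ATG start, single
    in-frame stop at the end, random strands), one annotated prophage-like
    element with exact boundaries, one composite transposon (two identical
    IS copies flanking a cargo segment with its own CDS, the whole block
    bracketed by a duplicated target site), and ``n_repeat_pairs`` short
    intergenic repeat pairs that later large deletions recombine across.
    Repeat pairs are annotated as ``other`` features (``product``
    ``repeat_pair ...``) so :func:`evolve_lineage` can find them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xA11CE]))
    L = params.genome_length
    seq = _random_sequence(rng, L, params.gc_fraction)
    is_seq = params.is_sequence
    t = params.tsd_length

    placed: list[tuple[int, int]] = []  # exclusion intervals

    def fits(s: int, e: int, margin: int = 50) -> bool:
        return 0 <= s and e <= L and all(
            e + margin <= ps or pe + margin <= s for ps, pe in placed
        )

    def place(length: int, label: str) -> tuple[int, int]:
        for _ in range(_PLACEMENT_RETRIES):
            s = int(rng.integers(0, L - length))
            if fits(s, s + length):
                placed.append((s, s + length))
                return s, s + length
        raise SimulationError(f"cannot place {label} without overlap")

    features: list[GeneFeature] = []
    gid = params.seed  # only for the record id suffix

    # -- prophage-like element
    pp_s, pp_e = place(params.prophage_length, "prophage")
    features.append(
        GeneFeature("ancestor", pp_s, pp_e, "+", kind="prophage", gene="php1",
                    locus_tag="el0001", product="cryptic prophage-like element")
    )

    # -- composite transposon: [TSD][IS][cargo][IS][TSD], TSDs identical
    block_len = 2 * t + 2 * len(is_seq) + params.cargo_length
    tn_s, tn_e = place(block_len, "composite transposon")
    tsd = "".join(rng.choice(list(_BASES), size=t))
    cargo = "".join(rng.choice(list(_BASES), size=params.cargo_length))
    cargo_cds_len = 3 * max(100, (params.cargo_length // 2) // 3)
    cargo_cds = _random_cds(rng, cargo_cds_len // 3)
    cargo_off = (params.cargo_length - len(cargo_cds)) // 2
    cargo = cargo[:cargo_off] + cargo_cds + cargo[cargo_off + len(cargo_cds):]
    block = tsd + is_seq + cargo + is_seq + tsd
    seq[tn_s:tn_e] = np.frombuffer(block.encode(), dtype="S1")
    isl_s = tn_s + t
    isr_s = isl_s + len(is_seq) + params.cargo_length
    features.append(
        GeneFeature("ancestor", isl_s, isl_s + len(is_seq), "+", kind="mobile_element",
                    gene="isL", locus_tag="el0002", product="insertion sequence")
    )
    features.append(
        GeneFeature("ancestor", isr_s, isr_s + len(is_seq), "+", kind="mobile_element",
                    gene="isR", locus_tag="el0003", product="insertion sequence")
    )
    cds_s = isl_s + len(is_seq) + cargo_off
    features.append(
        GeneFeature("ancestor", cds_s, cds_s + len(cargo_cds), "+", kind="CDS",
                    gene="carA", locus_tag="b9000", product="cargo protein")
    )

    # -- repeat pairs for microhomology-mediated deletions
    mh_lengths = sorted(params.microhomology_length_weights)
    mh_p = np.array([params.microhomology_length_weights[m] for m in mh_lengths])
    pair_idx = 0
    for _ in range(params.n_repeat_pairs):
        m = int(rng.choice(mh_lengths, p=mh_p))
        if m == 0:
            continue  # blunt deletions need no planted repeat
        size = int(np.clip(rng.lognormal(params.deletion_size_log_mean,
                                         params.deletion_size_log_sd), 200, L // 4))
        for _ in range(_PLACEMENT_RETRIES):
            s = int(rng.integers(0, L - size - m))
            e = s + size
            if fits(s, s + m) and fits(e, e + m):
                seed_word = "".join(rng.choice(list(_BASES), size=m))
                seq[s:s + m] = np.frombuffer(seed_word.encode(), dtype="S1")
                seq[e:e + m] = np.frombuffer(seed_word.encode(), dtype="S1")
                placed.append((s, s + m))
                placed.append((e, e + m))
                pair_idx += 1
                features.append(
                    GeneFeature("ancestor", s, e + m, ".", kind="other",
                                gene=f"rep{pair_idx}", locus_tag=f"rp{pair_idx:04d}",
                                product=f"repeat_pair len={m} left={s} right={e}")
                )
                break
        else:
            raise SimulationError("cannot place repeat pair without overlap")

    # -- protein-coding genes (may fall inside the prophage, as real ones do)
    gene_excl = [iv for iv in placed if not (pp_s <= iv[0] and iv[1] <= pp_e)]
    gene_ivs: list[tuple[int, int]] = []

    def gene_fits(s: int, e: int) -> bool:
        return 0 <= s and e <= L and all(
            e + 20 <= ps or pe + 20 <= s for ps, pe in gene_excl + gene_ivs
        )

    for i in range(params.n_genes):
        glen = 3 * max(50, int(round(rng.normal(params.gene_length_mean,
                                                params.gene_length_mean / 4))) // 3)
        for _ in range(_PLACEMENT_RETRIES):
            s = int(rng.integers(0, L - glen))
            if gene_fits(s, s + glen):
                gene_ivs.append((s, s + glen))
                strand = "+" if rng.random() < 0.5 else "-"
                cds = _random_cds(rng, glen // 3)
                if strand == "-":
                    cds = _revcomp(cds)
                seq[s:s + glen] = np.frombuffer(cds.encode(), dtype="S1")
                features.append(
                    GeneFeature("ancestor", s, s + glen, strand, kind="CDS",
                                gene=f"syg{i+1}", locus_tag=f"b{i+1:04d}",
                                product=f"synthetic protein {i+1}")
                )
                break
        else:
            raise SimulationError(f"cannot place gene {i+1} without overlap")

    genome = GenomeRecord(
        id="ancestor",
        sequence=seq.tobytes().decode(),
        circular=True,
        description="synthetic ancestor circular=true",
    )
    features.sort(key=lambda f: (f.start, f.end))
    return genome, features


# ---------------------------------------------------------------------------
# Lineage evolution
# ---------------------------------------------------------------------------


@dataclass
class _Landmark:
    start: int
    end: int
    alive: bool = True


class _Lineage:
    """Mutable evolving genome plus all coordinate bookkeeping."""

    def __init__(self, ancestor: GenomeRecord, features: list[GeneFeature],
                 params: EvolutionParams, strain: str):
        self.params = params
        self.ancestor = ancestor
        self.seq = ancestor.sequence
        self.amap = np.arange(len(self.seq), dtype=np.int64)
        self.events: list[AppliedEvent] = []
        self.strain = strain
        self.prophage: _Landmark | None = None
        self.repeat_pairs: list[tuple[_Landmark, _Landmark, int]] = []
        for f in features:
            if f.kind == "prophage":
                self.prophage = _Landmark(f.start, f.end)
            if f.kind == "other" and f.product.startswith("repeat_pair"):
                info = dict(kv.split("=") for kv in f.product.split()[1:])
                m, ls, rs = int(info["len"]), int(info["left"]), int(info["right"])
                self.repeat_pairs.append(
                    (_Landmark(ls, ls + m), _Landmark(rs, rs + m), m)
                )

    # -- coordinate bookkeeping -------------------------------------------

    def _shift(self, p: int, d: int, i: int) -> None:
        """Propagate an edit (remove d bases at p, insert i) to stored coords."""
        delta = i - d
        for ev in self.events:
            if ev.erased:
                continue
            if ev.protect_start >= p + d:
                ev.protect_start += delta
                ev.protect_end += delta
                ev.evolved_start += delta
                ev.evolved_end += delta
            elif d and ev.protect_start >= p and ev.protect_end <= p + d:
                ev.erased = True
        for lm in self._landmarks():
            if not lm.alive:
                continue
            if lm.start >= p + d:
                lm.start += delta
                lm.end += delta
            elif d and lm.start >= p and lm.end <= p + d:
                lm.alive = False
            elif d and not (lm.end <= p or lm.start >= p + d):
                lm.alive = False  # partially clipped landmark is unusable

    def _landmarks(self):
        if self.prophage is not None:
            yield self.prophage
        for left, right, _m in self.repeat_pairs:
            yield left
            yield right

    # margin keeping new events a few bases clear of existing footprints, so
    # adjacent edits cannot collapse into an ambiguous combined representation
    _MARGIN = 3

    def _conflicts(self, s: int, e: int, allow_contained: bool) -> bool:
        """True if [s, e) (plus a small margin) clashes with an existing footprint."""
        s0, e0 = s, e
        s, e = s - self._MARGIN, e + self._MARGIN
        for ev in self.events:
            if ev.erased:
                continue
            if ev.protect_end <= s or ev.protect_start >= e:
                continue
            if allow_contained and s0 <= ev.protect_start and ev.protect_end <= e0:
                continue  # will be erased by the deletion
            return True
        return False

    def _anc_interval(self, p: int, d: int) -> tuple[int, int]:
        if d == 0:
            # insertion point: first ancestral base at or right of p
            q = p
            while q < len(self.amap) and self.amap[q] < 0:
                q += 1
            a = int(self.amap[q]) if q < len(self.amap) else len(self.ancestor.sequence)
            return a, a
        window = self.amap[p : p + d]
        anc = window[window >= 0]
        if len(anc) == 0:
            return -1, -1
        return int(anc.min()), int(anc.max()) + 1

    def _apply(self, event_class: str, day: float, p: int, removed_len: int,
               inserted: str, protect: tuple[int, int], mh: int = 0,
               tsd: str = "") -> AppliedEvent:
        removed = self.seq[p : p + removed_len]
        a0, a1 = self._anc_interval(p, removed_len)
        ev = AppliedEvent(
            event_class=event_class, day_applied=day, apply_pos=p,
            removed=removed, inserted=inserted,
            ancestor_start=a0, ancestor_end=a1,
            evolved_start=p, evolved_end=p + len(inserted),
            protect_start=protect[0],
            protect_end=protect[0] + (protect[1] - protect[0]) - removed_len + len(inserted),
            planted_microhomology_length=mh, planted_tsd=tsd,
        )
        self._shift(p, removed_len, len(inserted))
        self.seq = self.seq[:p] + inserted + self.seq[p + removed_len :]
        ins_map = np.full(len(inserted), -1, dtype=np.int64)
        self.amap = np.concatenate([self.amap[:p], ins_map, self.amap[p + removed_len :]])
        self.events.append(ev)
        return ev

    # -- event constructors ------------------------------------------------

    def _try_snp(self, rng: np.random.Generator, day: float) -> bool:
        classes = list(self.params.spectrum_weights)
        weights = np.array([self.params.spectrum_weights[c] for c in classes])
        cls = classes[int(rng.choice(len(classes), p=weights))]
        pyr_ref, pyr_alt = cls[0], cls[4]
        if rng.random() < 0.5:
            ref, alt = pyr_ref, pyr_alt
        else:
            ref, alt = COMPLEMENT[pyr_ref], COMPLEMENT[pyr_alt]
        for _ in range(200):
            p = int(rng.integers(0, len(self.seq)))
            if self.seq[p] != ref or self._conflicts(p, p + 1, False):
                continue
            self._apply("snp", day, p, 1, alt, (p, p + 1))
            return True
        return False

    def _try_indel(self, rng: np.random.Generator, day: float) -> bool:
        length = int(rng.geometric(self.params.indel_length_geometric_p))
        is_insertion = rng.random() < 0.5
        for _ in range(200):
            p = int(rng.integers(1, len(self.seq) - length - 1))
            if is_insertion:
                if self._conflicts(p, p + 1, False):
                    continue
                if rng.random() < 0.5:  # tandem duplication (homopolymer-run growth)
                    ins = self.seq[p : p + length]
                else:
                    ins = "".join(rng.choice(list(_BASES), size=length))
                self._apply("small_indel", day, p, 0, ins, (p, p))
            else:
                if self._conflicts(p, p + length, False):
                    continue
                self._apply("small_indel", day, p, length, "", (p, p + length))
            return True
        return False

    def _try_is_insertion(self, rng: np.random.Generator, day: float) -> bool:
        t = self.params.tsd_length
        pwm = self.params.target_pwm
        enc = np.frombuffer(self.seq.encode(), dtype=np.uint8)
        code = np.full(256, -1, dtype=np.int64)
        for i, b in enumerate(_BASES):
            code[ord(b)] = i
        idx = code[enc]
        n_sites = len(self.seq) - t
        score = np.ones(n_sites)
        for j in range(t):
            col = idx[j : j + n_sites]
            score *= np.where(col >= 0, pwm[j][np.clip(col, 0, 3)], 0.0)
        total = score.sum()
        if total <= 0:
            return False
        prob = score / total
        for _ in range(200):
            p = int(rng.choice(n_sites, p=prob))
            if self._conflicts(p, p + t, False):
                continue
            target = self.seq[p : p + t]
            if "N" in target:
                continue
            element = self.params.is_sequence
            if rng.random() < 0.5:
                element = _revcomp(element)
            self._apply("is_insertion", day, p + t, 0, element + target,
                        (p, p + t), tsd=target)
            return True
        return False

    def _try_large_deletion(self, rng: np.random.Generator, day: float) -> bool:
        live = [(l, r, m) for l, r, m in self.repeat_pairs if l.alive and r.alive]
        if live:
            order = rng.permutation(len(live))
            for i in order:
                left, right, m = live[int(i)]
                s, e = left.start, right.start
                if self._conflicts(s, e, True):
                    continue
                self._apply("large_deletion", day, s, e - s, "", (s, e), mh=m)
                left.alive = right.alive = False
                return True
        # blunt fallback: random interval, no planted homology
        for _ in range(200):
            size = int(np.clip(rng.lognormal(self.params.deletion_size_log_mean,
                                             self.params.deletion_size_log_sd),
                               200, len(self.seq) // 4))
            if size >= len(self.seq) - 2:
                continue
            s = int(rng.integers(0, len(self.seq) - size))
            if self._conflicts(s, s + size, True):
                continue
            self._apply("large_deletion", day, s, size, "", (s, s + size))
            return True
        return False

    def _try_excision(self, rng: np.random.Generator, day: float) -> bool:
        pp = self.prophage
        if pp is None or not pp.alive:
            return False
        s, e = pp.start, pp.end
        if self._conflicts(s, e, True):
            return False
        self._apply("element_excision", day, s, e - s, "", (s, e))
        pp.alive = False
        return True

    # -- main loop ---------------------------------------------------------

    def run(self, rng: np.random.Generator, day_offset: float, days: float) -> None:
        n_events = int(rng.poisson(self.params.change_rate * days))
        times = np.sort(rng.uniform(day_offset, day_offset + days, size=n_events))
        classes = list(self.params.p_event_class)
        weights = np.array([self.params.p_event_class[c] for c in classes])
        makers = {
            "snp": self._try_snp,
            "small_indel": self._try_indel,
            "is_insertion": self._try_is_insertion,
            "large_deletion": self._try_large_deletion,
            "element_excision": self._try_excision,
        }
        for day in times:
            placed = False
            for _attempt in range(60):
                cls = classes[int(rng.choice(len(classes), p=weights))]
                if makers[cls](rng, float(day)):
                    placed = True
                    break
            if not placed:
                raise SimulationError(f"could not place any event on day {day:.1f}")

    def to_genome(self, strain: str) -> GenomeRecord:
        return GenomeRecord(id=strain, sequence=self.seq,
                            circular=self.ancestor.circular,
                            description=f"evolved from {self.ancestor.id}")


def evolve_lineage(
    ancestor: GenomeRecord,
    features: list[GeneFeature],
    params: EvolutionParams,
    days: float,
    seed: int,
    strain: str = "evolved",
) -> tuple[GenomeRecord, EvolutionGroundTruth]:
    """Evolve one lineage for ``days`` days under the serial-passage model.

    The number of events is Poisson(change_rate x days); events are
    timestamped uniformly and applied chronologically with full coordinate
    bookkeeping.  Events landing across the footprint of a prior event are
    resampled (deletions may wholly swallow earlier events, which are then
    flagged ``erased``).
    """
    if days < 0:
        raise ValueError("days must be >= 0")
    lin = _Lineage(ancestor, features, params, strain)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    lin.run(rng, 0.0, days)
    truth = EvolutionGroundTruth(strain=strain, ancestor_id=ancestor.id, events=lin.events)
    return lin.to_genome(strain), truth


def simulate_sibling_pair(
    params: EvolutionParams,
    ancestor: GenomeRecord | None = None,
    features: list[GeneFeature] | None = None,
) -> tuple[GenomeRecord, GenomeRecord, EvolutionGroundTruth, EvolutionGroundTruth]:
    """Simulate two isolates sharing a lineage that splits at divergence_day.

    Events applied before the split are present in both ledgers with
    ``shared=True``; the two continuations use independent child seeds
    derived deterministically from ``params.seed``.
    """
    if ancestor is None or features is None:
        ancestor, features = generate_ancestor(params)
    ss = np.random.SeedSequence([params.seed, 2])
    seed_shared, seed_a, seed_b = ss.spawn(3)

    shared = _Lineage(ancestor, features, params, "shared")
    shared.run(np.random.default_rng(seed_shared), 0.0, params.divergence_day)
    for ev in shared.events:
        ev.shared = True

    remaining = params.days_total - params.divergence_day
    lin_a = copy.deepcopy(shared)
    lin_b = copy.deepcopy(shared)
    lin_a.strain, lin_b.strain = "strainA", "strainB"
    lin_a.run(np.random.default_rng(seed_a), params.divergence_day, remaining)
    lin_b.run(np.random.default_rng(seed_b), params.divergence_day, remaining)

    truth_a = EvolutionGroundTruth("strainA", ancestor.id, lin_a.events)
    truth_b = EvolutionGroundTruth("strainB", ancestor.id, lin_b.events)
    return lin_a.to_genome("strainA"), lin_b.to_genome("strainB"), truth_a, truth_b


# ---------------------------------------------------------------------------
# Ledger output
# ---------------------------------------------------------------------------

_LEDGER_COLUMNS = [
    "strain", "event_class", "day_applied", "ancestor_start", "ancestor_end",
    "evolved_start", "evolved_end", "removed_len", "inserted_len",
    "planted_microhomology_length", "planted_tsd", "shared", "erased",
]


def write_ledger(truth: EvolutionGroundTruth, path) -> None:
    """Write the ground-truth ledger as TSV (1-based inclusive intervals)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_LEDGER_COLUMNS) + "\n")
        for ev in truth.events:
            fh.write("\t".join(map(str, [
                truth.strain, ev.event_class, f"{ev.day_applied:.3f}",
                ev.ancestor_start + 1, ev.ancestor_end,
                ev.evolved_start + 1, ev.evolved_end,
                len(ev.removed), len(ev.inserted),
                ev.planted_microhomology_length, ev.planted_tsd,
                int(ev.shared), int(ev.erased),
            ])) + "\n")
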