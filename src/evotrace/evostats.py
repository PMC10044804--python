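"""Whole-experiment evolution statistics.

Covers the numerical summaries of a serial-passage evolution experiment:
pyrimidine-collapsed mutational spectra, per-day change rates with exact
Poisson (Garwood) confidence intervals, the expected spontaneous load
under serial dilution, the hyper-mutagenesis factor (observed over
expected rate), sibling divergence dating from strain-specific change
counts, and enrichment of low-melting-temperature proteins among
knocked-out genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from evotrace.io import GenomeRecord, TmRecord, Variant

#: The six strand-collapsed substitution classes, keyed to the pyrimidine
#: of the reference base pair (C:G>T:A combines C>T and G>A).
SNP_CLASSES = (
    "C:G>T:A",
    "C:G>A:T",
    "C:G>G:C",
    "T:A>C:G",
    "T:A>A:T",
    "T:A>G:C",
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def collapse_snp(ref: str, alt: str) -> str:
    """Map a directional substitution to its pyrimidine-collapsed class."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"not a substitution: {ref}->{alt}")
    if ref in "AG":  # purine reference: read the complementary strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}:{COMPLEMENT[ref]}>{alt}:{COMPLEMENT[alt]}"


@dataclass
class SpectrumResult:
    counts: dict
    fractions: dict
    n_snps: int


@dataclass
class RateEstimate:
    n_changes: int
    days: float
    rate: float
    ci95: tuple


@dataclass
class LoadExpectation:
    doublings_per_day: float
    mu_per_bp_per_generation: float
    genome_length: int
    per_genome_per_generation: float
    expected_per_day: float


@dataclass
class DivergenceEstimate:
    strain: str
    n_specific: int
    rate: float
    days: float
    days_rounded: int
    ci95: tuple


@dataclass
class TmEnrichmentResult:
    t_max: float
    delta: float
    threshold: float
    n_low: int
    n_detected: int
    proportion: float
    background_proportion: float
    p_value: float
    undefined: bool = False


def spectrum(snps: list[Variant], reference: GenomeRecord | None = None) -> SpectrumResult:
    """Pyrimidine-collapsed spectrum over a set of SNP variants.

    Every SNP is mapped to one of the six classes of :data:`SNP_CLASSES`;
    a G>A change counts as C>T on the complementary strand, and so on.
    ``reference`` is accepted for interface symmetry (alleles already carry
    the strand information needed).
    """
    counts = {c: 0 for c in SNP_CLASSES}
    for v in snps:
        if v.event_class != "snp":
            raise ValueError(f"non-SNP variant in spectrum input: {v.event_class}")
        counts[collapse_snp(v.ref_allele, v.alt_allele)] += 1
    n = len(snps)
    fractions = {c: (counts[c] / n if n else 0.0) for c in SNP_CLASSES}
    return SpectrumResult(counts=counts, fractions=fractions, n_snps=n)


def poisson_ci(n: int, conf: float = 0.95) -> tuple:
    """Exact (Garwood) confidence interval for a Poisson count."""
    alpha = 1.0 - conf
    lo = 0.0 if n == 0 else stats.chi2.ppf(alpha / 2, 2 * n) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (n + 1)) / 2
    return (lo, hi)


def rate_per_day(n_changes: int, days: float) -> RateEstimate:
    """Per-day change rate with an exact Poisson 95% CI."""
    if days <= 0:
        raise ValueError("days must be > 0")
    if n_changes < 0:
        raise ValueError("n_changes must be >= 0")
    lo, hi = poisson_ci(n_changes)
    return RateEstimate(
        n_changes=n_changes,
        days=days,
        rate=n_changes / days,
        ci95=(lo / days, hi / days),
    )


def doublings_from_dilution(dilution_factor: float, interval_days: float) -> float:
    """Doublings per day implied by regrowth after an x-fold dilution.

    A culture diluted 1:8 every 48 h must double log2(8) = 3 times per
    transfer to return to the same density, i.e. 1.5 doublings per day.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if interval_days <= 0:
        raise ValueError("interval_days must be > 0")
    return math.log2(dilution_factor) / interval_days


def expected_load(
    doublings_per_day: float,
    mu_per_bp_per_generation: float,
    genome_length: int,
) -> LoadExpectation:
    """Expected spontaneous changes per day from the per-bp mutation rate."""
    if min(doublings_per_day, mu_per_bp_per_generation, genome_length) < 0:
        raise ValueError("inputs must be >= 0")
    per_genome = mu_per_bp_per_generation * genome_length
    return LoadExpectation(
        doublings_per_day=doublings_per_day,
        mu_per_bp_per_generation=mu_per_bp_per_generation,
        genome_length=genome_length,
        per_genome_per_generation=per_genome,
        expected_per_day=per_genome * doublings_per_day,
    )


def hyper_factor(observed_rate: float, expected_rate: float) -> float:
    """Fold elevation of the observed change rate over the spontaneous expectation."""
    if expected_rate <= 0:
        raise ValueError("expected_rate must be > 0")
    return observed_rate / expected_rate


def divergence_days(n_specific: int, rate_estimate: RateEstimate,
                    strain: str = "") -> DivergenceEstimate:
    """Date the split of sibling lineages from strain-specific change counts.

    ``days = n_specific / rate`` with the *unrounded* rate; the Poisson CI
    on the strain-specific count is propagated through the division.
    """
    rate = rate_estimate.rate
    if rate <= 0:
        raise ValueError("rate must be > 0")
    lo, hi = poisson_ci(n_specific)
    days = n_specific / rate
    return DivergenceEstimate(
        strain=strain,
        n_specific=n_specific,
        rate=rate,
        days=days,
        days_rounded=round(days),
        ci95=(lo / rate, hi / rate),
    )


def tm_enrichment(
    knockout_locus_tags: set,
    tm_table: list[TmRecord],
    t_max: float,
    background_proportion: float,
    delta: float = 5.0,
) -> TmEnrichmentResult:
    """Proportion of knocked-out genes encoding low-melting proteins.

    Restricts the knockout set to genes present in the melting-temperature
    table, counts those with Tm <= t_max + delta, and runs an exact
    two-sided binomial test against the genome-wide background proportion.
    """
    if not tm_table:
        raise ValueError("tm_table must be nonempty")
    if not 0 <= background_proportion <= 1:
        raise ValueError("background_proportion must be in [0, 1]")
    threshold = t_max + delta
    tm_by_tag = {r.locus_tag: r.tm for r in tm_table}
    detected = [tag for tag in knockout_locus_tags if tag in tm_by_tag]
    n_detected = len(detected)
    if n_detected == 0:
        return TmEnrichmentResult(
            t_max=t_max, delta=delta, threshold=threshold, n_low=0, n_detected=0,
            proportion=float("nan"), background_proportion=background_proportion,
            p_value=float("nan"), undefined=True,
        )
    n_low = sum(1 for tag in detected if tm_by_tag[tag] <= threshold)
    test = stats.binomtest(n_low, n_detected, background_proportion,
                           alternative="two-sided")
    return TmEnrichmentResult(
        t_max=t_max, delta=delta, threshold=threshold,
        n_low=n_low, n_detected=n_detected,
        proportion=n_low / n_detected,
        background_proportion=background_proportion,
        p_value=test.pvalue,
    )
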