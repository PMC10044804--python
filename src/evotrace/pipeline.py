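"""End-to-end pipeline orchestration from a single configuration.

Runs the stages in the order of a comparative-genomics study of serially
passaged isolates: anchored genome comparison, structural junction
characterization, IS scanning with TSD consensus, consequence annotation
and knockout calling, evolution statistics, and melting-temperature
enrichment.  Every stage consumes only files produced by earlier stages or
named in the configuration; a fixed seed makes reruns byte-identical.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import evotrace
from evotrace import io as eio
from evotrace import diffcall, effects, evostats, junctions, mobilome, simulate

_PARAM_DEFAULTS = {
    "k": 21,
    "max_gap": 5000,
    "large_threshold": 50,
    "tsd_length": 9,
    "loss_threshold": 0.10,
    "upstream_window": 50,
    "days": 2512.0,
    "dilution_factor": 8.0,
    "transfer_interval": 2.0,
    "mu": 1.0e-9,
    "t_max": 48.5,
    "delta": 5.0,
    "tm_background": 0.219,
    "consensus_threshold": 0.25,
    "min_identity": 0.95,
    "min_coverage": 0.90,
    "max_cargo": 15000,
}

_TOP_KEYS = {
    "reference", "queries", "features", "is_references", "tm_table",
    "gene_lists", "output_dir", "seed", "params",
}


class ConfigError(ValueError):
    """Raised for unknown keys, missing paths or out-of-domain parameters."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (flat key-value file, one params section)."""

    reference: Path
    queries: list
    features: Path
    output_dir: Path
    is_references: list = field(default_factory=list)
    tm_table: Path | None = None
    gene_lists: dict = field(default_factory=dict)
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        for req in ("reference", "queries", "features", "output_dir"):
            if req not in raw:
                raise ConfigError(f"missing required key {req!r}")
        params = dict(_PARAM_DEFAULTS)
        extra = set(raw.get("params", {})) - set(_PARAM_DEFAULTS)
        if extra:
            raise ConfigError(f"unknown parameter keys: {sorted(extra)}")
        params.update(raw.get("params", {}))
        cfg = cls(
            reference=Path(raw["reference"]),
            queries=[Path(p) for p in raw["queries"]],
            features=Path(raw["features"]),
            output_dir=Path(raw["output_dir"]),
            is_references=[Path(p) for p in raw.get("is_references", [])],
            tm_table=Path(raw["tm_table"]) if raw.get("tm_table") else None,
            gene_lists={k: Path(v) for k, v in (raw.get("gene_lists") or {}).items()},
            seed=int(raw.get("seed", 0)),
            params=params,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.reference, self.features, *self.queries,
                 *self.is_references, *self.gene_lists.values()]
        if self.tm_table:
            paths.append(self.tm_table)
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        pr = self.params
        if not 0 < pr["loss_threshold"] < 1:
            raise ConfigError("loss_threshold must be in (0, 1)")
        if pr["k"] < 5:
            raise ConfigError("k must be >= 5")
        if pr["dilution_factor"] < 1:
            raise ConfigError("dilution_factor must be >= 1")


def _config_hash(config: RunConfig) -> str:
    text = repr(
        (str(config.reference), [str(q) for q in config.queries],
         str(config.features), sorted(config.params.items()), config.seed)
    )
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write per-stage TSVs plus a summary.

    Returns a dictionary of the headline numbers (counts, rates, divergence
    estimates, enrichment) so callers can assert on them directly.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pr = config.params
    log: list[str] = [
        f"evotrace {evotrace.__version__}",
        f"config_hash {_config_hash(config)}",
        f"seed {config.seed}",
    ]
    log.extend(f"param {k} = {v}" for k, v in sorted(pr.items()))

    stage = "load inputs"
    try:
        reference = eio.read_genome(config.reference)[0]
        features = eio.read_features(config.features, [reference])
        queries = [eio.read_genome(q)[0] for q in config.queries]
        is_refs = [eio.read_genome(p)[0] for p in config.is_references]

        results: dict = {"strains": {}}
        per_strain_variants = {}
        for query in queries:
            stage = f"diff {query.id}"
            diff = diffcall.align_genomes(
                reference, query, k=pr["k"], max_gap=pr["max_gap"],
                large_threshold=pr["large_threshold"],
            )
            variants = mobilome.reclassify_is_insertions(diff.variants, is_refs)
            for v in variants:
                v.strain = query.id
            eio.write_variants(variants, out / f"{query.id}.variants.tsv")
            with open(out / f"{query.id}.unresolved.bed", "w") as fh:
                for u in diff.unresolved:
                    fh.write(f"{u.seq_id}\t{u.start}\t{u.end}\t{u.reason}\n")
            per_strain_variants[query.id] = variants

            stage = f"junctions {query.id}"
            junction_rows = []
            large = [v for v in variants if v.event_class == "large_deletion"]
            scan_copies = []
            for ref_is in is_refs:
                scan_copies.extend(mobilome.find_is_copies(
                    reference, ref_is, min_identity=pr["min_identity"],
                    min_coverage=pr["min_coverage"]))
            fusions = []
            for v in large:
                dj = junctions.characterize_deletion(reference, v.pos,
                                                     v.pos + len(v.ref_allele))
                junctions.classify_deletion(dj, features, scan_copies)
                fusion = junctions.detect_fusion(features, dj, reference)
                if fusion is not None and fusion.in_frame:
                    fusions.append(fusion)
                junction_rows.append(dj)
            with open(out / f"{query.id}.junctions.tsv", "w") as fh:
                fh.write("seq_id\tdel_start\tdel_end\tmh_length\tmh_sequence\t"
                         "category\tfusion\n")
                for dj in junction_rows:
                    fus = next(
                        (f"{f.gene5.gene}-{f.gene3.gene} "
                         f"{f.retained5[0]}-{f.retained5[1]}/"
                         f"{f.retained3[0]}-{f.retained3[1]}"
                         for f in fusions
                         if f.gene5.start <= dj.del_end and f.gene3.end >= dj.del_start),
                        "",
                    )
                    fh.write(f"{dj.seq_id}\t{dj.del_start + 1}\t{dj.del_end}\t"
                             f"{dj.mh_length}\t{dj.mh_sequence}\t{dj.category}\t{fus}\n")

            stage = f"is-scan {query.id}"
            copies = []
            for ref_is in is_refs:
                copies.extend(mobilome.find_is_copies(
                    query, ref_is, min_identity=pr["min_identity"],
                    min_coverage=pr["min_coverage"]))
            mobilome.flag_composite(copies, None, max_cargo=pr["max_cargo"])
            for c in copies:
                mobilome.extract_tsd(query, c, tsd_length=pr["tsd_length"])
            sites = [c.target_site for c in copies
                     if not c.in_composite and c.tsd_match]
            consensus = (mobilome.build_consensus(sites, pr["consensus_threshold"])
                         if sites else None)
            with open(out / f"{query.id}.iscopies.tsv", "w") as fh:
                fh.write("family\tstart\tend\tstrand\tidentity\tcoverage\t"
                         "tsd_left\ttsd_right\ttsd_match\tin_composite\n")
                for c in copies:
                    fh.write(f"{c.family}\t{c.start + 1}\t{c.end}\t{c.strand}\t"
                             f"{c.identity:.4f}\t{c.coverage:.4f}\t{c.tsd_left}\t"
                             f"{c.tsd_right}\t{int(c.tsd_match)}\t{int(c.in_composite)}\n")
            if consensus is not None:
                with open(out / f"{query.id}.target_consensus.txt", "w") as fh:
                    fh.write(consensus.iupac + "\n")

            stage = f"annotate {query.id}"
            calls = effects.annotate_all(variants, features, reference,
                                         upstream_window=pr["upstream_window"])
            knockouts = effects.call_knockouts(calls, large, features,
                                               loss_threshold=pr["loss_threshold"])
            with open(out / f"{query.id}.calls.tsv", "w") as fh:
                fh.write("pos\tevent_class\tgene\teffect\tcodon_affected\t"
                         "total_codons\tfraction_lost\tknockout\tsubstitution\n")
                for c in calls:
                    fh.write(f"{c.variant.pos + 1}\t{c.variant.event_class}\t"
                             f"{c.gene or '.'}\t{c.effect}\t{c.codon_affected}\t"
                             f"{c.total_codons}\t{c.fraction_lost:.3f}\t"
                             f"{int(c.knockout)}\t{c.substitution}\n")
            (out / f"{query.id}.knockouts.txt").write_text(
                "".join(tag + "\n" for tag in sorted(knockouts)))

            stage = f"stats {query.id}"
            n_changes = diffcall.count_changes(variants)
            rate = evostats.rate_per_day(n_changes, pr["days"])
            snps = [v for v in variants if v.event_class == "snp"]
            spec = evostats.spectrum(snps, reference)
            gene_lists = {
                label: [line.strip() for line in open(p) if line.strip()]
                for label, p in config.gene_lists.items()
            }
            crossref = effects.crossref_gene_sets(calls, gene_lists) if gene_lists else None

            strain_res = {
                "n_changes": n_changes,
                "rate_per_day": rate.rate,
                "rate_ci95": rate.ci95,
                "n_snps": spec.n_snps,
                "spectrum_fractions": spec.fractions,
                "n_large_deletions": len(large),
                "n_is_copies": len(copies),
                "n_isolated_is": sum(1 for c in copies if not c.in_composite),
                "target_consensus": consensus.iupac if consensus else "",
                "n_knockouts": len(knockouts),
                "knockouts": knockouts,
                "fusions": fusions,
                "unresolved": len(diff.unresolved),
            }
            if crossref is not None:
                strain_res["crossref"] = crossref.summary
            if config.tm_table:
                tm = eio.read_tm_table(config.tm_table)
                enr = evostats.tm_enrichment(
                    knockouts, tm, pr["t_max"], pr["tm_background"], pr["delta"])
                strain_res["tm_enrichment"] = enr
            results["strains"][query.id] = strain_res
            log.append(f"stage {query.id}: {n_changes} changes, "
                       f"{len(large)} large deletions, {len(copies)} IS copies, "
                       f"{len(knockouts)} knockouts")

        if len(queries) == 2:
            stage = "divergence"
            a, b = queries[0].id, queries[1].id
            comparison = diffcall.compare_variant_sets(
                per_strain_variants[a], per_strain_variants[b])
            div = {}
            for name, specific in ((a, comparison.a_only), (b, comparison.b_only)):
                rate = evostats.rate_per_day(
                    results["strains"][name]["n_changes"], pr["days"])
                div[name] = evostats.divergence_days(len(specific), rate, strain=name)
            results["comparison"] = {
                "shared": len(comparison.shared),
                f"{a}_specific": len(comparison.a_only),
                f"{b}_specific": len(comparison.b_only),
                "divergence": div,
            }
            log.append(
                f"stage divergence: {len(comparison.shared)} shared, "
                + ", ".join(f"{n}: {d.days_rounded} d" for n, d in div.items())
            )

        stage = "load expectation"
        doublings = evostats.doublings_from_dilution(
            pr["dilution_factor"], pr["transfer_interval"])
        load = evostats.expected_load(doublings, pr["mu"], len(reference))
        results["doublings_per_day"] = doublings
        results["expected_load_per_day"] = load.expected_per_day
        for name, res in results["strains"].items():
            res["hyper_factor"] = evostats.hyper_factor(
                res["rate_per_day"], load.expected_per_day)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = out / "summary.txt"
    with open(summary, "w") as fh:
        fh.write("\n".join(log) + "\n")
        fh.write(f"doublings_per_day {doublings:g}\n")
        fh.write(f"expected_load_per_day {load.expected_per_day:.4g}\n")
        for name, res in results["strains"].items():
            fh.write(f"strain {name}: rate {res['rate_per_day']:.4f}/day, "
                     f"hyper-factor {res['hyper_factor']:.1f}, "
                     f"C:G>T:A {res['spectrum_fractions']['C:G>T:A']:.3f}\n")
        if "comparison" in results:
            for name, d in results["comparison"]["divergence"].items():
                fh.write(f"divergence {name}: {d.days_rounded} days "
                         f"(95% CI {d.ci95[0]:.0f}-{d.ci95[1]:.0f})\n")
    return results


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

TINY_PARAM_OVERRIDES = dict(
    genome_length=30_000,
    n_genes=18,
    gene_length_mean=600,
    days_total=250.0,
    divergence_day=150.0,
    n_repeat_pairs=4,
    prophage_length=2_500,
    cargo_length=1_200,
    deletion_size_log_mean=math.log(800.0),
    deletion_size_log_sd=0.5,
)


def fixture_params(scale: str, seed: int) -> simulate.EvolutionParams:
    """Simulation parameters for the two supported fixture scales.

    ``paper-like`` keeps the study-condition defaults (0.092 changes/day
    over 2,512 days, split at day 2,112, spectrum weight 0.65 on C:G->T:A,
    9-bp TSDs); ``tiny`` shrinks the genome and timeline so a full
    simulate-diff-annotate round trip runs in well under a second.
    """
    if scale == "paper-like":
        return simulate.EvolutionParams(seed=seed)
    if scale == "tiny":
        return simulate.EvolutionParams(seed=seed, **TINY_PARAM_OVERRIDES)
    raise ValueError(f"unknown scale {scale!r} (use 'tiny' or 'paper-like')")


def make_fixtures(seed: int, scale: str, out_dir) -> dict:
    """Write a self-contained simulated bundle used by the test suite.

    Contains the ancestor (FASTA + GFF3), two sibling isolates, both truth
    ledgers, the truth projected into the variant-table dialect, the IS
    reference element, a melting-temperature table with a known low-Tm
    fraction, and an `essential`-style gene list.
    """
    import numpy as np

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = fixture_params(scale, seed)
    ancestor, features = simulate.generate_ancestor(params)
    ga, gb, ta, tb = simulate.simulate_sibling_pair(params, ancestor, features)

    paths = {
        "ancestor": out / "ancestor.fasta",
        "features": out / "ancestor.gff3",
        "strainA": out / "strainA.fasta",
        "strainB": out / "strainB.fasta",
        "truthA": out / "truthA.ledger.tsv",
        "truthB": out / "truthB.ledger.tsv",
        "variantsA": out / "strainA.truth_variants.tsv",
        "variantsB": out / "strainB.truth_variants.tsv",
        "is_reference": out / "is_element.fasta",
        "tm_table": out / "tm_table.tsv",
        "essential": out / "essential.txt",
    }
    eio.write_genome([ancestor], paths["ancestor"])
    eio.write_features(features, paths["features"])
    eio.write_genome([ga], paths["strainA"])
    eio.write_genome([gb], paths["strainB"])
    simulate.write_ledger(ta, paths["truthA"])
    simulate.write_ledger(tb, paths["truthB"])
    eio.write_variants(ta.to_variants(ancestor), paths["variantsA"])
    eio.write_variants(tb.to_variants(ancestor), paths["variantsB"])
    eio.write_genome(
        [eio.GenomeRecord(id="ISsyn1", sequence=params.is_sequence,
                          description="synthetic IS element")],
        paths["is_reference"],
    )

    # Tm table: a known fraction of proteins melt within 5 C of t_max=48.5
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    low_fraction = 0.219
    tms = []
    cds = [f for f in features if f.kind == "CDS"]
    for f in cds:
        if rng.random() < low_fraction:
            tm = rng.uniform(45.0, 53.5)
        else:
            tm = rng.uniform(53.6, 75.0)
        tms.append(eio.TmRecord(locus_tag=f.locus_tag, tm=round(tm, 1)))
    eio.write_tm_table(tms, paths["tm_table"])

    chosen = rng.choice(len(cds), size=max(3, len(cds) // 6), replace=False)
    paths["essential"].write_text(
        "".join(cds[i].locus_tag + "\n" for i in sorted(chosen)))
    return paths
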