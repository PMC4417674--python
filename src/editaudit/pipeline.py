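"""Scenario loading and the end-to-end runner.

A cohort scenario YAML describes a whole simulated experiment: the
locus/donor geometry, per-embryo read mixtures (as integer clone counts,
realized exactly), paralog-locus amplification outcomes, and an optional
exome plant specification.  :func:`run_all` executes simulate ->
classify -> summarize -> pathway -> off-target screen and writes every
table plus a markdown report under one output directory.

Seeds: every generator seed is derived from ``(run_seed, file seed,
index)`` through :func:`derive_seed`, so one integer reproduces the
whole run byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .errors import ConfigError
from .offtarget import GuideRule, run_chain, trace_table
from .outcomes import (
    CallParams,
    classify_reads,
    indel_spectrum,
    summarize_embryo,
    summarize_experiment,
)
from .pathway import assess_crossover, pathway_report
from .synthetic import (
    HDR_PARTIAL,
    DEFAULT_PROTOSPACER,
    EmbryoScenario,
    GuideSpec,
    generate_donor,
    generate_exome_variants,
    generate_locus_pair,
    simulate_embryo_reads,
    simulate_paralog_reads,
    truth_table,
)

logger = logging.getLogger("editaudit")


def derive_seed(*parts: int) -> int:
    """Mix integer parts into one sub-2^31 seed, deterministically."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def packaged_scenario(name: str) -> dict:
    """Load one of the scenario files shipped with the package."""
    ref = resources.files("editaudit").joinpath(f"scenarios/{name}.yaml")
    with resources.as_file(ref) as path:
        return eio.load_yaml(path)


@dataclass
class Cohort:
    """A fully built simulation scenario, ready to run."""

    name: str
    locus: object
    donor: object
    embryos: list[EmbryoScenario]
    paralog_specs: list[dict] = field(default_factory=list)
    exome_plant: dict | None = None
    guide_rule: GuideRule | None = None
    call_params: CallParams = field(default_factory=CallParams)


def build_cohort(config: dict, run_seed: int = 0) -> Cohort:
    """Expand a scenario mapping into locus, donor and embryo recipes.

    Embryo group mixtures are given as integer clone counts per
    category; they are normalized to proportions whose largest-remainder
    realization over ``n_reads`` returns exactly those counts.
    """
    name = config.get("name", "cohort")
    lp = dict(config.get("locus", {}))
    guide = GuideSpec(protospacer=lp.pop("protospacer", DEFAULT_PROTOSPACER),
                      strand=lp.pop("strand", "+"))
    locus_seed = derive_seed(run_seed, int(lp.pop("seed", 0)))
    locus = generate_locus_pair(
        length=int(lp.pop("length", 400)),
        n_discriminating=int(lp.pop("n_discriminating", 4)),
        guide_spec=guide, seed=locus_seed, **lp,
    )
    dp = dict(config.get("donor", {}))
    donor_seed = derive_seed(run_seed, int(dp.pop("seed", 1)))
    donor = generate_donor(locus, n_signatures=int(dp.pop("n_signatures", 6)),
                           arm_length=int(dp.pop("arm_length", 63)),
                           seed=donor_seed, **dp)

    embryos: list[EmbryoScenario] = []
    idx = 0
    for group in config.get("embryos", []):
        count = int(group.get("count", 1))
        prefix = group.get("prefix", "embryo")
        n_reads = int(group.get("n_reads", 50))
        amplified = bool(group.get("amplified", True))
        mixture_counts = {str(k): float(v) for k, v in group.get("mixture", {"WT": 1}).items()}
        total = sum(mixture_counts.values())
        if total <= 0:
            raise ConfigError(f"group {prefix}: mixture weights must be positive")
        mixture = {k: v / total for k, v in mixture_counts.items()}
        for j in range(count):
            embryos.append(EmbryoScenario(
                embryo_id=f"{prefix}{j + 1:02d}",
                mixture=mixture,
                n_reads=n_reads,
                partial_k=int(group.get("partial_k", 4)),
                amplified=amplified,
                seed=derive_seed(run_seed, 1000, idx),
            ))
            idx += 1

    paralog_specs = []
    for group in config.get("paralog_embryos", []):
        count = int(group.get("count", 1))
        prefix = group.get("prefix", "px")
        for j in range(count):
            paralog_specs.append({
                "embryo_id": f"{prefix}{j + 1:02d}",
                "amplified": bool(group.get("amplified", True)),
                "crossover": bool(group.get("crossover", False)),
                "n_reads": int(group.get("n_reads", 10)),
                "seed": derive_seed(run_seed, 2000, len(paralog_specs)),
            })

    rule_cfg = dict(config.get("guide_rule", {}))
    guide_rule = GuideRule(protospacer=locus.protospacer, **rule_cfg)
    cp = config.get("classifier", {})
    call_params = CallParams(
        cut_window_radius=int(cp.get("cut_window_radius", 5)),
        min_tract_run=int(cp.get("min_tract_run", 2)),
    )
    return Cohort(name=name, locus=locus, donor=donor, embryos=embryos,
                  paralog_specs=paralog_specs,
                  exome_plant=config.get("exome_plant"),
                  guide_rule=guide_rule, call_params=call_params)


def run_cohort(cohort: Cohort):
    """Simulate and classify every embryo; returns (calls, summaries, reads)."""
    all_calls, summaries, all_reads = [], [], []
    for scenario in cohort.embryos:
        reads = simulate_embryo_reads(cohort.locus, cohort.donor, scenario)
        all_reads.extend(reads)
        calls = classify_reads(((r.read_id, r.embryo_id, r.seq) for r in reads),
                               cohort.locus, cohort.donor, cohort.call_params)
        all_calls.extend(calls)
        summaries.append(summarize_embryo(calls, scenario.embryo_id,
                                          amplified=scenario.amplified))
    return all_calls, summaries, all_reads


def run_pathway(cohort: Cohort):
    """Simulate paralog-locus reads and assess crossover per embryo."""
    calls = []
    for spec in cohort.paralog_specs:
        reads = simulate_paralog_reads(
            cohort.locus, spec["embryo_id"], n_reads=spec["n_reads"],
            crossover=spec["crossover"], seed=spec["seed"],
        ) if spec["amplified"] else []
        calls.append(assess_crossover(spec["embryo_id"], reads, cohort.locus,
                                      paralog_amplified=spec["amplified"],
                                      params=cohort.call_params))
    return calls


def run_all(config: dict, outdir, run_seed: int = 0) -> Path:
    """Execute the full pipeline for one scenario config; returns outdir.

    Writes per-read calls, per-embryo and experiment summaries, the
    indel spectrum, crossover and pathway tables, the off-target screen
    outputs when an exome plant is configured, a markdown report, and a
    manifest carrying the config hash and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(config, run_seed)
    files: list[str] = []

    def save(df: pd.DataFrame, fname: str):
        df.to_csv(outdir / fname, sep="\t", index=False)
        files.append(fname)

    eio.write_fasta({"target": cohort.locus.target_seq,
                     "paralog": cohort.locus.paralog_seq}, outdir / "locus.fasta")
    eio.write_fasta({"donor": cohort.donor.seq}, outdir / "donor.fasta")
    files += ["locus.fasta", "donor.fasta"]

    calls, summaries, reads = run_cohort(cohort)
    if reads:
        eio.write_reads_fasta(reads, outdir / "reads.fasta")
        files.append("reads.fasta")
        save(truth_table(reads), "truth.tsv")
    save(pd.DataFrame([{
        "read_id": c.read_id, "embryo_id": c.embryo_id, "category": c.category,
        "indel": c.indel.descriptor if c.indel else "-",
        "allele": c.allele_key, "score": c.alignment_score,
    } for c in calls]), "read_calls.tsv")
    save(pd.DataFrame([{
        "embryo_id": s.embryo_id, "amplified": s.amplified, "cleaved": s.cleaved,
        "hdr_oligo": s.hdr_oligo, "hdr_paralog": s.hdr_paralog,
        "n_distinct_alleles": s.n_distinct_alleles, "mosaic": s.mosaic,
    } for s in summaries]), "embryo_summary.tsv")
    experiment = summarize_experiment(summaries)
    save(pd.DataFrame([experiment.as_row()]), "experiment_summary.tsv")
    save(indel_spectrum(calls), "indel_spectrum.tsv")

    crossover_calls = run_pathway(cohort)
    if crossover_calls:
        save(pd.DataFrame([{
            "embryo_id": c.embryo_id, "paralog_amplified": c.paralog_amplified,
            "paralog_has_target_bases": c.paralog_has_target_bases,
            "paralog_has_cut_indel": c.paralog_has_cut_indel, "verdict": c.verdict,
        } for c in crossover_calls]), "crossover.tsv")
        partials = [c for c in calls if c.category == HDR_PARTIAL]
        save(pathway_report(crossover_calls, partials), "pathway_summary.tsv")

    chain = None
    if cohort.exome_plant:
        planted = generate_exome_variants(
            cohort.guide_rule, {k: int(v) for k, v in cohort.exome_plant.items()},
            seed=derive_seed(run_seed, 3000),
        )
        eio.write_variants_tsv(planted.records, outdir / "variants.tsv")
        eio.write_vcf(planted.records, outdir / "variants.vcf",
                      {c: len(s) for c, s in planted.reference.items()})
        eio.write_bed(planted.exon_intervals, outdir / "exons.bed")
        eio.write_bed(planted.lc_intervals, outdir / "low_complexity.bed")
        files += ["variants.tsv", "variants.vcf", "exons.bed", "low_complexity.bed"]
        chain = run_chain(planted.records, planted.exon_intervals,
                          planted.lc_intervals, cohort.guide_rule,
                          planted.target_sites)
        save(chain.attrition, "attrition.tsv")
        save(trace_table(chain.traces), "filter_trace.tsv")
        save(pd.DataFrame([{
            "variant_id": rec.id, "call": call, "n_mismatches": hit.n_mismatches,
            "seed_perfect": hit.seed_perfect, "qualifies_by": hit.qualifies_by,
        } for rec, call, hit in chain.survivors]), "offtarget_calls.tsv")
        eio.write_vcf([rec for rec, _, _ in chain.survivors],
                      outdir / "survivors.vcf",
                      {c: len(s) for c, s in planted.reference.items()})
        files.append("survivors.vcf")

    _write_report(outdir, cohort, experiment, summaries, crossover_calls, chain)
    files.append("report.md")
    eio.write_manifest(outdir, config, run_seed, files)
    logger.info("run complete: %s (%d files)", outdir, len(files) + 1)
    return outdir


def _write_report(outdir, cohort, experiment, summaries, crossover_calls, chain):
    lines = [f"# edit-audit report: {cohort.name}", ""]
    row = experiment.as_row()
    lines += ["## Editing outcomes", "",
              "| metric | value |", "|---|---|"]
    lines += [f"| {k} | {v} |" for k, v in row.items()]
    mosaic = sum(s.mosaic for s in summaries if s.amplified)
    lines += ["", f"Mosaic embryos (>= 2 distinct alleles): {mosaic}", ""]
    if crossover_calls:
        lines += ["## Crossover assessment", "",
                  "| verdict | embryos |", "|---|---|"]
        for verdict in ("non_crossover", "crossover", "indeterminate"):
            n = sum(c.verdict == verdict for c in crossover_calls)
            lines.append(f"| {verdict} | {n} |")
        lines.append("")
    if chain is not None:
        lines += ["## Off-target screen attrition", "",
                  "| stage | in | removed | % removed |", "|---|---|---|---|"]
        for r in chain.attrition.itertuples(index=False):
            lines.append(f"| {r.stage} | {r.n_in} | {r.n_removed} | {r.pct_removed} |")
        n_on = sum(1 for _, call, _ in chain.survivors if call == "on_target")
        n_off = len(chain.survivors) - n_on
        lines += ["", f"Survivors: {len(chain.survivors)} "
                      f"({n_on} on-target, {n_off} off-target)", ""]
    (Path(outdir) / "report.md").write_text("\n".join(lines))
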