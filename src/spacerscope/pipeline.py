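"""End-to-end synthetic experiments.

Two orchestrated studies mirror the biology:

* the acquisition-bias study — RNA-derived spacer acquisition with and
  without active type III-B interference (interference modeled as post-hoc
  purging of antisense host-derived spacers, which are autoimmune when the
  targeting module is present), scored by the strand-bias statistic and the
  SUS expression null;
* the phage-escape study — a phage carrying the three-protospacer design
  (escape-PAM antisense, canonical-PAM antisense, seed-mismatched sense),
  interference-competence prediction, an escape cohort mutated at the
  type I-F-vulnerable protospacer, variant calling and escape
  classification, and MPN/EOP summaries from simulated dilution series.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phage_variants, protospacer_scan, spacer_orientation, synthetic_data
from .acquisition_null import envelope_test, null_envelope
from .assay_quant import DilutionLevel, eop, mpn
from .io_core import RunConfig, stage_rng
from .synthetic_data import ProtospacerSpec, SynthHostSpec

__all__ = ["PipelineReport", "run_bias_experiment", "run_escape_experiment"]

# model constants for the susceptibility simulation: log10 titer reduction
# contributed by each CRISPR-Cas system when at least one of its
# protospacers is interference-competent
LOG10_REDUCTION_TYPE_IF = 1.7
LOG10_REDUCTION_TYPE_IIIB = 3.0
ANTISENSE_BIAS_DEFAULT = 0.65  # moderate bias of RNA-derived acquisition
ANTISENSE_SURVIVAL_WITH_INTERFERENCE = 0.05


@dataclass
class PipelineReport:
    experiment: str
    config: dict
    stages: list[dict] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def add_stage(self, name: str, **outputs):
        digests = {}
        for key, obj in outputs.items():
            if isinstance(obj, pd.DataFrame):
                payload = obj.to_csv(sep="\t", index=False).encode()
            else:
                payload = json.dumps(obj, sort_keys=True, default=str).encode()
            digests[key] = hashlib.sha256(payload).hexdigest()[:16]
        self.stages.append({"stage": name, "digests": digests})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _default_host_spec(n_genes: int = 100) -> SynthHostSpec:
    r1, r2 = synthetic_data.random_repeat_pair(28, seed=20170918)
    return SynthHostSpec(
        genome_length=100_000,
        intergenic_fraction=0.114,
        n_genes=n_genes,
        arrays=[(r1, 8, 32), (r2, 8, 32)],
    )


def run_bias_experiment(
    config: RunConfig,
    n_samples: int = 8,
    spacers_per_sample: int = 500,
    antisense_bias: float = ANTISENSE_BIAS_DEFAULT,
    antisense_survival: float = ANTISENSE_SURVIVAL_WITH_INTERFERENCE,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Acquisition-bias study: interference-on vs interference-off genotypes."""
    report = PipelineReport("bias", dataclasses.asdict(config))
    host, arrays, truth = synthetic_data.generate_host(_default_host_spec(), config.seed)
    report.add_stage("synth_host", genes=truth.genes)

    rng = stage_rng(config.seed, "bias_experiment")
    genotype_truths: dict[str, list[pd.DataFrame]] = {"interference_off": [], "interference_on": []}
    for genotype in genotype_truths:
        for s in range(n_samples):
            _reads, t = synthetic_data.simulate_acquired_spacers(
                host,
                spacers_per_sample,
                "RNA",
                antisense_bias,
                seed=config.seed + 7919 * s + (0 if genotype == "interference_off" else 104729),
                sample_id=f"{genotype}_{s+1}",
            )
            if genotype == "interference_on":
                keep = np.array(
                    [
                        (row.orientation != "antisense") or (rng.random() < antisense_survival)
                        for row in t.itertuples()
                    ]
                )
                t = t[keep].reset_index(drop=True)
            genotype_truths[genotype].append(t)

    fractions = {
        g: [float((t.orientation == "sense").mean()) for t in ts]
        for g, ts in genotype_truths.items()
    }
    null = truth.annotated_fraction / 2.0
    p = spacer_orientation.compare_bias(
        fractions["interference_on"], fractions["interference_off"]
    )
    report.metrics.update(
        {
            "null_expectation": null,
            "sense_fraction_on": float(np.mean(fractions["interference_on"])),
            "sense_fraction_off": float(np.mean(fractions["interference_off"])),
            "p_value_on_vs_off": p,
        }
    )
    report.add_stage("strand_bias", fractions=fractions)

    # expression null for the interference-off cohort
    genes = truth.genes
    env = null_envelope(
        genes.gene_id, genes.end - genes.start, genes.expression, config
    )
    counts = (
        pd.concat(genotype_truths["interference_off"])
        .query("source != 'intergenic'")
        .source.value_counts()
        .reindex(genes.gene_id, fill_value=0)
    )
    table = envelope_test(counts, env)
    early = table.head(len(table) // 4)
    report.metrics["early_ranks_above_null"] = float((early.call == "above").mean())
    report.add_stage("expression_null", envelope=table)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "envelope.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(report.to_json())
    return report


def _escape_specs(array_id: str) -> list[ProtospacerSpec]:
    """The three-protospacer design: spacer 1 with an escape PAM (AG) and one
    non-seed mismatch, antisense; spacer 2 with the canonical GG PAM and a
    perfect match, antisense; spacer 3 sense with 3 mismatches including one
    in the seed."""
    return [
        ProtospacerSpec((array_id, 0), "antisense", pam="AG", n_mismatches=1),
        ProtospacerSpec((array_id, 1), "antisense", pam="GG", n_mismatches=0),
        ProtospacerSpec((array_id, 2), "sense", pam="TG", n_mismatches=3, seed_mismatch=True),
    ]


def _simulate_titer(
    true_conc: float, rng: np.random.Generator, tubes: int = 5
) -> float:
    """Simulated MPN assay at 100-fold dilutions spanning the assay range."""
    levels = []
    for d in (1e-1, 1e-3, 1e-5, 1e-7):
        p = 1.0 - np.exp(-true_conc * d * 1.0)
        levels.append(DilutionLevel(d, tubes, int(rng.binomial(tubes, p)), 1.0))
    res = mpn(levels, detection_limit=100.0)
    return res.value


def run_escape_experiment(
    config: RunConfig,
    n_variants: int = 11,
    phage_length: int = 40_000,
    base_titer: float = 1e6,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Phage-escape study: competence prediction, escape cohort, variant
    calling, escape classification and susceptibility ordering."""
    report = PipelineReport("escape", dataclasses.asdict(config))
    host, arrays, truth = synthetic_data.generate_host(_default_host_spec(), config.seed)
    if_array = arrays[0]

    phage, ptruth = synthetic_data.generate_phage(
        arrays, _escape_specs(if_array.array_id), phage_length, config.seed, config
    )
    report.add_stage("synth_phage", protospacers=ptruth)

    # scan + annotate + predict
    calls = {}
    matches = []
    for row in ptruth.itertuples():
        spacer = if_array.spacers[row.spacer_index]
        found = protospacer_scan.scan(
            f"{row.array_id}:{row.spacer_index}",
            spacer,
            phage.genome_id,
            phage.sequence,
            config.max_mismatches,
            config,
        )
        m = found[0]
        m.orientation = protospacer_scan.orientation_vs_transcript(m, phage.annotation)
        m.flank_class = protospacer_scan.flank_self_check(
            m, phage.sequence, if_array.repeat, config
        )
        call = protospacer_scan.predict_interference(m, config)
        calls[row.protospacer_id] = call
        matches.append(m)
    report.metrics["competence"] = {
        pid: {"typeIF": c.typeIF_competent, "typeIIIB": c.typeIIIB_competent}
        for pid, c in calls.items()
    }

    # escape cohort: every variant mutates the type I-F-vulnerable
    # (canonical-PAM) protospacer 2; 6 distinct spanning deletions, 3 seed
    # substitutions, 2 seed frameshifts
    p2 = ptruth[ptruth.protospacer_id == "ps2"].iloc[0]
    rng = stage_rng(config.seed, "escape_cohort")
    seed_lo, seed_hi = config.seed_region
    cohort = []
    for i in range(n_variants):
        if i < 6:
            pad_l = int(rng.integers(100, 900))
            pad_r = int(rng.integers(100, 900))
            ev = [("structural_deletion", int(p2.start) - pad_l, int(p2.end) + pad_r)]
        else:
            # genomic position of a random seed position on the protospacer strand
            p = int(rng.integers(seed_lo, seed_hi + 1))
            gpos = (int(p2.start) + p - 1) if p2.strand == "+" else (int(p2.end) - p)
            if i < 9:
                ev = [("snv", gpos)]
            else:
                ev = [("insertion", gpos, 1)]
        variant_seq, vtruth = synthetic_data.mutate_phage(phage, ev, seed=config.seed + i)
        called, rearranged = phage_variants.diff_genomes(phage.sequence, variant_seq)
        esc = phage_variants.classify_escape(called, ptruth, config, reference=phage.sequence)
        cohort.append(
            {
                "variant": f"v{i+1}",
                "n_sites": len(called),
                "escape": dict(zip(esc.protospacer_id, esc.escape_class)),
                "rearranged": rearranged,
            }
        )
    report.metrics["cohort"] = cohort
    report.add_stage("escape_cohort", cohort=cohort)

    # susceptibility ordering across host genotypes (simulated EOP)
    genotype_systems = {
        "WT": ("IF", "IIIB"),
        "dIF_Cas123": ("IIIB",),  # array and csy genes intact, effector gone
        "dIIIB": ("IF",),
        "dIF_dIIIB": (),
    }
    if_active = any(c.typeIF_competent for c in calls.values())
    iiib_active = any(c.typeIIIB_competent for c in calls.values())
    titers = {}
    srng = stage_rng(config.seed, "susceptibility")
    for g, systems in genotype_systems.items():
        red = 0.0
        if "IF" in systems and if_active:
            red += LOG10_REDUCTION_TYPE_IF
        if "IIIB" in systems and iiib_active:
            red += LOG10_REDUCTION_TYPE_IIIB
        titers[g] = _simulate_titer(base_titer * 10.0 ** (-red), srng)
    ref = titers["WT"] if titers["WT"] > 0 else 1.0
    eops = {g: eop(t, ref).value for g, t in titers.items()}
    report.metrics["titers"] = titers
    report.metrics["eop_vs_wt"] = eops
    report.add_stage("susceptibility", eop=eops)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ptruth.to_csv(outdir / "protospacers.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(report.to_json())
    return report
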