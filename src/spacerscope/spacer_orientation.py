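"""Strand-bias analysis of newly acquired spacers.

Maps acquired spacers back to the host genome, calls each one sense or
antisense relative to the annotated gene it falls in (or unassigned when
intergenic), and computes the sense-strand fraction against its
annotation-derived null: with a fraction *d* of the genome outside
annotated genes, unbiased acquisition yields an expected sense fraction of
(1 - d)/2 — 44.3% rather than 50% when d = 11.4% — because intergenic
spacers provide no basis for strand assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import AnnotatedGenome, AnnotationSet, revcomp
from .protospacer_scan import hamming_windows

__all__ = [
    "SpacerHit",
    "StrandBiasResult",
    "map_spacers",
    "classify_orientation",
    "strand_bias",
    "compare_bias",
]


@dataclass
class SpacerHit:
    spacer_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    mismatches: int
    gene_id: str | None = None
    orientation: str = "unassigned"  # sense | antisense | unassigned


def map_spacers(
    spacers: list[tuple[str, str]],
    genome: str,
    max_mismatches: int = 0,
) -> tuple[list[SpacerHit], int]:
    """Best genomic hit per spacer (fewest mismatches; ties broken leftmost
    on +, then leftmost on -).  Returns (hits, n_unmapped); spacers with no
    hit within ``max_mismatches`` are dropped and counted."""
    if not spacers:
        raise ValueError("spacers must be non-empty")
    hits: list[SpacerHit] = []
    unmapped = 0
    for sid, seq in spacers:
        best = None  # (mismatches, strand_rank, pos)
        for rank, (strand, query) in enumerate((("+", seq), ("-", revcomp(seq)))):
            mm = hamming_windows(genome, query)
            if mm.size == 0:
                continue
            pos = int(np.argmin(mm))
            key = (int(mm[pos]), rank, pos)
            if best is None or key < best[0]:
                best = (key, strand)
        if best is None or best[0][0] > max_mismatches:
            unmapped += 1
            continue
        (nmm, _rank, pos), strand = best
        hits.append(SpacerHit(sid, pos, pos + len(seq), strand, nmm))
    return hits, unmapped


def classify_orientation(
    hit: SpacerHit, annotation: AnnotationSet, min_overlap: float = 0.5
) -> str:
    """sense when the hit strand equals the overlapping gene's strand,
    antisense when opposite, unassigned when no gene covers at least
    ``min_overlap`` of the spacer."""
    length = hit.end - hit.start
    best, best_ov = None, 0
    for g in annotation.overlapping(hit.start, hit.end):
        ov = min(hit.end, g.end) - max(hit.start, g.start)
        if ov > best_ov:
            best, best_ov = g, ov
    if best is None or best_ov < min_overlap * length:
        hit.gene_id = None
        hit.orientation = "unassigned"
    else:
        hit.gene_id = best.gene_id
        hit.orientation = "sense" if hit.strand == best.strand else "antisense"
    return hit.orientation


@dataclass
class StrandBiasResult:
    n_sense: int
    n_antisense: int
    n_unassigned: int
    sense_fraction: float  # of ALL spacers, unassigned included in the denominator
    null_expectation: float
    per_sample_fractions: list[float] = field(default_factory=list)
    sem: float | None = None

    @property
    def total(self) -> int:
        return self.n_sense + self.n_antisense + self.n_unassigned


def strand_bias(
    samples: dict[str, list[SpacerHit]] | list[list[SpacerHit]],
    annotation: AnnotationSet,
    genome_length: int,
) -> StrandBiasResult:
    """Sense-fraction statistic over one or more samples of classified hits.

    The null expectation is (annotated base fraction)/2; the SEM is computed
    across per-sample sense fractions when two or more samples are given.
    """
    groups = list(samples.values()) if isinstance(samples, dict) else list(samples)
    if not groups:
        raise ValueError("at least one sample required")
    all_hits = [h for g in groups for h in g]
    if not all_hits:
        raise ValueError("zero spacers: strand bias undefined")
    n_sense = sum(h.orientation == "sense" for h in all_hits)
    n_anti = sum(h.orientation == "antisense" for h in all_hits)
    n_un = sum(h.orientation == "unassigned" for h in all_hits)
    fractions = [
        sum(h.orientation == "sense" for h in g) / len(g) for g in groups if g
    ]
    sem = (
        float(np.std(fractions, ddof=1) / np.sqrt(len(fractions)))
        if len(fractions) >= 2
        else None
    )
    null = annotation.annotated_fraction(genome_length) / 2.0
    return StrandBiasResult(
        n_sense=n_sense,
        n_antisense=n_anti,
        n_unassigned=n_un,
        sense_fraction=n_sense / len(all_hits),
        null_expectation=null,
        per_sample_fractions=fractions,
        sem=sem,
    )


def compare_bias(group_a: list[float], group_b: list[float]) -> float:
    """Two-sided Welch t-test on per-sample sense fractions."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("at least 2 samples per group required")
    t = stats.ttest_ind(group_a, group_b, equal_var=False)
    return float(t.pvalue)
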