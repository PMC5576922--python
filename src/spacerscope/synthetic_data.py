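"""Synthetic hosts, CRISPR arrays, reads, phages and phage variants.

Every generator returns a truth table alongside its sequence output, so each
downstream analysis stage can be scored against known ground truth.  The
defaults emulate the study system: a marine gammaproteobacterial host whose
genome is ~88.6% covered by annotated genes on both strands, carrying one
type I-F-like and one type III-B-like CRISPR array with 32-bp spacers, and
a ~40-kb podovirus-like phage whose protospacers differ in PAM, mismatch
load, seed status and orientation relative to the predicted transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    AnnotatedGenome,
    AnnotationSet,
    CrisprArray,
    GeneFeature,
    RunConfig,
    revcomp,
    stage_rng,
)
from .phage_variants import VariantCall, normalize_left

__all__ = [
    "SynthHostSpec",
    "ProtospacerSpec",
    "HostTruth",
    "generate_host",
    "random_repeat_pair",
    "simulate_acquired_spacers",
    "simulate_crrna_reads",
    "generate_phage",
    "mutate_phage",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


# ---------------------------------------------------------------------------
# Host genomes
# ---------------------------------------------------------------------------


@dataclass
class SynthHostSpec:
    """Parameters of a synthetic host genome.

    ``intergenic_fraction`` defaults to 0.114: the fraction of the genome
    outside annotated genes in the study host, which fixes the no-bias
    expectation for sense-strand spacers at (1 - 0.114)/2 = 44.3%.
    Expression is log-normal across genes (a broad, right-skewed
    distribution typical of bacterial transcriptomes).
    """

    genome_length: int = 100_000
    intergenic_fraction: float = 0.114
    n_genes: int = 100
    expression_mu: float = 2.0
    expression_sigma: float = 1.0
    # (repeat sequence, number of spacers, spacer length)
    arrays: list[tuple[str, int, int]] = field(default_factory=list)
    min_gene_length: int = 60

    def __post_init__(self):
        if not 0.0 <= self.intergenic_fraction <= 1.0:
            raise ValueError("intergenic_fraction must be in [0, 1]")
        if self.n_genes < 0 or self.genome_length <= 0:
            raise ValueError("n_genes and genome_length must be non-negative / positive")


@dataclass
class HostTruth:
    genes: pd.DataFrame  # gene_id, start, end, strand, expression
    arrays: list[CrisprArray]
    annotated_fraction: float


def _partition_exact(rng, total: int, parts: int, minimum: int = 0) -> np.ndarray:
    """Random non-negative integer partition of ``total`` into ``parts`` parts,
    each at least ``minimum``, summing exactly to ``total``."""
    if parts == 0:
        if total != 0:
            raise ValueError("cannot partition a positive total into zero parts")
        return np.zeros(0, dtype=int)
    spare = total - parts * minimum
    if spare < 0:
        raise ValueError("total too small for the requested minimum part size")
    weights = rng.dirichlet(np.ones(parts))
    raw = weights * spare
    counts = np.floor(raw).astype(int)
    remainder = spare - counts.sum()
    order = np.argsort(raw - counts)[::-1]
    counts[order[:remainder]] += 1
    return counts + minimum


def generate_host(spec: SynthHostSpec, seed: int) -> tuple[AnnotatedGenome, list[CrisprArray], HostTruth]:
    """Build a host genome with non-overlapping stranded genes and embedded
    repeat-spacer arrays; arrays sit in intergenic space."""
    rng = stage_rng(seed, "generate_host")
    L = spec.genome_length
    gene_bases = round(L * (1.0 - spec.intergenic_fraction))

    arrays: list[CrisprArray] = []
    for i, (repeat, n_spacers, spacer_len) in enumerate(spec.arrays):
        anchor = repeat[:5]
        handle = repeat[-8:]
        if anchor in handle:
            raise ValueError(
                "repeat's 5' anchor prefix recurs in its 3' handle; "
                "use random_repeat_pair to draw unambiguous repeats"
            )
        spacers: list[str] = []
        seen = set()
        while len(spacers) < n_spacers:
            s = _random_seq(rng, spacer_len)
            # unique within the array, and the repeat's 5-base anchor prefix
            # must not occur upstream of its true position in a mature read
            # (handle + spacer + next-repeat prefix), so trimming is exact
            clean = (handle + s + anchor).find(anchor) == 8 + spacer_len
            if s not in seen and clean:
                seen.add(s)
                spacers.append(s)
        arrays.append(CrisprArray(array_id=f"array{i+1}", repeat=repeat, spacers=spacers))
    array_bases = sum(len(a) for a in arrays)

    intergenic_bases = L - gene_bases - array_bases
    if intergenic_bases < 0 or gene_bases < spec.n_genes * spec.min_gene_length:
        raise ValueError("genome too small for the requested genes and arrays")

    if spec.n_genes > 0:
        gene_lengths = _partition_exact(rng, gene_bases, spec.n_genes, spec.min_gene_length)
    else:
        gene_lengths = np.zeros(0, dtype=int)
        if gene_bases > 0:
            intergenic_bases += gene_bases
            gene_bases = 0
    gaps = _partition_exact(rng, intergenic_bases, spec.n_genes + 1)

    # drop each array into the middle of a distinct gap slot
    if len(arrays) > len(gaps):
        raise ValueError("more arrays than intergenic gaps")
    array_slots = rng.choice(len(gaps), size=len(arrays), replace=False)
    slot_to_array = {int(s): a for s, a in zip(array_slots, arrays)}

    expr = rng.lognormal(spec.expression_mu, spec.expression_sigma, size=spec.n_genes)
    strands = rng.choice(np.array(["+", "-"]), size=spec.n_genes)

    parts: list[str] = []
    pos = 0
    genes: list[GeneFeature] = []
    for i in range(spec.n_genes + 1):
        gap = int(gaps[i])
        arr = slot_to_array.get(i)
        if arr is not None:
            half = gap // 2
            parts.append(_random_seq(rng, half))
            pos += half
            arr.start = pos
            parts.append(arr.sequence)
            pos += len(arr)
            parts.append(_random_seq(rng, gap - half))
            pos += gap - half
        else:
            parts.append(_random_seq(rng, gap))
            pos += gap
        if i < spec.n_genes:
            glen = int(gene_lengths[i])
            genes.append(
                GeneFeature(
                    gene_id=f"g{i+1:04d}",
                    start=pos,
                    end=pos + glen,
                    strand=str(strands[i]),
                    expression=float(expr[i]),
                )
            )
            parts.append(_random_seq(rng, glen))
            pos += glen

    sequence = "".join(parts)
    assert len(sequence) == L
    annotation = AnnotationSet(genome_id="synth_host", genes=genes)
    genome = AnnotatedGenome(genome_id="synth_host", sequence=sequence, annotation=annotation)
    truth = HostTruth(
        genes=pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "start": [g.start for g in genes],
                "end": [g.end for g in genes],
                "strand": [g.strand for g in genes],
                "expression": [g.expression for g in genes],
            }
        ),
        arrays=arrays,
        annotated_fraction=gene_bases / L,
    )
    return genome, arrays, truth


def random_repeat_pair(length: int, seed: int, max_identity: float = 0.6) -> tuple[str, str]:
    """Two random repeats sharing < ``max_identity`` positional identity,
    emulating the sparse similarity between type I-F and type III-B repeats."""
    rng = stage_rng(seed, "random_repeat_pair")

    def draw() -> str:
        while True:
            r = _random_seq(rng, length)
            if r[:5] not in r[-8:]:  # keep the trimming anchor unambiguous
                return r

    r1 = draw()
    while True:
        r2 = draw()
        ident = sum(a == b for a, b in zip(r1, r2)) / length
        if ident < max_identity:
            return r1, r2


# ---------------------------------------------------------------------------
# Acquired spacers
# ---------------------------------------------------------------------------


def simulate_acquired_spacers(
    host: AnnotatedGenome,
    n: int,
    source: str,
    antisense_bias: float,
    seed: int,
    spacer_length: int = 32,
    expression_exponent: float = 1.0,
    sample_id: str = "s1",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate newly acquired spacers from cellular RNA or DNA.

    A spacer originates from intergenic space with probability equal to the
    genome's intergenic base fraction (strandless, labelled unassignable);
    otherwise a source gene is drawn with weight length x expression (RNA)
    or length alone (DNA), and the spacer is antisense to its gene with
    probability ``antisense_bias`` (RNA) or 0.5 (DNA).
    """
    if source not in ("RNA", "DNA"):
        raise ValueError("source must be 'RNA' or 'DNA'")
    if not 0.0 <= antisense_bias <= 1.0:
        raise ValueError("antisense_bias must be in [0, 1]")
    rng = stage_rng(seed, f"simulate_acquired_spacers:{sample_id}")
    genes = host.annotation.genes
    L = len(host)

    eligible = [g for g in genes if g.length >= spacer_length]
    if source == "RNA":
        weights = np.array(
            [g.length * (g.expression or 1.0) ** expression_exponent for g in eligible],
            dtype=float,
        )
    else:
        weights = np.array([float(g.length) for g in eligible])
    if eligible:
        weights = weights / weights.sum()

    # intergenic intervals wide enough to hold a spacer
    covered = np.zeros(L, dtype=bool)
    for g in genes:
        covered[g.start : g.end] = True
    annotated_fraction = float(covered.sum()) / L
    boundaries = np.flatnonzero(np.diff(np.concatenate(([True], ~covered, [True]))))
    inter = [
        (int(boundaries[i]), int(boundaries[i + 1]))
        for i in range(0, len(boundaries), 2)
    ]
    inter = [(s, e) for s, e in inter if e - s >= spacer_length]
    inter_w = np.array([e - s - spacer_length + 1 for s, e in inter], dtype=float)
    if len(inter_w):
        inter_w = inter_w / inter_w.sum()

    p_inter = 1.0 - annotated_fraction
    if not eligible:
        p_inter = 1.0
    if not inter:
        p_inter = 0.0

    reads: list[tuple[str, str]] = []
    rows = []
    for i in range(n):
        rid = f"{sample_id}_sp{i+1:05d}"
        if rng.random() < p_inter:
            j = rng.choice(len(inter), p=inter_w)
            s0, e0 = inter[j]
            pos = int(rng.integers(s0, e0 - spacer_length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seg = host.sequence[pos : pos + spacer_length]
            seq = seg if strand == "+" else revcomp(seg)
            rows.append((rid, "intergenic", None, pos, strand, "unassignable"))
        else:
            g = eligible[rng.choice(len(eligible), p=weights)]
            pos = int(rng.integers(g.start, g.end - spacer_length + 1))
            p_anti = antisense_bias if source == "RNA" else 0.5
            anti = rng.random() < p_anti
            strand = (
                ("-" if g.strand == "+" else "+") if anti else g.strand
            )
            seg = host.sequence[pos : pos + spacer_length]
            seq = seg if strand == "+" else revcomp(seg)
            rows.append(
                (rid, g.gene_id, g.strand, pos, strand, "antisense" if anti else "sense")
            )
        reads.append((rid, seq))
    truth = pd.DataFrame(
        rows,
        columns=["spacer_id", "source", "gene_strand", "position", "spacer_strand", "orientation"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Small-RNA (crRNA) reads
# ---------------------------------------------------------------------------


def simulate_crrna_reads(
    arrays: list[CrisprArray],
    n_mature: int,
    n_background: int,
    trna_set: list[tuple[str, str]],
    seed: int,
    handle_len: int = 8,
    stub_min: int = 5,
    stub_max: int = 8,
    trna_fraction: float = 0.6,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a strand-preserving small-RNA library.

    Mature crRNA reads carry the repeat-derived 5' handle (last ``handle_len``
    nt of the repeat), the full spacer, and a 3' stub of the first
    ``stub_min``..``stub_max`` nt of the next repeat.  Background reads are
    tRNA fragments (the first tRNA in ``trna_set`` is the designated, most
    abundant species) plus random fragments.
    """
    if n_mature > 0 and not arrays:
        raise ValueError("arrays must be non-empty when mature reads are requested")
    rng = stage_rng(seed, "simulate_crrna_reads")
    reads: list[tuple[str, str]] = []
    rows = []
    for i in range(n_mature):
        a = arrays[rng.integers(len(arrays))]
        si = int(rng.integers(len(a.spacers)))
        stub = int(rng.integers(stub_min, stub_max + 1))
        seq = a.repeat[-handle_len:] + a.spacers[si] + a.repeat[:stub]
        rid = f"mature_{i+1:06d}"
        reads.append((rid, seq))
        rows.append((rid, "mature", a.array_id, si, stub, handle_len + len(a.spacers[si]), None))
    if n_background > 0 and trna_set:
        trna_w = np.full(len(trna_set), (1.0 - trna_fraction) / max(len(trna_set) - 1, 1))
        trna_w[0] = trna_fraction if len(trna_set) > 1 else 1.0
        trna_w = trna_w / trna_w.sum()
    for i in range(n_background):
        rid = f"bg_{i+1:06d}"
        if trna_set and rng.random() < 0.7:
            ti = int(rng.choice(len(trna_set), p=trna_w))
            tseq = trna_set[ti][1]
            flen = int(rng.integers(min(20, len(tseq)), len(tseq) + 1))
            start = int(rng.integers(0, len(tseq) - flen + 1))
            reads.append((rid, tseq[start : start + flen]))
            rows.append((rid, "trna", None, None, None, None, trna_set[ti][0]))
        else:
            reads.append((rid, _random_seq(rng, int(rng.integers(20, 51)))))
            rows.append((rid, "random", None, None, None, None, None))
    truth = pd.DataFrame(
        rows,
        columns=["read_id", "kind", "array_id", "spacer_index", "stub_len", "trimmed_len", "trna_id"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Phage genomes with planted protospacers
# ---------------------------------------------------------------------------


@dataclass
class ProtospacerSpec:
    """Design of one planted protospacer."""

    spacer_ref: tuple[str, int]  # (array_id, spacer index)
    strand_vs_transcript: str = "antisense"  # antisense | sense
    pam: str = "GG"
    n_mismatches: int = 0
    seed_mismatch: bool = False
    flank_mode: str = "random"  # random | repeat

    def __post_init__(self):
        if self.strand_vs_transcript not in ("antisense", "sense"):
            raise ValueError("strand_vs_transcript must be 'antisense' or 'sense'")
        if self.flank_mode not in ("random", "repeat"):
            raise ValueError("flank_mode must be 'random' or 'repeat'")
        if self.seed_mismatch and self.n_mismatches < 1:
            raise ValueError("seed_mismatch requires n_mismatches >= 1")


def generate_phage(
    host_arrays: list[CrisprArray],
    specs: list[ProtospacerSpec],
    genome_length: int,
    seed: int,
    config: RunConfig | None = None,
    orf_length: int = 600,
) -> tuple[AnnotatedGenome, pd.DataFrame]:
    """Random phage genome with one planted protospacer per spec, each inside
    its own +-strand ORF.  Truth table columns give the protospacer interval
    (0-based half-open on the + strand), the protospacer strand, the PAM as
    read on that strand, and 1-based PAM-proximal mismatch positions."""
    cfg = config or RunConfig()
    rng = stage_rng(seed, "generate_phage")
    arrays = {a.array_id: a for a in host_arrays}

    spacing = (genome_length - len(specs) * orf_length) // (len(specs) + 1)
    if spacing < 20:
        raise ValueError("genome too small to place the requested protospacers")

    seq = list(_random_seq(rng, genome_length))
    genes: list[GeneFeature] = []
    rows = []
    pos = spacing
    for k, spec in enumerate(specs):
        arr = arrays[spec.spacer_ref[0]]
        spacer = arr.spacers[spec.spacer_ref[1]]
        slen = len(spacer)
        if spec.n_mismatches > slen:
            raise ValueError("n_mismatches exceeds spacer length")

        seed_lo, seed_hi = cfg.seed_region
        seed_positions = list(range(seed_lo, min(seed_hi, slen) + 1))
        non_seed = [p for p in range(1, slen + 1) if p not in seed_positions]
        mm_positions: list[int] = []
        if spec.seed_mismatch:
            mm_positions.append(int(rng.choice(seed_positions)))
        n_rest = spec.n_mismatches - len(mm_positions)
        if n_rest > len(non_seed):
            raise ValueError("not enough non-seed positions for the requested mismatches")
        mm_positions += [int(p) for p in rng.choice(non_seed, size=n_rest, replace=False)]
        mm_positions.sort()

        variant = list(spacer)
        for p in mm_positions:  # 1-based from the PAM-proximal (5') end
            variant[p - 1] = _mutate_base(rng, variant[p - 1])
        variant = "".join(variant)

        if spec.flank_mode == "repeat":
            flank5 = arr.repeat[-cfg.handle_len :]
            pam = flank5[-2:]
        else:
            flank5 = _random_seq(rng, cfg.handle_len - 2) + spec.pam
            pam = spec.pam
        flank3 = _random_seq(rng, cfg.handle_len)
        cassette = flank5 + variant + flank3  # protospacer-strand orientation

        orf_start = pos
        orf_end = pos + orf_length
        cass_off = (orf_length - len(cassette)) // 2
        proto_strand = "-" if spec.strand_vs_transcript == "antisense" else "+"
        if proto_strand == "+":
            placed = cassette
            p_start = orf_start + cass_off + len(flank5)
        else:
            placed = revcomp(cassette)
            # after revcomp, flank3 leads; protospacer occupies the mirror slot
            p_start = orf_start + cass_off + len(flank3)
        p_end = p_start + slen
        seq[orf_start + cass_off : orf_start + cass_off + len(cassette)] = placed
        genes.append(GeneFeature(f"orf{k+1:03d}", orf_start, orf_end, "+", expression=1.0))
        rows.append(
            (
                f"ps{k+1}",
                spec.spacer_ref[0],
                spec.spacer_ref[1],
                p_start,
                p_end,
                proto_strand,
                pam,
                ",".join(map(str, mm_positions)),
                spec.n_mismatches,
                spec.seed_mismatch,
                spec.strand_vs_transcript,
                spec.flank_mode,
            )
        )
        pos = orf_end + spacing

    genome = AnnotatedGenome(
        genome_id="synth_phage",
        sequence="".join(seq),
        annotation=AnnotationSet(genome_id="synth_phage", genes=genes),
    )
    truth = pd.DataFrame(
        rows,
        columns=[
            "protospacer_id",
            "array_id",
            "spacer_index",
            "start",
            "end",
            "strand",
            "pam",
            "mismatch_positions",
            "n_mismatches",
            "seed_mismatch",
            "orientation",
            "flank_mode",
        ],
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Phage variants (escape cohorts)
# ---------------------------------------------------------------------------


def mutate_phage(
    genome: AnnotatedGenome | str,
    events: list[tuple],
    seed: int,
) -> tuple[str, list[VariantCall]]:
    """Apply SNVs, short indels and large deletions to a phage genome.

    ``events`` entries are ``("snv", pos0)``, ``("insertion", pos0, length)``,
    ``("deletion", pos0, length)`` or ``("structural_deletion", start0, end0)``
    with 0-based reference coordinates (deletion interval half-open).
    Overlapping events are rejected.  Returns the mutated sequence and the
    truth-table variant calls (1-based reference coordinates).
    """
    seq = genome.sequence if isinstance(genome, AnnotatedGenome) else genome
    rng = stage_rng(seed, "mutate_phage")
    L = len(seq)

    intervals = []
    for ev in events:
        kind = ev[0]
        if kind == "snv":
            intervals.append((ev[1], ev[1] + 1))
        elif kind == "insertion":
            intervals.append((ev[1], ev[1]))
        elif kind == "deletion":
            intervals.append((ev[1], ev[1] + ev[2]))
        elif kind == "structural_deletion":
            intervals.append((ev[1], ev[2]))
        else:
            raise ValueError(f"unknown event type {kind!r}")
        s, e = intervals[-1]
        if s < 0 or e > L:
            raise ValueError(f"event {ev} outside genome bounds")
    order = sorted(range(len(events)), key=lambda i: intervals[i][0])
    for a, b in zip(order, order[1:]):
        if intervals[a][1] > intervals[b][0]:
            raise ValueError("overlapping events are not allowed")

    calls: list[VariantCall] = []
    out = seq
    for i in sorted(order, key=lambda i: intervals[i][0], reverse=True):
        ev = events[i]
        kind = ev[0]
        if kind == "snv":
            p = ev[1]
            alt = _mutate_base(rng, out[p])
            calls.append(VariantCall("SNV", p + 1, out[p], alt, 1))
            out = out[:p] + alt + out[p + 1 :]
        elif kind == "insertion":
            p, ln = ev[1], ev[2]
            ins = _random_seq(rng, ln)
            calls.append(VariantCall("insertion", p + 1, "", ins, ln))
            out = out[:p] + ins + out[p:]
        elif kind == "deletion":
            p, ln = ev[1], ev[2]
            calls.append(VariantCall("deletion", p + 1, out[p : p + ln], "", ln))
            out = out[:p] + out[p + ln :]
        elif kind == "structural_deletion":
            s, e = ev[1], ev[2]
            calls.append(
                VariantCall(
                    "structural_deletion", s + 1, out[s:e], "", e - s, breakpoints=(s + 1, e)
                )
            )
            out = out[:s] + out[e:]
    calls = [normalize_left(seq, c) for c in calls]
    calls.sort(key=lambda c: c.position)
    return out, calls
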