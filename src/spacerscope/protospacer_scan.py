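"""Protospacer discovery and interference-competence prediction.

Scans phage or plasmid genomes for spacer matches (Hamming distance only:
described matches are length-preserving), annotates each with its PAM, seed
mismatches, orientation relative to the predicted transcript, and the
self/non-self status of the flank adjacent to the crRNA 5' handle, then
predicts per-system competence:

* type I-F: DNA targeting — requires the canonical PAM and a clean seed,
  independent of transcription;
* type III-B: transcription-dependent — requires the crRNA to be
  complementary to the mRNA (antisense protospacer) and a non-self flank,
  with no PAM requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import AnnotationSet, RunConfig, revcomp

__all__ = [
    "ProtospacerMatch",
    "InterferenceCall",
    "hamming_windows",
    "scan",
    "orientation_vs_transcript",
    "flank_self_check",
    "predict_interference",
    "find_orfs",
]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_N = ord("N")


def hamming_windows(genome: str, query: str) -> np.ndarray:
    """Mismatch count of ``query`` against every window of ``genome``.

    N never matches any base, including another N.  Returns an array of
    length ``len(genome) - len(query) + 1`` (empty when the query is longer
    than the genome).
    """
    g, q = _encode(genome), _encode(query)
    L, m = len(g), len(q)
    if L < m:
        return np.zeros(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(g, m)
    mm = (win != q) | (win == _N) | (q == _N)
    return mm.sum(axis=1)


@dataclass
class ProtospacerMatch:
    spacer_id: str
    genome_id: str
    start: int  # 0-based half-open on the + strand
    end: int
    strand: str  # strand carrying the spacer sequence
    mismatches: int
    mismatch_positions: list[int] = field(default_factory=list)  # 1-based, PAM-proximal
    pam: str | None = None
    pam_available: bool = True
    pam_canonical: bool = False
    seed_mismatch: bool = False
    orientation: str | None = None  # antisense_crRNA_complementary | sense_crRNA_noncomplementary | no_transcript
    flank_class: str | None = None  # self | non_self


@dataclass
class InterferenceCall:
    typeIF_competent: bool
    typeIIIB_competent: bool
    reasons: list[str]


def _mismatch_positions(proto: str, spacer: str, pam_proximal_5prime: bool) -> list[int]:
    """1-based mismatch positions counted from the PAM-proximal end of the
    protospacer-strand sequence."""
    n = len(spacer)
    pos = [i + 1 for i in range(n) if proto[i] != spacer[i] or "N" in (proto[i], spacer[i])]
    if not pam_proximal_5prime:
        pos = sorted(n - p + 1 for p in pos)
    return pos


def scan(
    spacer_id: str,
    spacer: str,
    genome_id: str,
    genome: str,
    max_mismatches: int,
    config: RunConfig | None = None,
) -> list[ProtospacerMatch]:
    """All protospacer matches on both strands with <= max_mismatches,
    sorted by (mismatches, coordinate, strand)."""
    cfg = config or RunConfig()
    if len(spacer) < cfg.seed_region[1]:
        raise ValueError("spacer shorter than the configured seed region")
    five_prime = cfg.pam_convention == "five_prime_of_protospacer"
    m = len(spacer)
    matches: list[ProtospacerMatch] = []
    for strand, query in (("+", spacer), ("-", revcomp(spacer))):
        mm = hamming_windows(genome, query)
        for s in np.flatnonzero(mm <= max_mismatches):
            s = int(s)
            e = s + m
            proto = genome[s:e] if strand == "+" else revcomp(genome[s:e])
            mpos = _mismatch_positions(proto, spacer, five_prime)
            pam, avail = _extract_pam(genome, s, e, strand, cfg)
            seed_lo, seed_hi = cfg.seed_region
            match = ProtospacerMatch(
                spacer_id=spacer_id,
                genome_id=genome_id,
                start=s,
                end=e,
                strand=strand,
                mismatches=int(mm[s]),
                mismatch_positions=mpos,
                pam=pam,
                pam_available=avail,
                pam_canonical=avail and pam == cfg.pam_canonical,
                seed_mismatch=any(seed_lo <= p <= seed_hi for p in mpos),
            )
            matches.append(match)
    matches.sort(key=lambda h: (h.mismatches, h.start, h.strand))
    return matches


def _extract_pam(genome: str, s: int, e: int, strand: str, cfg: RunConfig):
    """PAM read on the protospacer strand at the configured side."""
    five = cfg.pam_convention == "five_prime_of_protospacer"
    if (strand == "+") == five:
        lo, hi = s - 2, s
    else:
        lo, hi = e, e + 2
    if lo < 0 or hi > len(genome):
        return None, False
    pam = genome[lo:hi]
    if strand == "-":
        pam = revcomp(pam)
    return pam, True


def orientation_vs_transcript(match: ProtospacerMatch, annotation: AnnotationSet, min_overlap: float = 0.5) -> str:
    """Orientation of the crRNA relative to the overlapping transcript.

    The crRNA has the spacer's sequence, so when the spacer maps to the
    strand opposite the coding strand it base-pairs with the mRNA
    (antisense_crRNA_complementary)."""
    length = match.end - match.start
    best, best_ov = None, 0
    for g in annotation.overlapping(match.start, match.end):
        ov = min(match.end, g.end) - max(match.start, g.start)
        if ov > best_ov:
            best, best_ov = g, ov
    if best is None or best_ov < min_overlap * length:
        return "no_transcript"
    return (
        "antisense_crRNA_complementary"
        if match.strand != best.strand
        else "sense_crRNA_noncomplementary"
    )


def flank_self_check(
    match: ProtospacerMatch,
    genome: str,
    repeat: str,
    config: RunConfig | None = None,
    threshold: int | None = None,
) -> str:
    """Self/non-self status of the flank adjacent to the crRNA 5' handle.

    Compares the ``handle_len`` bases immediately 5' of the protospacer (on
    the protospacer strand) against the repeat's last ``handle_len`` bases.
    Full identity (by default) marks the target as self — the genomic CRISPR
    array context — which suppresses type III interference.  A flank
    truncated by the genome edge is non_self.
    """
    cfg = config or RunConfig()
    h = cfg.handle_len
    need = h if threshold is None else threshold
    if match.strand == "+":
        lo, hi = match.start - h, match.start
        if lo < 0:
            return "non_self"
        flank = genome[lo:hi]
    else:
        lo, hi = match.end, match.end + h
        if hi > len(genome):
            return "non_self"
        flank = revcomp(genome[lo:hi])
    ident = sum(a == b for a, b in zip(flank, repeat[-h:]))
    return "self" if ident >= need else "non_self"


def predict_interference(match: ProtospacerMatch, config: RunConfig | None = None) -> InterferenceCall:
    """Per-system interference competence from a fully annotated match."""
    cfg = config or RunConfig()
    reasons: list[str] = []

    type_if = True
    if not match.pam_canonical:
        type_if = False
        reasons.append("pam_noncanonical")
    if match.seed_mismatch:
        type_if = False
        reasons.append("seed_mismatch")
    if match.mismatches > cfg.max_mismatches:
        type_if = False

    type_iiib = True
    if match.orientation != "antisense_crRNA_complementary":
        type_iiib = False
        reasons.append(
            "no_transcript" if match.orientation == "no_transcript" else "sense_orientation"
        )
    if match.flank_class == "self":
        type_iiib = False
        reasons.append("self_flank")
    if match.mismatches > cfg.max_mismatches:
        type_iiib = False
        reasons.append("too_many_mismatches")

    return InterferenceCall(type_if, type_iiib, reasons)


# ---------------------------------------------------------------------------
# Minimal 6-frame ORF caller (used when no annotation is supplied)
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(genome: str, min_len: int = 150) -> AnnotationSet:
    """ATG-to-stop open reading frames >= min_len nt, both strands."""
    from .io_core import GeneFeature

    genes = []
    n = 0
    for strand, seq in (("+", genome), ("-", revcomp(genome))):
        L = len(seq)
        for frame in range(3):
            i = frame
            while i + 3 <= L:
                if seq[i : i + 3] == "ATG":
                    j = i + 3
                    while j + 3 <= L and seq[j : j + 3] not in _STOPS:
                        j += 3
                    if j + 3 <= L:
                        j += 3  # include the stop codon
                    if j - i >= min_len:
                        n += 1
                        if strand == "+":
                            genes.append(GeneFeature(f"orf{n}", i, j, "+"))
                        else:
                            genes.append(GeneFeature(f"orf{n}", L - j, L - i, "-"))
                        i = j
                        continue
                i += 3
    genes.sort(key=lambda g: g.start)
    return AnnotationSet(genome_id="", genes=genes)
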