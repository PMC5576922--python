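"""Pairwise comparison of near-identical phage genomes.

Calls SNVs, short indels and large (structural) deletions between two
collinear assemblies by chaining unique k-mer anchors and aligning the
inter-anchor gaps; classifies each variant against protospacer loci as an
escape mutation; predicts diagnostic PCR amplicons; and compares protein
products of homologous genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_core import revcomp

__all__ = [
    "VariantCall",
    "diff_genomes",
    "apply_variants",
    "classify_escape",
    "insilico_pcr",
    "compare_proteins",
]


@dataclass
class VariantCall:
    """One variant site on the reference.

    ``position`` is 1-based: for SNVs and deletions it is the first affected
    reference base; for insertions it is the reference base before which the
    alternate bases are inserted.  ``breakpoints`` (1-based inclusive,
    ``Δstart-end``) are set for structural deletions.
    """

    type: str  # SNV | insertion | deletion | structural_deletion
    position: int
    ref: str
    alt: str
    length: int
    breakpoints: tuple[int, int] | None = None

    def __post_init__(self):
        if self.type == "SNV" and (self.length != 1 or self.ref == self.alt):
            raise ValueError("SNV must have length 1 and ref != alt")
        if self.type == "structural_deletion" and self.breakpoints is None:
            self.breakpoints = (self.position, self.position + self.length - 1)

    @property
    def ref_interval(self) -> tuple[int, int]:
        """0-based half-open interval of affected reference bases (empty for
        insertions)."""
        p0 = self.position - 1
        if self.type == "insertion":
            return (p0, p0)
        return (p0, p0 + len(self.ref))


# ---------------------------------------------------------------------------
# diff_genomes: unique k-mer anchor chaining + gap alignment
# ---------------------------------------------------------------------------


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _lis_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest strictly increasing subsequence in the second coordinate of
    pairs already sorted by the first coordinate."""
    import bisect

    tails: list[int] = []
    tidx: list[int] = []
    prev = [-1] * len(pairs)
    for i, (_, a) in enumerate(pairs):
        j = bisect.bisect_left(tails, a)
        if j == len(tails):
            tails.append(a)
            tidx.append(i)
        else:
            tails[j] = a
            tidx[j] = i
        prev[i] = tidx[j - 1] if j > 0 else -1
    chain = []
    i = tidx[-1] if tidx else -1
    while i >= 0:
        chain.append(pairs[i])
        i = prev[i]
    return chain[::-1]


def _gap_events(gref: str, galt: str, ref_offset: int, structural_min: int) -> list[VariantCall]:
    """Variant calls for one inter-anchor gap (edlib NW alignment of the
    alternate gap against the reference gap)."""
    calls: list[VariantCall] = []
    if gref == galt:
        return calls
    if not gref:
        calls.append(
            VariantCall("insertion", ref_offset + 1, "", galt, len(galt))
        )
        return calls
    if not galt:
        t = "structural_deletion" if len(gref) >= structural_min else "deletion"
        calls.append(VariantCall(t, ref_offset + 1, gref, "", len(gref)))
        return calls
    cig = edlib.align(galt, gref, mode="NW", task="path")["cigar"]
    r = a = 0  # cursors into gref / galt
    i = 0
    import re

    for num, op in re.findall(r"(\d+)([=XIDM])", cig):
        n = int(num)
        if op in "=M":
            r += n
            a += n
        elif op == "X":
            for j in range(n):
                calls.append(
                    VariantCall("SNV", ref_offset + r + j + 1, gref[r + j], galt[a + j], 1)
                )
            r += n
            a += n
        elif op == "D":  # present in reference, absent in alternate
            t = "structural_deletion" if n >= structural_min else "deletion"
            calls.append(VariantCall(t, ref_offset + r + 1, gref[r : r + n], "", n))
            r += n
        elif op == "I":  # present in alternate only
            calls.append(VariantCall("insertion", ref_offset + r + 1, "", galt[a : a + n], n))
            a += n
    return calls


def diff_genomes(
    reference: str,
    variant: str,
    k: int = 21,
    structural_min: int = 50,
) -> tuple[list[VariantCall], bool]:
    """Call variant sites between two collinear genomes.

    Returns ``(calls, rearranged)`` where ``rearranged`` is True when shared
    unique-k-mer anchors are substantially out of order (results are then
    partial).  Each contiguous event counts as one site.
    """
    if reference == variant:
        return [], False
    ref_k = _unique_kmers(reference, k)
    alt_k = _unique_kmers(variant, k)
    shared = sorted(
        ((rp, alt_k[km]) for km, rp in ref_k.items() if km in alt_k),
        key=lambda t: t[0],
    )
    chain = _lis_chain(shared) if shared else []
    rearranged = bool(shared) and len(chain) < 0.9 * len(shared)

    # merge chained anchors into contiguously covered blocks of constant offset
    blocks: list[tuple[int, int, int]] = []  # (ref_start, alt_start, length)
    for rp, ap in chain:
        if blocks:
            r0, a0, ln = blocks[-1]
            if ap - rp == a0 - r0 and rp <= r0 + ln:
                blocks[-1] = (r0, a0, max(ln, rp + k - r0))
                continue
        blocks.append((rp, ap, k))

    calls: list[VariantCall] = []
    pr = pa = 0
    for r0, a0, ln in blocks:
        # neighboring blocks may overlap when an event duplicates flanking
        # sequence; trim the later block so cursors never move backwards
        shift = max(pr - r0, pa - a0, 0)
        r0, a0, ln = r0 + shift, a0 + shift, ln - shift
        if ln <= 0:
            continue
        calls += _gap_events(reference[pr:r0], variant[pa:a0], pr, structural_min)
        pr, pa = r0 + ln, a0 + ln
    calls += _gap_events(reference[pr:], variant[pa:], pr, structural_min)
    calls = [normalize_left(reference, c) for c in calls]
    calls.sort(key=lambda c: c.position)
    return calls, rearranged


def normalize_left(reference: str, call: VariantCall) -> VariantCall:
    """Left-align an indel to its canonical leftmost-equivalent position.

    Indels inside repeated sequence have several equivalent placements; both
    the caller and the generators report the leftmost one so representations
    are comparable.
    """
    if call.type in ("deletion", "structural_deletion"):
        s = call.position - 1
        e = s + len(call.ref)
        while s > 0 and reference[s - 1] == reference[e - 1]:
            s -= 1
            e -= 1
        bp = (s + 1, e) if call.type == "structural_deletion" else None
        return VariantCall(call.type, s + 1, reference[s:e], "", call.length, bp)
    if call.type == "insertion":
        p = call.position - 1
        alt = call.alt
        while p > 0 and reference[p - 1] == alt[-1]:
            alt = alt[-1] + alt[:-1]
            p -= 1
        return VariantCall("insertion", p + 1, "", alt, call.length)
    return call


def apply_variants(reference: str, calls: list[VariantCall]) -> str:
    """Reconstruct the variant genome from the reference and its calls."""
    out = reference
    for c in sorted(calls, key=lambda c: c.position, reverse=True):
        s, e = c.ref_interval
        if out[s:e] != c.ref:
            raise ValueError(f"call at {c.position} does not match the reference")
        out = out[:s] + c.alt + out[e:]
    return out


# ---------------------------------------------------------------------------
# Escape classification
# ---------------------------------------------------------------------------


def _indel_span(reference: str | None, call: VariantCall) -> tuple[int, int, int]:
    """0-based (left start, right-shifted end, max right shift) of all
    equivalent placements of an indel.  Without a reference only the stored
    (left-aligned) placement is known."""
    vs, ve = call.ref_interval
    if reference is None or call.type == "SNV":
        return vs, ve, 0
    if call.type == "insertion":
        q, alt = vs, call.alt
        while q < len(reference) and reference[q] == alt[0]:
            alt = alt[1:] + alt[0]
            q += 1
        return vs, q, q - vs
    # deletion / structural deletion
    s2, e2 = vs, ve
    while e2 < len(reference) and reference[e2] == reference[s2]:
        s2 += 1
        e2 += 1
    return vs, e2, s2 - vs


def classify_escape(
    variants: list[VariantCall],
    matches,
    config=None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Classify variant calls against protospacer loci.

    ``matches`` is an iterable of objects (or a DataFrame) carrying
    ``protospacer_id``/``spacer_id``, ``start``, ``end`` (0-based half-open
    reference coordinates) and ``strand``.  Classes, in priority order:
    deletion spanning the whole protospacer, PAM mutation, seed substitution,
    seed frameshift (indel at seed positions), other in-protospacer change,
    none.  When ``reference`` is given, an indel inside repeated sequence is
    matched against every equivalent placement, not only its left-aligned
    representation.
    """
    from .io_core import RunConfig

    cfg = config or RunConfig()
    seed_lo, seed_hi = cfg.seed_region

    if isinstance(matches, pd.DataFrame):
        items = list(matches.itertuples())
    else:
        items = list(matches)

    rows = []
    for m in items:
        pid = getattr(m, "protospacer_id", None) or getattr(m, "spacer_id", None)
        s, e, strand = int(m.start), int(m.end), m.strand
        if strand == "+":
            pam_iv = (s - 2, s)
            seed_iv = {s + p - 1 for p in range(seed_lo, seed_hi + 1)}
        else:
            pam_iv = (e, e + 2)
            seed_iv = {e - p for p in range(seed_lo, seed_hi + 1)}

        cls = "none"
        detail = ""

        for v in variants:
            if v.type not in ("deletion", "structural_deletion"):
                continue
            vs, ve = v.ref_interval
            _lo, _hi, max_shift = _indel_span(reference, v)
            # some placement [vs+k, ve+k) contains the protospacer?
            k_lo = max(0, e - ve)
            k_hi = min(max_shift, s - vs)
            if k_lo <= k_hi:
                cls, detail = "deletion_spanning_protospacer", f"Δ{vs + 1}-{ve}"
                break
        if cls == "none":
            for v in variants:
                vs, _ve = v.ref_interval
                if v.type == "SNV" and pam_iv[0] <= vs < pam_iv[1]:
                    cls, detail = "pam_mutation", f"{v.ref}{v.position}{v.alt}"
                    break
        if cls == "none":
            for v in variants:
                vs, ve = v.ref_interval
                if v.type == "SNV" and vs in seed_iv:
                    cls, detail = "seed_substitution", f"{v.ref}{v.position}{v.alt}"
                    break
                if v.type in ("insertion", "deletion"):
                    lo, hi, _sh = _indel_span(reference, v)
                    if v.type == "insertion":
                        hit = any(lo <= q <= hi for q in seed_iv)
                    else:
                        hit = any(lo <= q < hi for q in seed_iv)
                    if hit:
                        cls, detail = "seed_frameshift", f"{v.type}@{v.position}"
                        break
        if cls == "none":
            for v in variants:
                lo, hi, _sh = _indel_span(reference, v)
                hit = lo < e and hi > s if v.type != "insertion" else s < lo <= e or s < hi <= e
                if hit:
                    cls, detail = "non_seed_change", f"{v.type}@{v.position}"
                    break
        rows.append((pid, cls, detail))
    return pd.DataFrame(rows, columns=["protospacer_id", "escape_class", "detail"])


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def insilico_pcr(
    genome: str, fwd: str, rev: str, max_product: int = 5000
) -> list[tuple[int, int, int]]:
    """Exact-match PCR products as (start, end, length), 1-based inclusive.

    A product pairs a forward-primer site with a downstream reverse-primer
    binding site (the reverse complement of ``rev`` on the same strand); both
    primer orientations are tried.  Products longer than ``max_product`` are
    discarded.
    """
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    products = []
    for p1, p2 in ((fwd, rev), (rev, fwd)):
        starts = _find_all(genome, p1)
        ends = _find_all(genome, revcomp(p2))
        for s in starts:
            for e in ends:
                end = e + len(p2)
                if end <= s + len(p1):
                    continue
                length = end - s
                if length <= max_product:
                    products.append((s + 1, end, length))
    return sorted(set(products))


# ---------------------------------------------------------------------------
# Protein comparison
# ---------------------------------------------------------------------------


def compare_proteins(ref: str, alt: str) -> tuple[float, float, int]:
    """Global (end-gap-free) BLOSUM62 alignment of two proteins.

    Returns (percent identity, percent similarity, C-terminal loss in
    residues).  Similarity counts positively scoring aligned pairs; the
    C-terminal loss is the number of reference residues beyond the last one
    aligned to a non-gap.
    """
    if not ref or not alt:
        raise ValueError("protein sequences must be non-empty")
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    aln = aligner.align(ref, alt)[0]
    matrix = aligner.substitution_matrix
    a, b = str(aln[0]), str(aln[1])
    n = len(a)
    ident = sim = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
        if matrix[x, y] > 0:
            sim += 1
    last_ref_aligned = aln.aligned[0][-1][1] if len(aln.aligned[0]) else 0
    c_loss = len(ref) - last_ref_aligned
    return 100.0 * ident / n, 100.0 * sim / n, c_loss
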