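"""File formats, run configuration, seeded randomness and provenance logging.

Internal coordinates are 0-based half-open throughout the package; GFF3 I/O
converts to and from the standard 1-based inclusive convention at the file
boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FormatError",
    "ConfigError",
    "RunConfig",
    "GeneFeature",
    "AnnotationSet",
    "AnnotatedGenome",
    "CrisprArray",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "load_config",
    "stage_rng",
    "revcomp",
]

logger = logging.getLogger("spacerscope")

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConfigError(ValueError):
    """A run configuration is invalid or contains unknown keys."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_PAM_CONVENTIONS = ("five_prime_of_protospacer", "three_prime_of_protospacer")


@dataclass(frozen=True)
class RunConfig:
    """Fixed constants of a pipeline run.

    ``seed_region`` is a 1-based inclusive position range counted from the
    PAM-proximal end of the protospacer.  ``handle_len`` is the length of the
    repeat-derived 5' crRNA tag (the last ``handle_len`` nt of the repeat).
    """

    seed: int = 0
    pam_convention: str = "five_prime_of_protospacer"
    pam_canonical: str = "GG"
    seed_region: tuple[int, int] = (1, 8)
    max_mismatches: int = 5
    min_trimmed_junction_len: int = 12
    repeat_anchor_len: int = 5
    handle_len: int = 8
    sus_sample_size: int = 500
    sus_trials: int = 1000
    detection_limits: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pam_convention not in _PAM_CONVENTIONS:
            raise ConfigError(f"unknown pam_convention {self.pam_convention!r}")
        if len(self.pam_canonical) != 2 or not set(self.pam_canonical) <= DNA_ALPHABET:
            raise ConfigError("pam_canonical must be a 2-letter DNA string")
        lo, hi = self.seed_region
        if lo < 1 or hi < lo:
            raise ConfigError("seed_region must be a 1-based range with lo <= hi")
        for name in (
            "max_mismatches",
            "min_trimmed_junction_len",
            "repeat_anchor_len",
            "handle_len",
            "sus_sample_size",
            "sus_trials",
        ):
            if getattr(self, name) < (1 if name.startswith("sus") else 0):
                raise ConfigError(f"{name} out of range")

    def validate_against(self, spacer_length: int | None = None, repeat_length: int | None = None):
        """Check constraints that depend on the sequences in play."""
        if spacer_length is not None and self.seed_region[1] > spacer_length:
            raise ConfigError("seed_region extends beyond spacer length")
        if repeat_length is not None:
            if self.repeat_anchor_len > repeat_length:
                raise ConfigError("repeat_anchor_len exceeds repeat length")
            if self.handle_len > repeat_length:
                raise ConfigError("handle_len exceeds repeat length")


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON config, applying defaults for absent keys.

    Unknown keys raise :class:`ConfigError` so that typos cannot silently
    fall back to defaults.  The resolved config is echoed to the log.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a JSON object")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed_region" in doc:
        doc["seed_region"] = tuple(doc["seed_region"])
    cfg = RunConfig(**doc)
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream for a named pipeline stage.

    Streams are derived from (seed, crc32(stage)) so reproducibility does not
    depend on the order in which stages execute.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    expression: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    genome_id: str
    genes: list[GeneFeature]

    def annotated_fraction(self, genome_length: int) -> float:
        """Fraction of genome bases covered by at least one gene."""
        if genome_length <= 0:
            raise ValueError("genome_length must be positive")
        covered = np.zeros(genome_length, dtype=bool)
        for g in self.genes:
            covered[g.start : g.end] = True
        return float(covered.sum()) / genome_length

    def overlapping(self, start: int, end: int) -> list[GeneFeature]:
        return [g for g in self.genes if g.start < end and g.end > start]


@dataclass
class AnnotatedGenome:
    genome_id: str
    sequence: str
    annotation: AnnotationSet

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CrisprArray:
    """A repeat-spacer array: R s1 R s2 ... sN R."""

    array_id: str
    repeat: str
    spacers: list[str]
    start: int | None = None  # genomic placement on the + strand, 0-based
    strand: str = "+"

    @property
    def sequence(self) -> str:
        parts = [self.repeat]
        for sp in self.spacers:
            parts.append(sp)
            parts.append(self.repeat)
        return "".join(parts)

    def __len__(self) -> int:
        return len(self.repeat) * (len(self.spacers) + 1) + sum(
            len(s) for s in self.spacers
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ordered (id, upper-cased sequence) pairs.

    Sequences must be over {A,C,G,T,N} (case-insensitive).  Malformed headers
    and empty sequences raise :class:`FormatError` naming the line number.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {header_line}: record {header!r} has an empty sequence")
        records.append((header, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                header, header_line, chunks = name, lineno, []
            else:
                if header is None:
                    raise FormatError(f"line {lineno}: sequence before any header")
                seq = line.upper()
                bad = set(seq) - DNA_ALPHABET
                if bad:
                    raise FormatError(
                        f"line {lineno}: invalid characters {sorted(bad)} in record {header!r}"
                    )
                chunks.append(seq)
    flush()
    return records


def write_fasta(path: str | Path, records, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene features with an optional expr= attribute)
# ---------------------------------------------------------------------------


def read_gff(path: str | Path, expression_key: str = "expr") -> AnnotationSet:
    """Read gene features from GFF3 into 0-based half-open coordinates."""
    genes: list[GeneFeature] = []
    genome_id = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"line {lineno}: expected 9 GFF columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"line {lineno}: end < start")
            if strand not in "+-":
                raise FormatError(f"line {lineno}: unknown strand {strand!r}")
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            expr = attr_map.get(expression_key)
            genes.append(
                GeneFeature(
                    gene_id=attr_map.get("ID", f"gene_{lineno}"),
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    expression=float(expr) if expr is not None else None,
                )
            )
            genome_id = seqid
    return AnnotationSet(genome_id=genome_id, genes=genes)


def write_gff(path: str | Path, annotation: AnnotationSet, expression_key: str = "expr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            attrs = f"ID={g.gene_id}"
            if g.expression is not None:
                attrs += f";{expression_key}={g.expression:.6g}"
            fh.write(
                "\t".join(
                    [
                        annotation.genome_id,
                        "spacerscope",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
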