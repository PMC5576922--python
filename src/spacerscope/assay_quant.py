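"""Quantification of wet-lab readouts.

Log-transformed cfu/mL with detection-limit censoring, efficiency of
plaquing (EOP), Most Probable Number (MPN) titers by direct likelihood
maximization under the Poisson single-hit model, and the relative
protospacer transcript level (log10 RNA reads / log10 DNA reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "CensoredValue",
    "DilutionLevel",
    "MpnResult",
    "log_cfu",
    "eop",
    "mpn",
    "relative_transcript_level",
    "TMTC",
]

TMTC = "TMTC"  # plate sentinel: too many colonies to count


@dataclass
class CensoredValue:
    value: float | None
    censored: str = "none"  # none | lower | upper

    @property
    def is_censored(self) -> bool:
        return self.censored != "none"


def log_cfu(
    count,
    plated_volume_ml: float,
    dilution: float,
    detection_limit: float | None = None,
) -> CensoredValue:
    """log10 cfu/mL from a plate count.

    ``dilution`` is the dilution factor of the plated material (e.g. 1e-3).
    A zero count returns the detection limit with a lower-censor flag; the
    TMTC sentinel returns an upper-censored result with no numeric value.
    """
    if plated_volume_ml <= 0 or dilution <= 0:
        raise ValueError("volume and dilution must be positive")
    if count == TMTC:
        return CensoredValue(None, "upper")
    count = float(count)
    if count < 0:
        raise ValueError("negative colony count")
    if count == 0:
        if detection_limit is None or detection_limit <= 0:
            raise ValueError("zero count requires a positive detection limit")
        return CensoredValue(math.log10(detection_limit), "lower")
    return CensoredValue(math.log10(count / (plated_volume_ml * dilution)), "none")


@dataclass
class EopResult:
    value: float
    bound: str = "eq"  # eq | le (censored test titer)


def eop(pfu_test: float, pfu_ref: float, test_censored: bool = False) -> EopResult:
    """Efficiency of plaquing: fold change of test titer over reference."""
    if pfu_ref <= 0:
        raise ValueError("reference titer must be positive")
    if pfu_test < 0:
        raise ValueError("test titer must be non-negative")
    return EopResult(pfu_test / pfu_ref, "le" if test_censored else "eq")


@dataclass
class DilutionLevel:
    dilution: float  # dilution factor of the inoculum, e.g. 1e-2
    tubes: int
    positives: int
    volume_ml: float  # inoculum volume per tube

    def __post_init__(self):
        if not 0 <= self.positives <= self.tubes:
            raise ValueError("positives must lie in [0, tubes]")
        if self.dilution <= 0 or self.volume_ml <= 0:
            raise ValueError("dilution and volume must be positive")

    @property
    def sample_volume(self) -> float:
        """Undiluted sample volume delivered per tube (mL)."""
        return self.dilution * self.volume_ml


@dataclass
class MpnResult:
    value: float  # concentration per mL
    censored: str = "none"  # none | upper (all negative) | lower (all positive)
    log_likelihood: float | None = None


def _loglik(c: float, levels: list[DilutionLevel]) -> float:
    ll = 0.0
    for lv in levels:
        p = -math.expm1(-c * lv.sample_volume)  # 1 - exp(-c v)
        if lv.positives > 0:
            if p <= 0:
                return -math.inf
            ll += lv.positives * math.log(p)
        neg = lv.tubes - lv.positives
        if neg > 0:
            ll += neg * (-c * lv.sample_volume)
    return ll


def mpn(levels: list[DilutionLevel], detection_limit: float | None = None) -> MpnResult:
    """Most Probable Number titer: maximum-likelihood concentration under
    P(positive tube at level i) = 1 - exp(-c * v_i).

    All tubes negative -> 0, upper-censored at ``detection_limit``.
    All tubes positive at every level -> lower-bound-only result: the
    concentration at which an all-positive outcome at the most dilute level
    has probability one half.
    """
    if not levels:
        raise ValueError("at least one dilution level required")
    dil = [lv.dilution for lv in levels]
    if sorted(dil) != dil and sorted(dil, reverse=True) != dil:
        raise ValueError("dilution factors must be strictly ordered")
    total_pos = sum(lv.positives for lv in levels)
    total = sum(lv.tubes for lv in levels)
    if total_pos == 0:
        return MpnResult(0.0, "upper" if detection_limit else "none")
    if total_pos == total:
        lv = min(levels, key=lambda x: x.sample_volume)
        c_lb = -math.log(1.0 - 0.5 ** (1.0 / lv.tubes)) / lv.sample_volume
        return MpnResult(c_lb, "lower")
    res = minimize_scalar(
        lambda lc: -_loglik(10.0**lc, levels),
        bounds=(-12.0, 15.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    c = 10.0 ** float(res.x)
    return MpnResult(c, "none", -float(res.fun))


@dataclass
class TranscriptLevelResult:
    construct_id: str
    rna_reads: int
    dna_reads: int
    relative_incidence: float | None
    defined: bool


def relative_transcript_level(
    construct_id: str, rna_reads: int, dna_reads: int, floor: int = 10
) -> TranscriptLevelResult:
    """Relative protospacer RNA incidence: log10(RNA reads) / log10(DNA reads).

    Undefined (flagged) when either count is below ``floor``.  Comparable
    across constructs within one experiment, but not a transcript-to-template
    ratio: doubling both counts changes the value.
    """
    if rna_reads < floor or dna_reads < floor:
        return TranscriptLevelResult(construct_id, rna_reads, dna_reads, None, False)
    return TranscriptLevelResult(
        construct_id,
        rna_reads,
        dna_reads,
        math.log10(rna_reads) / math.log10(dna_reads),
        True,
    )
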