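"""Completeness classification and the nine-code quality scheme.

Draft-assembly gaps (N runs) translate to X residues; the fraction of X in
the central repeat domain drives both the completeness call and the NNN-band
quality codes.  Structural defects (frameshift, premature stop, missing
start/stop) and severe truncation take precedence over the NNN bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .domains import DomainPartition, GlyLoop
from .records import DefectFlags, ProteinRecord

# Completeness thresholds on the central-domain unknown fraction.
COMPLETE_MAX_UNKNOWN = 0.15
PARTIAL_MAX_UNKNOWN = 0.70

# Default precedence among structural-defect codes (most severe first):
# truncation below 10% of the reference, frameshift, premature stop,
# missing start, missing stop.  The table the scheme comes from prints a
# single code per gene but no tie-break, so this order is a convention.
DEFAULT_PRECEDENCE: tuple[int, ...] = (9, 7, 8, 6, 5)

MIN_RELATIVE_LENGTH = 0.10


@dataclass(frozen=True)
class QualityAssessment:
    id: str
    completeness: str  # complete | partial | fragmentary
    code: int
    central_unknown_fraction: float
    flags: DefectFlags
    relative_length: float


def central_unknown_fraction(record: ProteinRecord, partition: DomainPartition) -> float:
    """Fraction of unknown (X) residues within the central span; 0 if empty."""
    a, b = partition.central
    if partition.length != len(record):
        raise ValueError("partition does not tile the record")
    if b == a:
        return 0.0
    central = record.residues[a:b]
    return central.count("X") / len(central)


def classify_completeness(
    record: ProteinRecord,
    partition: DomainPartition,
    loops: Sequence[GlyLoop],
) -> str:
    """Classify a record as complete, partial or fragmentary.

    Complete: both termini free of X, at least three X-free loops in the
    central domain, and central unknown fraction <= 15%.  Partial: the first
    two conditions hold with the fraction in (15%, 70%).  Fragmentary
    otherwise.  ``loops`` must be detected on the central span with the
    X-exclusion rule so every loop passed in is X-free.
    """
    a, b = partition.central
    termini_clean = (
        "X" not in record.residues[: a] and "X" not in record.residues[b:]
    )
    clean_loops = sum(1 for lp in loops if "X" not in record.residues[a + lp.start : a + lp.end])
    frac = central_unknown_fraction(record, partition)
    if termini_clean and clean_loops >= 3:
        if frac <= COMPLETE_MAX_UNKNOWN:
            return "complete"
        if frac < PARTIAL_MAX_UNKNOWN:
            return "partial"
    return "fragmentary"


def assign_quality_code(
    record: ProteinRecord,
    partition: DomainPartition,
    flags: DefectFlags,
    reference_length: int,
    precedence: tuple[int, ...] = DEFAULT_PRECEDENCE,
) -> int:
    """Assign the 1-9 quality code; first matching defect code wins.

    Codes 5-9 flag structural problems (9: under 10% of the reference
    orthologue length; 7: frameshift; 8: premature stop; 6: missing start;
    5: missing stop) in ``precedence`` order.  Otherwise the NNN band on the
    central unknown fraction f applies: 1 if f = 0, 2 if f <= 0.15, 3 if
    f <= 0.75, 4 above.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    rel = len(record) / reference_length
    triggers = {
        9: rel < MIN_RELATIVE_LENGTH,
        7: flags.frameshift,
        8: flags.premature_stop,
        6: flags.missing_start,
        5: flags.missing_stop,
    }
    for code in precedence:
        if triggers.get(code, False):
            return code
    f = central_unknown_fraction(record, partition)
    if f == 0.0:
        return 1
    if f <= 0.15:
        return 2
    if f <= 0.75:
        return 3
    return 4


def assess(
    record: ProteinRecord,
    partition: DomainPartition,
    loops: Sequence[GlyLoop],
    flags: DefectFlags,
    reference_length: int,
) -> QualityAssessment:
    """Bundle completeness, code, unknown fraction and flags for one record.

    A record carrying any structural defect flag is never complete or
    partial: sequences entered downstream analyses only with both termini,
    no premature stop and no frameshift, so defects demote to fragmentary.
    """
    completeness = classify_completeness(record, partition, loops)
    if flags.any():
        completeness = "fragmentary"
    return QualityAssessment(
        id=record.id,
        completeness=completeness,
        code=assign_quality_code(record, partition, flags, reference_length),
        central_unknown_fraction=central_unknown_fraction(record, partition),
        flags=flags,
        relative_length=len(record) / reference_length,
    )
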