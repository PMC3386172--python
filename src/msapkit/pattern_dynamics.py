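"""Control-to-stress methylation transition patterns.

Comparing the (EH, EM) digest pair of a locus between a control and a
stressed sample gives a 4-bit quad (control EH, control EM, stress EH,
stress EM) with sixteen possible banding patterns, conventionally labelled
A-P and grouped by what the transition means for cytosine methylation:

* A-D  — no change: the digest pair is identical in both conditions.
* E-J  — demethylation: bands gained under stress, i.e. stress digests cut
  sites that were protected by methylation in the control.
* K-P  — methylation: bands lost under stress.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import EmptyInputError, InvalidObservationError
from .msap_core import BandObservation

__all__ = [
    "PATTERN_CLASSES",
    "PATTERN_GROUPS",
    "GROUP_NAMES",
    "PatternRecord",
    "PatternSummary",
    "classify_pattern",
    "pattern_summary",
    "transitions_from_bands",
]

logger = logging.getLogger(__name__)

Quad = tuple[int, int, int, int]

# quad -> class letter; the canonical 16-row lookup
# (control EH, control EM, stress EH, stress EM).
PATTERN_CLASSES: dict[Quad, str] = {
    (1, 0, 1, 0): "A",
    (0, 1, 0, 1): "B",
    (1, 1, 1, 1): "C",
    (0, 0, 0, 0): "D",
    (1, 0, 1, 1): "E",
    (0, 1, 1, 1): "F",
    (0, 0, 1, 1): "G",
    (0, 1, 1, 0): "H",
    (0, 0, 1, 0): "I",
    (0, 0, 0, 1): "J",
    (1, 1, 1, 0): "K",
    (1, 1, 0, 1): "L",
    (1, 1, 0, 0): "M",
    (1, 0, 0, 1): "N",
    (1, 0, 0, 0): "O",
    (0, 1, 0, 0): "P",
}

GROUP_NAMES = ("no_change", "demethylation", "methylation")

PATTERN_GROUPS: dict[str, str] = {
    **{k: "no_change" for k in "ABCD"},
    **{k: "demethylation" for k in "EFGHIJ"},
    **{k: "methylation" for k in "KLMNOP"},
}


@dataclass(frozen=True)
class PatternRecord:
    """One locus's control-to-stress transition, classified."""

    locus_id: str
    quad: Quad
    klass: str
    group: str


def classify_pattern(quad: Sequence[int], locus_id: str = "<anonymous>") -> PatternRecord:
    """Classify a 4-bit banding quad into its class A-P and group."""
    key = tuple(quad)
    if key not in PATTERN_CLASSES:
        raise InvalidObservationError(
            f"locus {locus_id!r}: quad {quad!r} is not a 4-tuple of 0/1"
        )
    klass = PATTERN_CLASSES[key]
    return PatternRecord(locus_id=locus_id, quad=key, klass=klass,
                         group=PATTERN_GROUPS[klass])


def transitions_from_bands(
    control: BandObservation, stress: BandObservation
) -> PatternRecord | None:
    """Join a locus's control and stress observations into a PatternRecord.

    Returns None (with a logged warning) when the locus ids disagree or
    either observation is missing; callers count such skips in an exclusion
    report rather than failing the run.
    """
    if control.locus_id != stress.locus_id:
        logger.warning(
            "locus mismatch: control %r vs stress %r; skipped",
            control.locus_id, stress.locus_id,
        )
        return None
    if control.missing or stress.missing:
        logger.warning("locus %r has a missing digest call; skipped", control.locus_id)
        return None
    return classify_pattern(
        (control.eh, control.em, stress.eh, stress.em), control.locus_id
    )


@dataclass(frozen=True)
class PatternSummary:
    """Class counts A-P, group counts/percentages, and the grand total.

    Group percentages use the all-sixteen-class grand total as denominator
    (bands in any pattern, including the doubly-absent class D).
    """

    class_counts: dict[str, int]
    group_counts: dict[str, int]
    group_pcts: dict[str, float]
    grand_total: int
    n_excluded: int = 0


def pattern_summary(
    records: Iterable[PatternRecord | None],
) -> PatternSummary:
    """Summarise classified loci into class counts and group percentages.

    ``None`` entries (skipped loci from :func:`transitions_from_bands`) are
    tolerated and reported via ``n_excluded``.
    """
    class_counts = {k: 0 for k in "ABCDEFGHIJKLMNOP"}
    n_excluded = 0
    for rec in records:
        if rec is None:
            n_excluded += 1
            continue
        class_counts[rec.klass] += 1
    grand_total = sum(class_counts.values())
    if grand_total == 0:
        raise EmptyInputError("no classified loci to summarise")
    group_counts = {g: 0 for g in GROUP_NAMES}
    for klass, n in class_counts.items():
        group_counts[PATTERN_GROUPS[klass]] += n
    group_pcts = {g: 100.0 * n / grand_total for g, n in group_counts.items()}
    if n_excluded:
        logger.info("pattern summary excluded %d loci", n_excluded)
    return PatternSummary(
        class_counts=class_counts,
        group_counts=group_counts,
        group_pcts=group_pcts,
        grand_total=grand_total,
        n_excluded=n_excluded,
    )
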