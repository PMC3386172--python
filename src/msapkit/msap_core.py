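"""MSAP band typing and methylation-percentage summaries.

MSAP (methylation-sensitive amplified polymorphism) scores each locus in two
parallel digests of the same DNA: EcoRI+HpaII (EH) and EcoRI+MspI (EM).
HpaII and MspI are isoschizomers of the 5'-CCGG-3' site with different
methylation sensitivity, so the presence/absence combination of a band across
the two digests reports the methylation state of that CCGG site:

======  ====  ====  ==========================================
Type     EH    EM   Interpretation
======  ====  ====  ==========================================
I         1     1   unmethylated
II        1     0   hemimethylated (one strand, external C)
III       0     1   full methylation of the internal (CG) C
IV        0     0   full methylation at both cytosines, or
                    band absence from sequence change
======  ====  ====  ==========================================

Three headline percentages summarise a sample: total MSAP methylation
``(II+III+IV)/total``, fully methylated ``(III+IV)/total`` and hemimethylated
``II/total``, each times 100.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import EmptyInputError, InvalidObservationError

__all__ = [
    "BandObservation",
    "BandType",
    "BandTypeCounts",
    "MethylationSummary",
    "classify_band",
    "count_band_types",
    "methylation_summary",
    "round_display",
]


class BandType(enum.Enum):
    """The four presence/absence combinations across the EH and EM digests."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


@dataclass(frozen=True)
class BandObservation:
    """Presence/absence of one locus in both digests of one sample/condition.

    Parameters
    ----------
    locus_id
        Locus identifier, conventionally primer combination plus fragment
        size (e.g. ``"EACG-MAATC_132"``).
    eh
        Band presence (0/1) in the EcoRI+HpaII digest.
    em
        Band presence (0/1) in the EcoRI+MspI digest.
    missing
        True when either digest is unscored; missing observations are
        excluded from every count and denominator.
    """

    locus_id: str
    eh: int
    em: int
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            for name, value in (("eh", self.eh), ("em", self.em)):
                if value not in (0, 1):
                    raise InvalidObservationError(
                        f"locus {self.locus_id!r}: {name}={value!r} is not 0 or 1"
                    )


# (eh, em) -> band type; total over {0,1}^2.
_BAND_LOOKUP = {
    (1, 1): BandType.I,
    (1, 0): BandType.II,
    (0, 1): BandType.III,
    (0, 0): BandType.IV,
}


def classify_band(eh: int, em: int, locus_id: str = "<anonymous>") -> BandType:
    """Map one (EH, EM) presence pair to its band type I-IV.

    Raises
    ------
    InvalidObservationError
        If either flag is not exactly 0 or 1.
    """
    try:
        return _BAND_LOOKUP[(eh, em)]
    except (KeyError, TypeError):
        raise InvalidObservationError(
            f"locus {locus_id!r}: band calls must be 0/1, got eh={eh!r}, em={em!r}"
        ) from None


@dataclass(frozen=True)
class BandTypeCounts:
    """Non-negative counts of band types I-IV for one sample/condition."""

    n1: int
    n2: int
    n3: int
    n4: int
    n_excluded: int = 0  # missing observations dropped before counting

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n1, self.n2, self.n3, self.n4)


def count_band_types(observations: Iterable[BandObservation]) -> BandTypeCounts:
    """Tally band types over the non-missing observations.

    Raises
    ------
    EmptyInputError
        If no non-missing observation remains (downstream percentages would
        be undefined).
    """
    tally = {t: 0 for t in BandType}
    n_excluded = 0
    for obs in observations:
        if obs.missing:
            n_excluded += 1
            continue
        tally[classify_band(obs.eh, obs.em, obs.locus_id)] += 1
    counts = BandTypeCounts(
        tally[BandType.I], tally[BandType.II], tally[BandType.III], tally[BandType.IV],
        n_excluded=n_excluded,
    )
    if counts.total == 0:
        raise EmptyInputError("no non-missing band observations to count")
    return counts


@dataclass(frozen=True)
class MethylationSummary:
    """The three MSAP methylation percentages, at full precision.

    ``msap_pct == full_pct + hemi_pct`` holds exactly (before any display
    rounding) because the numerators partition II+III+IV.
    """

    msap_pct: float
    full_pct: float
    hemi_pct: float
    total: int


def methylation_summary(
    counts: BandTypeCounts, *, include_type_iv: bool = True
) -> MethylationSummary:
    """Compute MSAP, fully-methylated and hemimethylated percentages.

    By default type IV (absence in both digests) counts as fully methylated.
    ``include_type_iv=False`` drops type IV from numerator and denominator,
    for the reading that double absence may reflect sequence change rather
    than methylation.

    Raises
    ------
    EmptyInputError
        If the (effective) total is zero.
    """
    n1, n2, n3, n4 = counts.as_tuple()
    if not include_type_iv:
        n4 = 0
    total = n1 + n2 + n3 + n4
    if total == 0:
        raise EmptyInputError("methylation percentages undefined for zero total")
    full_pct = 100.0 * (n3 + n4) / total
    hemi_pct = 100.0 * n2 / total
    # summing the components keeps msap = full + hemi exact in floating point
    return MethylationSummary(
        msap_pct=full_pct + hemi_pct,
        full_pct=full_pct,
        hemi_pct=hemi_pct,
        total=total,
    )


def round_display(value: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used for printed tables.

    Python's built-in ``round`` is banker's rounding; gel-score tables are
    conventionally printed with 0.05 rounding up.
    """
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)
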