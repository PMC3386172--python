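"""Per-cytosine methylation calling on bisulfite-converted top strands.

Sodium bisulfite deaminates unmethylated cytosine to uracil, read as T
after PCR, while 5-methylcytosine resists conversion and stays C. Aligning
a converted top-strand read to the untreated reference therefore calls each
reference C directly: read C = methylated, read T = unmethylated, anything
else (mismatch, gap, N) = ambiguous.

Each call carries its sequence context on the reference — CG, CHG or CHH
(H = A, T or C) — because plant methyltransferases maintain the three
contexts through distinct pathways and their levels are reported separately.
Context is a property of the reference alone, never of the read.

Alignment is conversion-aware: reference C against read T is scored as a
match, so fully converted reads still align cleanly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import (
    EmptyInputError,
    IncompatibleReportError,
    InvalidPositionError,
    LowQualityAlignmentError,
)

__all__ = [
    "ReferenceSeq",
    "BisulfiteRead",
    "SiteCall",
    "ContextMethylationReport",
    "ConditionComparison",
    "classify_context",
    "make_aligner",
    "align_converted",
    "call_sites",
    "consensus_calls",
    "methylation_percent",
    "estimate_conversion_rate",
    "compare_conditions",
]

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
_H = {"A", "T", "C"}


@dataclass(frozen=True)
class ReferenceSeq:
    """Untreated top-strand reference; positions are 1-based."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not seq:
            raise EmptyInputError(f"reference {self.id!r} is empty")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise InvalidPositionError(
                f"reference {self.id!r} contains non-DNA characters {sorted(bad)}")
        object.__setattr__(self, "seq", seq)


@dataclass(frozen=True)
class BisulfiteRead:
    """A bisulfite-converted top-strand consensus sequence."""

    id: str
    seq: str
    sample: str = ""
    tissue: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise EmptyInputError(f"read {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())


@dataclass(frozen=True)
class SiteCall:
    """Methylation call for one reference cytosine (1-based position)."""

    ref_pos: int
    ref_base: str
    read_base: str
    call: str      # methylated | unmethylated | ambiguous
    context: str   # CG | CHG | CHH | undefined


def classify_context(ref: ReferenceSeq, pos: int) -> str:
    """Context of the cytosine at 1-based ``pos``: CG, CHG, CHH or undefined.

    CG if the next base is G; CHG if the next base is H and the one after is
    G; CHH if both following bases are H. A C too close to the 3' end to
    resolve its context, or one whose needed neighbours are N, is undefined.
    """
    seq = ref.seq
    if not 1 <= pos <= len(seq):
        raise InvalidPositionError(f"{ref.id}: position {pos} out of range 1..{len(seq)}")
    if seq[pos - 1] != "C":
        raise InvalidPositionError(
            f"{ref.id}: base at position {pos} is {seq[pos - 1]}, not C")
    nxt = seq[pos] if pos < len(seq) else None
    if nxt == "G":
        return "CG"
    if nxt not in _H:  # None (end of sequence) or N
        return "undefined"
    nxt2 = seq[pos + 1] if pos + 1 < len(seq) else None
    if nxt2 == "G":
        return "CHG"
    if nxt2 in _H:
        return "CHH"
    return "undefined"


def make_aligner(
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    """Global aligner whose scoring treats reference C vs read T as a match.

    The substitution matrix is asymmetric (rows index the reference, columns
    the read); N scores 0 against everything.
    """
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                matrix[a, b] = 0.0
            elif a == b or (a == "C" and b == "T"):
                matrix[a, b] = match
            else:
                matrix[a, b] = mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_converted(
    ref: ReferenceSeq,
    read: BisulfiteRead,
    *,
    min_identity: float = 0.70,
    aligner: Align.PairwiseAligner | None = None,
) -> Align.Alignment:
    """Globally align a converted read to its reference, conversion-aware.

    Identity is computed over matchable columns (both sequences aligned,
    counting ref C / read T as identical); an alignment below
    ``min_identity`` raises :class:`LowQualityAlignmentError`.
    """
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(ref.seq, read.seq)[0]  # highest score, deterministic
    indices = alignment.indices
    both = (indices[0] >= 0) & (indices[1] >= 0)
    n_aligned = int(both.sum())
    if n_aligned == 0:
        raise LowQualityAlignmentError(
            f"{read.id} vs {ref.id}: no aligned columns")
    ref_arr = np.frombuffer(ref.seq.encode(), dtype="S1")[indices[0][both]]
    read_arr = np.frombuffer(read.seq.encode(), dtype="S1")[indices[1][both]]
    matches = (ref_arr == read_arr) | ((ref_arr == b"C") & (read_arr == b"T"))
    identity = matches.mean()
    if identity < min_identity:
        raise LowQualityAlignmentError(
            f"{read.id} vs {ref.id}: identity {identity:.2f} below {min_identity:.2f}")
    return alignment


def call_sites(alignment: Align.Alignment, ref: ReferenceSeq) -> list[SiteCall]:
    """One SiteCall per reference cytosine covered by the read.

    Read C = methylated, read T = unmethylated; a gap or any other base
    (including N) = ambiguous. Reference positions the read does not span
    are absent from the list.
    """
    indices = alignment.indices
    read_seq = alignment.sequences[1]
    calls: list[SiteCall] = []
    for col in range(indices.shape[1]):
        ri = indices[0, col]
        if ri < 0 or ref.seq[ri] != "C":
            continue
        qi = indices[1, col]
        read_base = read_seq[qi] if qi >= 0 else "-"
        if read_base == "C":
            call = "methylated"
        elif read_base == "T":
            call = "unmethylated"
        else:
            call = "ambiguous"
        calls.append(SiteCall(
            ref_pos=int(ri) + 1,
            ref_base="C",
            read_base=read_base,
            call=call,
            context=classify_context(ref, int(ri) + 1),
        ))
    return calls


def consensus_calls(per_read_calls: Sequence[Sequence[SiteCall]]) -> list[SiteCall]:
    """Majority vote across reads at each reference position.

    Ambiguous votes are discarded; a position with no informative vote, or
    a methylated/unmethylated tie, is called ambiguous.
    """
    by_pos: dict[int, list[SiteCall]] = {}
    for calls in per_read_calls:
        for c in calls:
            by_pos.setdefault(c.ref_pos, []).append(c)
    out: list[SiteCall] = []
    for pos in sorted(by_pos):
        votes = Counter(c.call for c in by_pos[pos] if c.call != "ambiguous")
        n_m, n_u = votes["methylated"], votes["unmethylated"]
        if n_m > n_u:
            call, base = "methylated", "C"
        elif n_u > n_m:
            call, base = "unmethylated", "T"
        else:
            call, base = "ambiguous", "N"
        out.append(SiteCall(ref_pos=pos, ref_base="C", read_base=base,
                            call=call, context=by_pos[pos][0].context))
    return out


@dataclass(frozen=True)
class ContextMethylationReport:
    """Per-context methylated fractions. ``pct`` is None when no site of
    that context was called (undefined, not zero)."""

    ref_id: str
    n_methylated: dict[str, int]
    n_total: dict[str, int]
    pct: dict[str, float | None]
    overall_pct: float
    calls: tuple[SiteCall, ...] = ()


def methylation_percent(
    calls: Sequence[SiteCall], ref_id: str = ""
) -> ContextMethylationReport:
    """Percent methylated cytosines per context and overall.

    Ambiguous calls and undefined-context calls enter neither numerator nor
    denominator.
    """
    n_meth = {c: 0 for c in CONTEXTS}
    n_tot = {c: 0 for c in CONTEXTS}
    for call in calls:
        if call.call == "ambiguous" or call.context not in CONTEXTS:
            continue
        n_tot[call.context] += 1
        if call.call == "methylated":
            n_meth[call.context] += 1
    total = sum(n_tot.values())
    if total == 0:
        raise EmptyInputError("all calls ambiguous or of undefined context")
    pct = {c: (100.0 * n_meth[c] / n_tot[c] if n_tot[c] else None) for c in CONTEXTS}
    return ContextMethylationReport(
        ref_id=ref_id,
        n_methylated=n_meth,
        n_total=n_tot,
        pct=pct,
        overall_pct=100.0 * sum(n_meth.values()) / total,
        calls=tuple(calls),
    )


def estimate_conversion_rate(calls: Sequence[SiteCall]) -> float | None:
    """QC estimate of bisulfite conversion from CHH sites.

    CHH methylation is rare in plants, so the fraction of CHH sites still
    read as C approximates the non-conversion rate. Reported for QC only;
    calls are never adjusted.
    """
    chh = [c for c in calls if c.context == "CHH" and c.call != "ambiguous"]
    if not chh:
        return None
    non_converted = sum(c.call == "methylated" for c in chh)
    return 1.0 - non_converted / len(chh)


@dataclass(frozen=True)
class ConditionComparison:
    """Stress-minus-control deltas plus position-level call flips."""

    ref_id: str
    delta_pct: dict[str, float | None]
    delta_overall: float
    demethylation_events: tuple[int, ...]  # methylated -> unmethylated
    methylation_events: tuple[int, ...]    # unmethylated -> methylated


def compare_conditions(
    report_control: ContextMethylationReport,
    report_stress: ContextMethylationReport,
) -> ConditionComparison:
    """Per-context percentage deltas and per-position call changes."""
    if report_control.ref_id != report_stress.ref_id:
        raise IncompatibleReportError(
            f"reports are for different references: "
            f"{report_control.ref_id!r} vs {report_stress.ref_id!r}")
    delta = {}
    for c in CONTEXTS:
        a, b = report_control.pct[c], report_stress.pct[c]
        delta[c] = (b - a) if (a is not None and b is not None) else None
    control_by_pos = {c.ref_pos: c.call for c in report_control.calls}
    demeth, meth = [], []
    for call in report_stress.calls:
        before = control_by_pos.get(call.ref_pos)
        if before == "methylated" and call.call == "unmethylated":
            demeth.append(call.ref_pos)
        elif before == "unmethylated" and call.call == "methylated":
            meth.append(call.ref_pos)
    return ConditionComparison(
        ref_id=report_control.ref_id,
        delta_pct=delta,
        delta_overall=report_stress.overall_pct - report_control.overall_pct,
        demethylation_events=tuple(sorted(demeth)),
        methylation_events=tuple(sorted(meth)),
    )
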