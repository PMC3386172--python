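"""Relative expression by the ddCt (double-delta Ct) method.

For a target gene normalised to a reference gene (e.g. *eEF1α*):

    dCt(condition)  = Ct_target - Ct_reference
    ddCt            = dCt(stress) - dCt(control)
    fold change     = 2 ** (-ddCt)

assuming perfect doubling per cycle. Technical replicates are averaged in
Ct space before the subtractions; the fold is computed per biological
replicate, then summarised by mean and sample SD (ddof = 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError

__all__ = ["CtRecord", "FoldChangeResult", "ddct_fold", "aggregate_folds"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR threshold-cycle measurement."""

    gene: str
    sample: str
    condition: str  # "control" or "stress"
    bio_rep: int
    tech_rep: int
    ct: float

    @property
    def valid(self) -> bool:
        return math.isfinite(self.ct) and self.ct > 0


@dataclass(frozen=True)
class FoldChangeResult:
    """Stress-relative-to-control fold change with replicate dispersion."""

    gene: str
    sample: str
    fold: float          # mean over biological replicates
    sd: float            # sample SD over biological replicates (nan if n=1)
    n_bio_reps: int
    per_rep_folds: tuple[float, ...]


def ddct_fold(
    ct_target_stress: float,
    ct_ref_stress: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Fold change 2^(-ddCt) from four Ct values."""
    dct_stress = ct_target_stress - ct_ref_stress
    dct_control = ct_target_control - ct_ref_control
    return 2.0 ** (-(dct_stress - dct_control))


def _mean_ct(records: list[CtRecord]) -> float | None:
    cts = [r.ct for r in records if r.valid]
    dropped = len(records) - len(cts)
    if dropped:
        logger.warning("dropped %d invalid Ct values", dropped)
    return float(np.mean(cts)) if cts else None


def aggregate_folds(
    records: Iterable[CtRecord],
    gene: str,
    sample: str,
    *,
    reference_gene: str,
    control_label: str = "control",
    stress_label: str = "stress",
) -> FoldChangeResult:
    """Fold change of ``gene`` in ``sample``, normalised to ``reference_gene``.

    Technical replicates are averaged to one Ct per (gene, biological
    replicate, condition); a fold is computed for each biological replicate
    with complete target/reference Ct in both conditions; the result is the
    mean and sample SD over those folds.

    Raises
    ------
    InsufficientDataError
        If no biological replicate is complete.
    """
    grouped: dict[tuple[str, int, str], list[CtRecord]] = {}
    bio_reps: set[int] = set()
    for r in records:
        if r.sample != sample or r.gene not in (gene, reference_gene):
            continue
        grouped.setdefault((r.gene, r.bio_rep, r.condition), []).append(r)
        bio_reps.add(r.bio_rep)

    folds = []
    for rep in sorted(bio_reps):
        cts = {}
        for g in (gene, reference_gene):
            for cond in (control_label, stress_label):
                cts[(g, cond)] = _mean_ct(grouped.get((g, rep, cond), []))
        if any(v is None for v in cts.values()):
            logger.warning("bio rep %d of %s/%s incomplete; skipped", rep, gene, sample)
            continue
        folds.append(ddct_fold(
            cts[(gene, stress_label)], cts[(reference_gene, stress_label)],
            cts[(gene, control_label)], cts[(reference_gene, control_label)],
        ))
    if not folds:
        raise InsufficientDataError(
            f"no complete biological replicate for gene {gene!r}, sample {sample!r}")
    arr = np.array(folds)
    return FoldChangeResult(
        gene=gene,
        sample=sample,
        fold=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
        n_bio_reps=len(arr),
        per_rep_folds=tuple(folds),
    )
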