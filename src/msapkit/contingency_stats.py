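"""Independence tests for methylation level versus treatment condition.

Pearson chi-square and likelihood-ratio (G) statistics on r x c count
tables, with adjusted standardized residuals for cell-level interpretation:

    chi2 = sum (O - E)^2 / E
    G    = 2 sum O ln(O / E)          (cells with O = 0 contribute 0)
    r_ij = (O - E) / sqrt(E (1 - n_i./n)(1 - n_.j/n))

Under independence each adjusted residual is asymptotically standard
normal, so |r| > 2 flags a cell driving the association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, UndefinedResidualError
from .msap_core import BandTypeCounts

__all__ = [
    "ContingencyTable",
    "TestResult",
    "ResidualMatrix",
    "pearson_chi_square",
    "likelihood_ratio_test",
    "adjusted_residuals",
    "level_by_treatment_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise DegenerateTableError(
                f"need an r x c table with r, c >= 2, got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise DegenerateTableError("counts must be non-negative")
        if counts.sum() == 0:
            raise DegenerateTableError("grand total must be positive")
        if not self.row_labels:
            object.__setattr__(
                self, "row_labels",
                tuple(f"row{i}" for i in range(counts.shape[0])))
        if not self.col_labels:
            object.__setattr__(
                self, "col_labels",
                tuple(f"col{j}" for j in range(counts.shape[1])))

    @property
    def expected(self) -> np.ndarray:
        """Expected counts under independence, E_ij = n_i. n_.j / n."""
        counts = self.counts
        if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
            raise DegenerateTableError("zero row or column margin")
        return stats.contingency.expected_freq(counts)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str


@dataclass(frozen=True)
class ResidualMatrix:
    residuals: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]


def _chi2_contingency(table: ContingencyTable, lambda_: str, method: str,
                      yates: bool = False) -> TestResult:
    table.expected  # raises DegenerateTableError on a zero margin
    res = stats.chi2_contingency(table.counts, correction=yates, lambda_=lambda_)
    return TestResult(statistic=float(res.statistic), df=int(res.dof),
                      p_value=float(res.pvalue), method=method)


def pearson_chi_square(table: ContingencyTable, *, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence.

    No continuity correction by default; ``yates=True`` enables it for 2x2
    tables.
    """
    return _chi2_contingency(table, "pearson", "pearson", yates=yates)


def likelihood_ratio_test(table: ContingencyTable) -> TestResult:
    """Likelihood-ratio (G) test of independence, same df and tail as Pearson."""
    return _chi2_contingency(table, "log-likelihood", "likelihood_ratio")


def adjusted_residuals(table: ContingencyTable) -> ResidualMatrix:
    """Adjusted standardized residuals, asymptotically N(0,1) under independence.

    Raises
    ------
    UndefinedResidualError
        If any margin equals the grand total (the variance factor vanishes).
    """
    counts = table.counts.astype(float)
    expected = table.expected
    n = counts.sum()
    row_frac = counts.sum(axis=1) / n
    col_frac = counts.sum(axis=0) / n
    if np.any(row_frac >= 1.0) or np.any(col_frac >= 1.0):
        raise UndefinedResidualError(
            "a margin equals the grand total; adjusted residuals undefined")
    denom = np.sqrt(
        expected * (1.0 - row_frac)[:, None] * (1.0 - col_frac)[None, :])
    return ResidualMatrix(residuals=(counts - expected) / denom,
                          row_labels=table.row_labels,
                          col_labels=table.col_labels)


def level_by_treatment_table(
    control: BandTypeCounts,
    stress: BandTypeCounts,
    *,
    pool_full: bool = True,
    col_labels: tuple[str, str] = ("control", "salinity"),
) -> ContingencyTable:
    """Build the methylation-level x treatment table from band-type counts.

    Default rows pool types III and IV into one "fully methylated" level,
    giving a 3x2 table (unmethylated / hemimethylated / fully methylated by
    control / stress); ``pool_full=False`` keeps III and IV separate (4x2).
    """
    if pool_full:
        rows = ["unmethylated", "hemimethylated", "fully_methylated"]
        counts = [
            [control.n1, stress.n1],
            [control.n2, stress.n2],
            [control.n3 + control.n4, stress.n3 + stress.n4],
        ]
    else:
        rows = ["unmethylated", "hemimethylated", "full_internal_CG", "full_both"]
        counts = [
            [control.n1, stress.n1],
            [control.n2, stress.n2],
            [control.n3, stress.n3],
            [control.n4, stress.n4],
        ]
    return ContingencyTable(np.array(counts), tuple(rows), col_labels)
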