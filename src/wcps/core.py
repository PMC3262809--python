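"""Change-point statistics for single-gene differential expression.

A gene's expression values are modelled as a sequence ``X = (X1, X2)`` in
which the control block ``X1`` (size ``n1``) follows a reference
distribution ``F1`` and the case block ``X2`` (size ``n2``) may switch to a
different distribution at an unknown position.  The scan statistic compares,
for every candidate split ``p = [n*t]``, the empirical distribution of the
segment after the split against the control ECDF:

    D_n(t) = sqrt(n - [n*t]) * sup_x | F_seg(x) - F1_hat(x) |

and the weighted variant (WCPS) multiplies each ``D_n(t)`` by an ascending
step weight ``w(t)`` that compensates the statistic's natural decay near the
right bound, restoring sensitivity when only a few case samples changed.
The scan maximum is compared against the asymptotic Kolmogorov critical
value ``C(alpha)`` (1.358 at alpha=0.05, 1.628 at alpha=0.01), and the
argmax position estimates the change-point fraction ``t_hat``.

Two input conventions are supported.  When the case block is an ordered
sequence whose potential change sits at the right end (the Monte Carlo
sequence model), it is scanned as given.  For real expression matrices the
case samples carry no order, so the case block is sorted ascending first,
which maps any changed subset to the right end of the block; this reduction
maximises sensitivity but makes the fixed critical values anti-conservative
(see the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import kolmogi

__all__ = [
    "DataValidationError",
    "ExpressionProfile",
    "EmpiricalDistribution",
    "ChangePointScan",
    "ChangePointResult",
    "build_empirical_distribution",
    "critical_value",
    "weight_function",
    "dn_scan",
    "weighted_dn_scan",
    "detect",
    "flag_dge_samples",
    "WEIGHT_SLOPE",
    "WEIGHT_CEILING",
]

# Weight w(t) = min(1 + WEIGHT_SLOPE / m, WEIGHT_CEILING), m = n - [n*t]:
# ~1/x-shaped compensation that is ~1 on the left/middle of the grid and
# rises only near the right bound.  The ceiling caps the final steps so that
# a single extreme sample (whose segment statistic is bounded by 1) can
# never exceed C(0.01) = 1.628 on its own.
WEIGHT_SLOPE = 0.6
WEIGHT_CEILING = 1.5

_MIN_SEQUENCE = 4


class DataValidationError(ValueError):
    """Raised when an input profile, matrix or parameter is invalid."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DataValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise DataValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ExpressionProfile:
    """One gene's control-group and case-group expression values.

    Parameters
    ----------
    gene_id:
        Identifier carried through to results.
    control_values, case_values:
        Expression values of the two groups; each needs at least two finite
        entries.
    as_sequence:
        If True the case block is treated as an ordered sequence (a change,
        if present, sits at its right end) and scanned as given.  If False
        (default, the convention for unordered case groups) the case block
        is sorted ascending before scanning.
    """

    gene_id: str
    control_values: np.ndarray
    case_values: np.ndarray
    as_sequence: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "control_values", _as_float_array(self.control_values, "control_values")
        )
        object.__setattr__(
            self, "case_values", _as_float_array(self.case_values, "case_values")
        )
        if self.n1 < 2 or self.n2 < 2:
            raise DataValidationError(
                f"gene {self.gene_id!r}: need >=2 values per group "
                f"(got n1={self.n1}, n2={self.n2})"
            )

    @property
    def n1(self) -> int:
        return self.control_values.size

    @property
    def n2(self) -> int:
        return self.case_values.size

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    def scan_sequence(self) -> np.ndarray:
        """Combined sequence scanned by ``dn_scan``: sorted controls followed
        by the case block (sorted ascending unless ``as_sequence``)."""
        case = self.case_values if self.as_sequence else np.sort(self.case_values)
        return np.concatenate([np.sort(self.control_values), case])

    def negated(self) -> "ExpressionProfile":
        """Sign-flipped profile used for the under-expression scan."""
        return ExpressionProfile(
            self.gene_id,
            -self.control_values,
            -self.case_values,
            as_sequence=self.as_sequence,
        )


class EmpiricalDistribution:
    """Right-continuous step CDF of a sample with its generalized inverse.

    ``cdf(x)`` is ``P(X <= x)`` under the empirical measure, ``cdf_left(x)``
    its left limit ``P(X < x)``, and ``inverse(y)`` the generalized inverse
    ``inf{x : F(x) >= y}``.  ``y_grid`` exposes the fixed-step probability
    grid on which the inverse is evaluated in the grid approximation mode of
    the scan (default step ``1/(4*n)``).
    """

    def __init__(self, values):
        arr = _as_float_array(values, "values")
        if arr.size < 2:
            raise DataValidationError("need at least 2 values for an ECDF")
        self.support = np.sort(arr)
        self.n = arr.size

    def cdf(self, x) -> np.ndarray | float:
        return np.searchsorted(self.support, x, side="right") / self.n

    def cdf_left(self, x) -> np.ndarray | float:
        return np.searchsorted(self.support, x, side="left") / self.n

    def inverse(self, y) -> np.ndarray | float:
        y = np.asarray(y, dtype=float)
        if np.any((y < 0) | (y > 1)):
            raise DataValidationError("inverse() expects probabilities in [0, 1]")
        idx = np.clip(np.ceil(y * self.n).astype(int) - 1, 0, self.n - 1)
        return self.support[idx] if idx.ndim else float(self.support[idx])

    def y_grid(self, step: float | None = None) -> np.ndarray:
        step = 1.0 / (4 * self.n) if step is None else float(step)
        if not 0 < step < 1:
            raise DataValidationError("y-grid step must lie in (0, 1)")
        return np.arange(step, 1.0 + step / 2, step)


def build_empirical_distribution(values) -> EmpiricalDistribution:
    """ECDF of the control sample with generalized-inverse evaluation."""
    return EmpiricalDistribution(values)


def critical_value(alpha: float) -> float:
    """Asymptotic two-sided Kolmogorov critical value ``C(alpha)``.

    ``C(0.05) = 1.358`` and ``C(0.01) = 1.628`` to three decimals.
    """
    if not 0.0 < alpha < 1.0:
        raise DataValidationError(f"alpha must lie in (0, 1), got {alpha}")
    return float(kolmogi(alpha))


def _candidate_positions(n1: int, n2: int, positions: str) -> np.ndarray:
    if positions == "case":
        return np.arange(n1, n1 + n2)  # p = n1 .. n-1
    if positions == "full":
        return np.arange(1, n1 + n2)
    raise DataValidationError(f"positions must be 'case' or 'full', got {positions!r}")


def weight_function(positions, n: int) -> np.ndarray:
    """Ascending step weight ``w`` on the candidate grid.

    ``w = min(1 + 0.6/m, 1.5)`` with ``m = n - p`` the number of points
    after candidate split ``p``; ~1 on the left and middle of the grid,
    rising like 1/x toward the right bound, capped at 1.5.
    """
    if n < _MIN_SEQUENCE:
        raise DataValidationError(f"sequence too short for a scan (n={n} < {_MIN_SEQUENCE})")
    p = np.asarray(positions, dtype=int)
    if np.any((p < 1) | (p >= n)):
        raise DataValidationError("candidate positions must satisfy 1 <= p < n")
    m = n - p
    return np.minimum(1.0 + WEIGHT_SLOPE / m, WEIGHT_CEILING)


@dataclass
class ChangePointScan:
    """Per-position scan values over the candidate grid."""

    positions: np.ndarray  # integer split positions p = [n*t]
    t_grid: np.ndarray  # p / n
    dn_values: np.ndarray
    weights: np.ndarray
    weighted_values: np.ndarray
    n1: int
    n2: int

    @property
    def n(self) -> int:
        return self.n1 + self.n2


def _scan_values(
    sequence: np.ndarray,
    n1: int,
    positions: np.ndarray,
    control_ecdf: EmpiricalDistribution,
    sup: str,
    y_step: float | None,
) -> np.ndarray:
    """sup_x |F_segment(x) - F1(x)| for every candidate split, times sqrt(m)."""
    n = sequence.size
    if sup == "exact":
        # evaluate at every jump point of either step function (both limits)
        z = np.sort(sequence)
    elif sup == "grid":
        z = control_ecdf.inverse(control_ecdf.y_grid(y_step))
    else:
        raise DataValidationError(f"sup must be 'exact' or 'grid', got {sup!r}")
    f1_le = control_ecdf.cdf(z)
    f1_lt = control_ecdf.cdf_left(z)
    le = sequence[None, :] <= z[:, None]
    lt = sequence[None, :] < z[:, None]
    pre_le = np.cumsum(le, axis=1)
    pre_lt = np.cumsum(lt, axis=1)
    m = (n - positions).astype(float)
    seg_le = (pre_le[:, -1][:, None] - pre_le[:, positions - 1]) / m
    seg_lt = (pre_lt[:, -1][:, None] - pre_lt[:, positions - 1]) / m
    sup_vals = np.maximum(
        np.abs(seg_le - f1_le[:, None]).max(axis=0),
        np.abs(seg_lt - f1_lt[:, None]).max(axis=0),
    )
    return np.sqrt(m) * sup_vals


def dn_scan(
    profile: ExpressionProfile,
    positions: str = "case",
    sup: str = "exact",
    y_step: float | None = None,
) -> ChangePointScan:
    """Scan ``D_n(t)`` over candidate change positions.

    By default the candidate splits are ``p = n1 .. n-1`` (a change at the
    group boundary or inside the case block); ``positions='full'`` scans the
    whole sequence.  The sup is evaluated exactly at the ECDF jump points
    (both one-sided limits); ``sup='grid'`` instead evaluates it on the
    fixed-step quantile grid of the control ECDF (an approximation, default
    step ``1/(4*n1)``).
    """
    n1, n = profile.n1, profile.n
    if n < _MIN_SEQUENCE:
        raise DataValidationError(f"gene {profile.gene_id!r}: n={n} < {_MIN_SEQUENCE}")
    pos = _candidate_positions(n1, profile.n2, positions)
    ecdf = build_empirical_distribution(profile.control_values)
    dn = _scan_values(profile.scan_sequence(), n1, pos, ecdf, sup, y_step)
    w = weight_function(pos, n)
    return ChangePointScan(
        positions=pos,
        t_grid=pos / n,
        dn_values=dn,
        weights=w,
        weighted_values=w * dn,
        n1=n1,
        n2=profile.n2,
    )


def weighted_dn_scan(profile: ExpressionProfile, **kwargs) -> ChangePointScan:
    """Scan with the weighted statistic populated (same grid as ``dn_scan``)."""
    return dn_scan(profile, **kwargs)


@dataclass
class ChangePointResult:
    """Decision and change-point estimate for a single gene."""

    gene_id: str
    mode: str  # 'wcps' or 'npcps'
    statistic: float
    cp_fraction: float
    cp_index: int
    cp_value: float
    significant: bool
    direction: str  # 'over', 'under' or 'none'
    alpha: float
    critical_value: float
    scan: ChangePointScan = field(repr=False, default=None)


def _scan_maximum(scan: ChangePointScan, mode: str) -> tuple[float, int]:
    if mode == "wcps":
        values = scan.weighted_values
    elif mode == "npcps":
        values = scan.dn_values
    else:
        raise DataValidationError(f"mode must be 'wcps' or 'npcps', got {mode!r}")
    idx = int(np.argmax(values))  # ties -> leftmost position
    return float(values[idx]), idx


def detect(
    profile: ExpressionProfile,
    alpha: float = 0.05,
    mode: str = "wcps",
    direction: str = "both",
    positions: str = "case",
) -> ChangePointResult:
    """Test a gene for a change point and estimate its position.

    ``direction='over'`` scans the profile as given (an upward change at the
    right end of the case block); ``'under'`` scans the negated profile so a
    downward-shifted subset maps to the right end; ``'both'`` (default) runs
    both scans and keeps the larger statistic.  The result is significant
    when the scan maximum exceeds ``C(alpha)``; ``direction`` of the result
    is the winning side for significant genes and ``'none'`` otherwise.
    """
    if direction not in ("over", "under", "both"):
        raise DataValidationError(f"direction must be over/under/both, got {direction!r}")
    cval = critical_value(alpha)

    candidates = []
    if direction in ("over", "both"):
        candidates.append(("over", profile, dn_scan(profile, positions=positions)))
    if direction in ("under", "both"):
        neg = profile.negated()
        candidates.append(("under", neg, dn_scan(neg, positions=positions)))

    best = None
    for side, prof, scan in candidates:
        stat, idx = _scan_maximum(scan, mode)
        if best is None or stat > best[0]:
            best = (stat, idx, side, prof, scan)
    stat, idx, side, prof, scan = best

    p = int(scan.positions[idx])
    seq = prof.scan_sequence()
    cp_value = float(seq[p - 1])
    if side == "under":
        cp_value = -cp_value
    significant = stat > cval
    return ChangePointResult(
        gene_id=profile.gene_id,
        mode=mode,
        statistic=stat,
        cp_fraction=p / profile.n,
        cp_index=p,
        cp_value=cp_value,
        significant=significant,
        direction=side if significant else "none",
        alpha=alpha,
        critical_value=cval,
        scan=scan,
    )


def flag_dge_samples(profile: ExpressionProfile, result: ChangePointResult) -> np.ndarray:
    """0/1 flags over the case samples (original order): 1 for samples beyond
    the change-point value in the detected direction.

    The sample at the change point itself is not flagged (strict
    inequality).  When the change point sits at the group boundary
    (``cp_index == n1``) the entire case group is the changed segment and
    every case sample is flagged.  For a non-significant result the flags
    are all zero and a warning is issued.
    """
    case = profile.case_values
    if not result.significant or result.direction == "none":
        warnings.warn(
            f"gene {profile.gene_id!r}: flag_dge_samples called on a "
            "non-significant result; returning all-zero flags",
            stacklevel=2,
        )
        return np.zeros(case.size, dtype=int)
    if result.cp_index <= profile.n1:
        return np.ones(case.size, dtype=int)
    if profile.as_sequence:
        # ordered sequence: the detected segment is positional
        flags = np.zeros(case.size, dtype=int)
        flags[result.cp_index - profile.n1 :] = 1
        return flags
    if result.direction == "over":
        return (case > result.cp_value).astype(int)
    return (case < result.cp_value).astype(int)
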