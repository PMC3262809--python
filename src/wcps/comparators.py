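"""Comparator statistics for ranking genes by outlier differential expression.

Each scorer maps an :class:`~wcps.core.ExpressionProfile` to a single real
number oriented so that a larger score means stronger evidence of
differential expression; a registry keyed by method name exposes them to
the simulation harness and the CLI.  The outlier statistics (COPA, OS, ORT,
MOST) follow their original published definitions; LRS is a likelihood
ratio over a two-component shifted-normal model for the case group.  The
trigonometric TriORT/TriMOST variants fall back to ORT/MOST (see
``FALLBACK_METHODS``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DataValidationError, ExpressionProfile, dn_scan

__all__ = [
    "GeneScore",
    "METHODS",
    "FALLBACK_METHODS",
    "score_gene",
    "t_statistic",
    "copa_score",
    "os_score",
    "ort_score",
    "tri_ort_score",
    "most_score",
    "tri_most_score",
    "lrs_score",
    "npcps_score",
    "wcps_score",
]

_EPS = 1e-8


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    method: str
    score: float


def _mad(x: np.ndarray, center: float | None = None) -> float:
    center = np.median(x) if center is None else center
    return 1.4826 * float(np.median(np.abs(x - center)))


def _guarded_scale(scale: float, what: str) -> float:
    if scale <= _EPS:
        warnings.warn(f"{what}: zero scale, falling back to {_EPS}", stacklevel=3)
        return _EPS
    return scale


def t_statistic(profile: ExpressionProfile) -> float:
    """Two-sample pooled-variance t statistic (case minus control, signed)."""
    x, y = profile.control_values, profile.case_values
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= _EPS**2:
        warnings.warn(
            f"gene {profile.gene_id!r}: zero pooled variance, t set to 0", stacklevel=2
        )
        return 0.0
    return float((y.mean() - x.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))


def copa_score(profile: ExpressionProfile, r: float = 0.75) -> float:
    """Cancer outlier profile analysis: the r-th percentile of the case
    values after median-centering and MAD-scaling the gene over all samples."""
    if not 0.0 < r < 1.0:
        raise DataValidationError(f"percentile r must lie in (0,1), got {r}")
    allv = np.concatenate([profile.control_values, profile.case_values])
    med = float(np.median(allv))
    mad = _guarded_scale(_mad(allv, med), f"gene {profile.gene_id!r} COPA MAD")
    return float(np.quantile((profile.case_values - med) / mad, r))


def os_score(profile: ExpressionProfile) -> float:
    """Outlier sum: sum of standardized case values above q75 + IQR of the
    standardized combined sample."""
    allv = np.concatenate([profile.control_values, profile.case_values])
    med = float(np.median(allv))
    mad = _guarded_scale(_mad(allv, med), f"gene {profile.gene_id!r} OS MAD")
    std_all = (allv - med) / mad
    std_case = (profile.case_values - med) / mad
    q25, q75 = np.quantile(std_all, [0.25, 0.75])
    cut = q75 + (q75 - q25)
    return float(std_case[std_case > cut].sum())


def ort_score(profile: ExpressionProfile) -> float:
    """Outlier robust t: sum of case values beyond q75 + IQR of the control
    group, centred at the control median and scaled by the pooled median
    absolute residual from each group's own median."""
    x, y = profile.control_values, profile.case_values
    med_x, med_y = float(np.median(x)), float(np.median(y))
    resid = np.concatenate([np.abs(x - med_x), np.abs(y - med_y)])
    scale = _guarded_scale(
        1.4826 * float(np.median(resid)), f"gene {profile.gene_id!r} ORT scale"
    )
    q25, q75 = np.quantile(x, [0.25, 0.75])
    cut = q75 + (q75 - q25)
    out = y[y > cut]
    return float(((out - med_x) / scale).sum())


_MOST_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_MOST_SIMS = 20000


def _most_constants(n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sd of the sum of the top-k of n2 standard normal draws,
    k = 1..n2 (order-statistic normalization of MOST); seeded Monte Carlo,
    cached per case-group size."""
    if n2 not in _MOST_CACHE:
        rng = np.random.default_rng(19680801)
        sims = np.sort(rng.standard_normal((_MOST_SIMS, n2)), axis=1)[:, ::-1]
        csum = np.cumsum(sims, axis=1)
        _MOST_CACHE[n2] = (csum.mean(axis=0), csum.std(axis=0, ddof=1))
    return _MOST_CACHE[n2]


def most_score(profile: ExpressionProfile) -> float:
    """Maximum ordered subset t: max over k of the standardized sum of the
    k largest case values (centred at the control median, robust scale as in
    ORT, order-statistic normalization)."""
    x, y = profile.control_values, profile.case_values
    med_x, med_y = float(np.median(x)), float(np.median(y))
    resid = np.concatenate([np.abs(x - med_x), np.abs(y - med_y)])
    scale = _guarded_scale(
        1.4826 * float(np.median(resid)), f"gene {profile.gene_id!r} MOST scale"
    )
    ordered = np.sort(y)[::-1]
    sums = np.cumsum((ordered - med_x) / scale)
    mu_k, sd_k = _most_constants(y.size)
    return float(((sums - mu_k) / sd_k).max())


def lrs_score(profile: ExpressionProfile) -> float:
    """Likelihood ratio for a two-component shifted-normal case group.

    H0: all samples ~ N(mu0, s2).  H1: the j largest case values are
    shifted to a second component N(mu1, s2), j maximized over 1..n2-1
    with maximum-likelihood estimates of the means and the common variance.
    Returns the largest log-likelihood-ratio statistic (>= 0).
    """
    x, y = profile.control_values, profile.case_values
    n1, n2 = x.size, y.size
    n = n1 + n2
    allv = np.concatenate([x, y])
    rss0 = float(((allv - allv.mean()) ** 2).sum())
    if rss0 <= _EPS**2:
        warnings.warn(f"gene {profile.gene_id!r}: constant values, LRS set to 0", stacklevel=2)
        return 0.0
    y_sorted = np.sort(y)
    base = np.concatenate([x, y_sorted])  # background block: x plus lowest cases
    best = 0.0
    for j in range(1, n2):
        top = y_sorted[n2 - j :]
        rest = base[: n - j]
        rss1 = float(((top - top.mean()) ** 2).sum() + ((rest - rest.mean()) ** 2).sum())
        lr = n * np.log(rss0 / max(rss1, _EPS**2))
        best = max(best, lr)
    return best


def npcps_score(profile: ExpressionProfile) -> float:
    """Maximum unweighted D_n over the scan grid."""
    return float(dn_scan(profile).dn_values.max())


def wcps_score(profile: ExpressionProfile) -> float:
    """Maximum weighted D_n over the scan grid."""
    return float(dn_scan(profile).weighted_values.max())


def tri_ort_score(profile: ExpressionProfile) -> float:
    return ort_score(profile)


def tri_most_score(profile: ExpressionProfile) -> float:
    return most_score(profile)


def _abs_t(profile: ExpressionProfile) -> float:
    # two-sided ranking: |t|
    return abs(t_statistic(profile))


#: method name -> scorer oriented for descending ranking (larger = more DGE)
METHODS = {
    "t": _abs_t,
    "copa": copa_score,
    "os": os_score,
    "ort": ort_score,
    "tri_ort": tri_ort_score,
    "most": most_score,
    "tri_most": tri_most_score,
    "lrs": lrs_score,
    "npcps": npcps_score,
    "wcps": wcps_score,
}

#: methods implemented as fallbacks to their base statistic
FALLBACK_METHODS = {"tri_ort": "ort", "tri_most": "most"}


def score_gene(profile: ExpressionProfile, method: str) -> GeneScore:
    """Score one gene with a registered method."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise DataValidationError(
            f"unknown method {method!r}; known methods: {sorted(METHODS)}"
        ) from None
    return GeneScore(gene_id=profile.gene_id, method=method, score=fn(profile))
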