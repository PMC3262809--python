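"""Monte Carlo harness: change-point recovery tables and ROC/AUC comparison.

The generator draws genes under the sequence model: ``n1`` control values
and ``n2`` case values from a base distribution (standard normal or a
standardized skew-normal), with a shift ``mu`` added to the final ``k``
case positions of DGE genes, so the true change-point fraction is
``(n - k) / n``.  ``run_cp_table`` reproduces the change-point-estimate /
miss-rate tables; ``run_roc_table`` scores mixed DGE / null gene sets with
any registered method and tabulates ROC AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .comparators import METHODS
from .core import DataValidationError, ExpressionProfile, critical_value, dn_scan

__all__ = [
    "SimulationConfig",
    "EvaluationSummary",
    "RocCurve",
    "generate_gene",
    "run_cp_table",
    "run_roc_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Monte Carlo cell.

    ``n1``/``n2`` are the control/case group sizes, ``k`` the number of
    shifted case samples (0 < k <= n2), ``mu`` the shift (may be negative),
    ``distribution`` either ``'normal'`` (standard normal) or
    ``'skew_normal'`` (shape ``shape``, standardized to mean 0, sd 1).
    ``n_genes``/``dge_fraction`` describe ROC datasets, ``reps`` the
    replicates per cell of a change-point table, ``alpha`` the significance
    level, ``seed`` the base seed of every stochastic routine.
    """

    n1: int = 25
    n2: int = 25
    k: int = 3
    mu: float = 2.0
    distribution: str = "normal"
    shape: float = 4.0
    n_genes: int = 7000
    dge_fraction: float = 0.1
    reps: int = 1000
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise DataValidationError("need n1 >= 2 and n2 >= 2")
        if not 0 < self.k <= self.n2:
            raise DataValidationError(f"need 0 < k <= n2, got k={self.k}, n2={self.n2}")
        if self.distribution not in ("normal", "skew_normal"):
            raise DataValidationError(f"unknown distribution {self.distribution!r}")
        if not 0 < self.dge_fraction < 1:
            raise DataValidationError("dge_fraction must lie in (0, 1)")
        if self.reps < 1:
            raise DataValidationError("reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise DataValidationError("alpha must lie in (0, 1)")

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def actual_cp(self) -> float:
        return (self.n - self.k) / self.n


def _draw(config: SimulationConfig, rng: np.random.Generator, size) -> np.ndarray:
    if config.distribution == "normal":
        return rng.standard_normal(size)
    a = config.shape
    delta = a / np.sqrt(1 + a * a)
    mean = delta * np.sqrt(2 / np.pi)
    sd = np.sqrt(1 - 2 * delta * delta / np.pi)
    raw = stats.skewnorm.rvs(a, size=size, random_state=rng)
    return (raw - mean) / sd


def generate_gene(
    config: SimulationConfig, has_dge: bool, rng: np.random.Generator, gene_id: str = "g"
) -> ExpressionProfile:
    """One simulated gene; DGE genes carry ``mu`` on the last ``k`` case
    positions (the sequence-model change point)."""
    control = _draw(config, rng, config.n1)
    case = _draw(config, rng, config.n2)
    if has_dge:
        case[config.n2 - config.k :] += config.mu
    return ExpressionProfile(gene_id, control, case, as_sequence=True)


def _scan_profile(profile: ExpressionProfile, mu: float):
    """One scan per gene; downward shifts are scanned on the negated scale.

    Returns (npcps_stat, npcps_cp, wcps_stat, wcps_cp)."""
    scanned = profile.negated() if mu < 0 else profile
    scan = dn_scan(scanned)
    i_n = int(np.argmax(scan.dn_values))
    i_w = int(np.argmax(scan.weighted_values))
    return (
        float(scan.dn_values[i_n]),
        float(scan.t_grid[i_n]),
        float(scan.weighted_values[i_w]),
        float(scan.t_grid[i_w]),
    )


@dataclass
class EvaluationSummary:
    """Grid-level aggregation of a change-point table."""

    mae: dict = field(default_factory=dict)  # method -> mean |t_hat - actual|
    mean_miss: dict = field(default_factory=dict)  # method -> mean miss rate
    table: pd.DataFrame = None


def run_cp_table(config: SimulationConfig, k_grid) -> EvaluationSummary:
    """Change-point estimate and miss rate (the fraction of DGE genes not
    declared significant at C(alpha); type-II error) per k.

    The mean estimate averages over all replicates; a detected-only average
    is reported alongside.
    """
    rng = np.random.default_rng(config.seed)
    cval = critical_value(config.alpha)
    rows = []
    for k in k_grid:
        cfg = replace(config, k=int(k))
        stats_ = np.array(
            [
                _scan_profile(generate_gene(cfg, True, rng), cfg.mu)
                for _ in range(config.reps)
            ]
        )
        d_n, t_n, d_w, t_w = stats_.T
        det_n, det_w = d_n > cval, d_w > cval
        rows.append(
            {
                "k": int(k),
                "actual_cp": cfg.actual_cp,
                "cp_wcps": t_w.mean(),
                "cp_npcps": t_n.mean(),
                "miss_wcps": 1.0 - det_w.mean(),
                "miss_npcps": 1.0 - det_n.mean(),
                "cp_wcps_detected": t_w[det_w].mean() if det_w.any() else np.nan,
                "cp_npcps_detected": t_n[det_n].mean() if det_n.any() else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    err_w = (table.cp_wcps - table.actual_cp).abs()
    err_n = (table.cp_npcps - table.actual_cp).abs()
    return EvaluationSummary(
        mae={"wcps": err_w.mean(), "npcps": err_n.mean()},
        mean_miss={"wcps": table.miss_wcps.mean(), "npcps": table.miss_npcps.mean()},
        table=table,
    )


@dataclass
class RocCurve:
    """ROC curve with trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @classmethod
    def from_scores(cls, labels, scores) -> "RocCurve":
        labels = np.asarray(labels, dtype=bool)
        scores = np.asarray(scores, dtype=float)
        fpr, tpr, thr = roc_curve(labels, scores)
        return cls(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


def _dataset_scores(config: SimulationConfig, methods, rng) -> tuple[np.ndarray, dict]:
    n_dge = max(1, int(round(config.n_genes * config.dge_fraction)))
    labels = np.zeros(config.n_genes, dtype=bool)
    labels[:n_dge] = True
    scores = {m: np.empty(config.n_genes) for m in methods}
    scan_modes = [m for m in methods if m in ("wcps", "npcps")]
    others = [m for m in methods if m not in ("wcps", "npcps")]
    for i in range(config.n_genes):
        profile = generate_gene(config, bool(labels[i]), rng, gene_id=f"g{i}")
        if scan_modes:
            d_n, _, d_w, _ = _scan_profile(profile, config.mu)
            if "wcps" in scores:
                scores["wcps"][i] = d_w
            if "npcps" in scores:
                scores["npcps"][i] = d_n
        for m in others:
            scores[m][i] = METHODS[m](profile)
    return labels, scores


def run_roc_table(cells, methods=("wcps", "npcps"), seed: int | None = None):
    """AUC matrix over simulation cells.

    ``cells`` is an iterable of :class:`SimulationConfig`; every gene set
    mixes ``dge_fraction`` DGE genes with null genes, each method scores
    every gene, and ROC/AUC is computed against the ground-truth labels.
    Returns ``(table, curves)``: a DataFrame with one row per cell plus a
    mean row, and a dict ``(cell_index, method) -> RocCurve``.
    """
    methods = list(methods)
    for m in methods:
        if m not in METHODS:
            raise DataValidationError(
                f"unknown method {m!r}; known methods: {sorted(METHODS)}"
            )
    rows, curves = [], {}
    for idx, cfg in enumerate(cells):
        rng = np.random.default_rng(cfg.seed if seed is None else seed + idx)
        labels, scores = _dataset_scores(cfg, methods, rng)
        row = {"n": cfg.n, "mu": cfg.mu, "k": cfg.k, "distribution": cfg.distribution}
        for m in methods:
            curve = RocCurve.from_scores(labels, scores[m])
            curves[(idx, m)] = curve
            row[m] = curve.auc
        rows.append(row)
    table = pd.DataFrame(rows)
    mean_row = {c: "" for c in ("n", "mu", "k", "distribution")}
    mean_row.update({m: table[m].mean() for m in methods})
    table = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
    return table, curves
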