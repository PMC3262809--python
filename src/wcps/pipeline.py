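"""Apply the change-point scan to a gene x sample expression matrix.

Plain TSV is the interchange format: a matrix file (first column gene or
probe identifiers, header row of sample identifiers) and a two-column
labels file mapping each sample to ``control`` or ``case``.  The pipeline
collapses multi-probe genes, ranks genes by the scan statistic, and builds
the binary DGE matrix (genes x case samples) with its marginal summaries.
Case groups in real matrices carry no sample order, so each gene's case
values are sorted ascending before scanning (the reduction described in
the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    ChangePointResult,
    DataValidationError,
    ExpressionProfile,
    critical_value,
    detect,
    dn_scan,
    flag_dge_samples,
)

__all__ = [
    "ExpressionMatrix",
    "DgeMatrix",
    "read_expression",
    "write_expression",
    "collapse_probes",
    "rank_genes",
    "build_dge_matrix",
    "generate_fixture",
]

GROUPS = ("control", "case")


@dataclass
class ExpressionMatrix:
    """Expression values (genes x samples) with per-sample group labels,
    samples ordered control block first."""

    data: pd.DataFrame
    groups: pd.Series  # sample id -> 'control' | 'case'

    @property
    def control_samples(self) -> list:
        return [s for s in self.data.columns if self.groups[s] == "control"]

    @property
    def case_samples(self) -> list:
        return [s for s in self.data.columns if self.groups[s] == "case"]

    def profile(self, gene_id: str) -> ExpressionProfile:
        row = self.data.loc[gene_id]
        return ExpressionProfile(
            str(gene_id),
            row[self.control_samples].to_numpy(float),
            row[self.case_samples].to_numpy(float),
        )


def _validate_matrix(data: pd.DataFrame, groups: pd.Series) -> ExpressionMatrix:
    if data.index.duplicated().any():
        dup = data.index[data.index.duplicated()][0]
        raise DataValidationError(f"duplicate row identifier {dup!r}")
    if data.columns.duplicated().any():
        dup = data.columns[data.columns.duplicated()][0]
        raise DataValidationError(f"duplicate sample identifier {dup!r}")
    missing = [s for s in data.columns if s not in groups.index]
    if missing:
        raise DataValidationError(f"sample {missing[0]!r} missing from the labels file")
    bad = [s for s in data.columns if groups[s] not in GROUPS]
    if bad:
        raise DataValidationError(
            f"sample {bad[0]!r} has group {groups[bad[0]]!r}; expected control/case"
        )
    for col in data.columns:
        if not np.issubdtype(data[col].dtype, np.number):
            row = data[col][pd.to_numeric(data[col], errors="coerce").isna()].index[0]
            raise DataValidationError(f"non-numeric value at row {row!r}, column {col!r}")
    if not np.isfinite(data.to_numpy(float)).all():
        raise DataValidationError("matrix contains non-finite values")
    ordered = [s for s in data.columns if groups[s] == "control"] + [
        s for s in data.columns if groups[s] == "case"
    ]
    if len({groups[s] for s in ordered} & set(GROUPS)) < 2 or min(
        sum(groups[s] == g for s in ordered) for g in GROUPS
    ) < 2:
        raise DataValidationError("need at least 2 samples in each of control and case")
    return ExpressionMatrix(data=data[ordered], groups=groups.loc[ordered])


def read_expression(matrix_path, labels_path) -> ExpressionMatrix:
    """Load and validate a TSV matrix plus a two-column TSV labels file."""
    data = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0].astype(str)
    return _validate_matrix(data, labels)


def write_expression(matrix: ExpressionMatrix, matrix_path, labels_path=None) -> None:
    matrix.data.to_csv(matrix_path, sep="\t")
    if labels_path is not None:
        matrix.groups.rename("group").to_frame().to_csv(labels_path, sep="\t")


def collapse_probes(matrix: ExpressionMatrix, probe_to_gene, mode: str = "wcps") -> ExpressionMatrix:
    """One row per gene: unmapped probes are dropped and, among multiple
    probes of a gene, the probe with the largest scan statistic is kept."""
    mapping = dict(probe_to_gene.items() if hasattr(probe_to_gene, "items") else probe_to_gene)
    keep: dict[str, tuple[float, str]] = {}
    for probe in matrix.data.index:
        gene = mapping.get(probe)
        if gene is None:
            continue
        scan = dn_scan(matrix.profile(probe))
        stat = float((scan.weighted_values if mode == "wcps" else scan.dn_values).max())
        prev = keep.get(gene)
        if prev is None or stat > prev[0]:
            keep[gene] = (stat, probe)
    if not keep:
        raise DataValidationError("no probe mapped to any gene; empty result")
    genes = sorted(keep)
    data = matrix.data.loc[[keep[g][1] for g in genes]]
    data.index = pd.Index(genes, name=matrix.data.index.name)
    return ExpressionMatrix(data=data, groups=matrix.groups)


def rank_genes(
    matrix: ExpressionMatrix, mode: str = "wcps", alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, ChangePointResult]]:
    """Rank all genes by the scan statistic in descending order.

    Returns the ranked table (statistic, change-point fraction and value,
    direction, significance at 0.05 and 0.01) and the per-gene
    :class:`ChangePointResult` map.  Ties are broken by gene identifier.
    """
    c05, c01 = critical_value(0.05), critical_value(0.01)
    results: dict[str, ChangePointResult] = {}
    rows = []
    for gene in matrix.data.index:
        res = detect(matrix.profile(gene), alpha=alpha, mode=mode, direction="both")
        results[gene] = res
        rows.append(
            {
                "gene": gene,
                "statistic": res.statistic,
                "cp_fraction": res.cp_fraction,
                "cp_value": res.cp_value,
                "direction": res.direction,
                "significant_0.05": res.statistic > c05,
                "significant_0.01": res.statistic > c01,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["statistic", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return table, results


@dataclass
class DgeMatrix:
    """Binary genes x case-samples matrix of significant-DGE flags with its
    marginals: per-sample DGE gene counts and the histogram of genes by
    DGE-subset size."""

    flags: pd.DataFrame
    per_sample_counts: pd.Series
    subset_size_histogram: pd.Series


def build_dge_matrix(
    matrix: ExpressionMatrix,
    results: dict[str, ChangePointResult],
    alpha: float = 0.05,
) -> DgeMatrix:
    """Per-sample DGE flags for every gene significant at C(alpha).

    Non-significant genes contribute all-zero rows (and mass at subset size
    zero in the histogram)."""
    cval = critical_value(alpha)
    case_samples = matrix.case_samples
    flags = pd.DataFrame(
        0, index=matrix.data.index, columns=case_samples, dtype=int
    )
    for gene, res in results.items():
        if res.statistic > cval and res.direction != "none":
            flags.loc[gene] = flag_dge_samples(matrix.profile(gene), res)
    sizes = flags.sum(axis=1)
    hist = sizes.value_counts().sort_index()
    hist.index.name = "subset_size"
    return DgeMatrix(
        flags=flags,
        per_sample_counts=flags.sum(axis=0),
        subset_size_histogram=hist,
    )


def generate_fixture(
    out_dir,
    n_genes: int,
    n1: int,
    n2: int,
    dge_spec=(),
    seed: int = 0,
    prefix: str = "fixture",
):
    """Write a synthetic matrix, labels and ground-truth TSV trio.

    ``dge_spec`` lists blocks ``(count, k, mu, direction)``: ``count`` genes
    whose expression is shifted by ``mu`` (direction ``'over'``) or ``-mu``
    (``'under'``) in ``k`` randomly chosen case samples; remaining genes are
    pure standard-normal null.  Returns the three file paths.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    total_dge = sum(b[0] for b in dge_spec)
    if total_dge > n_genes:
        raise DataValidationError("dge_spec lists more genes than n_genes")
    for _, k, _, direction in dge_spec:
        if not 0 < k <= n2:
            raise DataValidationError(f"dge_spec k={k} inconsistent with n2={n2}")
        if direction not in ("over", "under"):
            raise DataValidationError(f"dge_spec direction must be over/under, got {direction!r}")

    samples = [f"ctrl_{i+1}" for i in range(n1)] + [f"case_{i+1}" for i in range(n2)]
    values = rng.standard_normal((n_genes, n1 + n2))
    truth_rows = []
    gi = 0
    for count, k, mu, direction in dge_spec:
        for _ in range(count):
            cols = n1 + rng.choice(n2, size=k, replace=False)
            shift = mu if direction == "over" else -mu
            values[gi, cols] += shift
            truth_rows.append(
                {"gene": f"gene_{gi+1}", "is_dge": True, "k": k, "mu": shift, "direction": direction}
            )
            gi += 1
    for j in range(gi, n_genes):
        truth_rows.append({"gene": f"gene_{j+1}", "is_dge": False, "k": 0, "mu": 0.0, "direction": "none"})

    genes = [f"gene_{i+1}" for i in range(n_genes)]
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    groups = pd.Series(
        ["control"] * n1 + ["case"] * n2, index=pd.Index(samples, name="sample"), name="group"
    )
    matrix_path = out_dir / f"{prefix}_matrix.tsv"
    labels_path = out_dir / f"{prefix}_labels.tsv"
    truth_path = out_dir / f"{prefix}_truth.tsv"
    data.to_csv(matrix_path, sep="\t")
    groups.to_frame().to_csv(labels_path, sep="\t")
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    return matrix_path, labels_path, truth_path
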