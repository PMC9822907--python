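"""Timepoint transcriptomics: baseline transform, differential-expression
filtering, pairwise timepoint comparisons, unique/core set partitioning,
hierarchical clustering of samples, and qPCR relative quantification.

The pipeline consumes a normalized genes × samples log2 matrix (e.g. an
RMA-normalized microarray series); array preprocessing itself is upstream
and out of scope.  Differential expression uses the gate
|fold change| > 1.5 AND p < 0.01 AND FDR < 0.01 (Benjamini–Hochberg),
with fold change measured on the linear scale against the 0-month baseline.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "DEResult",
    "VennPartition",
    "baseline_transform",
    "anova_de_filter",
    "pairwise_de",
    "venn_core",
    "hierarchical_cluster",
    "relative_quantification",
    "read_series_matrix",
    "read_expression_tsv",
]

TIMEPOINTS = (0, 2, 4, 6)
FC_THRESHOLD = 1.5
P_THRESHOLD = 0.01
FDR_THRESHOLD = 0.01


@dataclass
class ExpressionDataset:
    """Genes × samples log2 matrix plus a sample sheet (sample, timepoint, subject)."""

    matrix: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self):
        sheet = self.sample_sheet
        missing = set(self.matrix.columns) - set(sheet["sample"])
        if missing:
            raise ValueError(f"samples without timepoint labels: {sorted(missing)[:5]}")
        if sheet["timepoint"].isna().any():
            raise ValueError("sample sheet has missing timepoint labels")

    def timepoint_of(self) -> pd.Series:
        return (self.sample_sheet.set_index("sample")["timepoint"]
                .reindex(self.matrix.columns))

    def samples_at(self, t) -> list:
        tp = self.timepoint_of()
        return list(tp.index[tp == t])


@dataclass
class DEResult:
    """Per-gene fold change / p / FDR table with the pass gate applied.

    ``fold_change`` is linear and signed: positive = up at the later
    timepoint versus the 0-month baseline, FC = ±2^|Δ log2 means|.
    """

    table: pd.DataFrame   # index gene, columns fold_change, p_value, fdr, passed
    thresholds: dict = field(default_factory=dict)

    @property
    def passing(self) -> set:
        return set(self.table.index[self.table["passed"]])


@dataclass
class VennPartition:
    """Unique/core partition of three against-baseline gene sets."""

    S2: set
    S4: set
    S6: set
    unique2: set
    unique4: set
    unique6: set
    core: set

    def region_sizes(self) -> dict:
        return {"unique2": len(self.unique2), "unique4": len(self.unique4),
                "unique6": len(self.unique6), "core": len(self.core)}


# --------------------------------------------------------------------------

def baseline_transform(dataset: ExpressionDataset) -> ExpressionDataset:
    """Subtract each gene's median across all samples (baseline-to-median)."""
    med = dataset.matrix.median(axis=1)
    return ExpressionDataset(matrix=dataset.matrix.sub(med, axis=0),
                             sample_sheet=dataset.sample_sheet.copy())


def _signed_fc(log2_delta: float) -> float:
    return float(np.sign(log2_delta) * 2.0 ** abs(log2_delta)) if log2_delta != 0 else 1.0


def _max_fc_vs_baseline(matrix: pd.DataFrame, groups: dict) -> pd.Series:
    """Largest-magnitude linear FC of any post-baseline timepoint mean vs 0 months."""
    base = matrix[groups[0]].mean(axis=1)
    best = pd.Series(0.0, index=matrix.index)
    for t in (2, 4, 6):
        if t not in groups:
            continue
        delta = matrix[groups[t]].mean(axis=1) - base
        take = delta.abs() > best.abs()
        best[take] = delta[take]
    return best.map(_signed_fc)


def _degenerate_p(values_by_group) -> float:
    """p for the zero-within-variance case: 0 if group means differ, else 1."""
    means = [np.mean(g) for g in values_by_group]
    return 0.0 if np.ptp(means) > 0 else 1.0


def anova_de_filter(dataset: ExpressionDataset, fc: float = FC_THRESHOLD,
                    p: float = P_THRESHOLD, fdr: float = FDR_THRESHOLD) -> DEResult:
    """Per-gene one-way ANOVA across the four timepoints with the FC/p/FDR gate."""
    groups = {t: dataset.samples_at(t) for t in TIMEPOINTS if dataset.samples_at(t)}
    for t, s in groups.items():
        if len(s) < 2:
            raise ValueError(f"timepoint {t} has fewer than 2 samples")
    mat = dataset.matrix
    arrs = [mat[s].to_numpy() for s in groups.values()]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fstat, pvals = stats.f_oneway(*arrs, axis=1)
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        logger.info("one-way ANOVA: %d genes with zero within-group variance", degenerate.sum())
        for i in np.flatnonzero(degenerate):
            pvals[i] = _degenerate_p([a[i] for a in arrs])
    fdr_vals = multipletests(pvals, method="fdr_bh")[1]
    fold = _max_fc_vs_baseline(mat, {t: list(s) for t, s in groups.items()})
    table = pd.DataFrame({"fold_change": fold, "p_value": pvals, "fdr": fdr_vals},
                         index=mat.index)
    table["passed"] = ((table["fold_change"].abs() > fc)
                       & (table["p_value"] < p) & (table["fdr"] < fdr))
    return DEResult(table, {"fc": fc, "p": p, "fdr": fdr, "test": "one-way ANOVA"})


def pairwise_de(dataset: ExpressionDataset, timepoint_t: int,
                fc: float = FC_THRESHOLD, p: float = P_THRESHOLD,
                fdr: float = FDR_THRESHOLD, use_fdr: bool = True) -> DEResult:
    """Two-group comparison (0 months vs ``timepoint_t``) with the same gates.

    Uses Welch's two-sample t-test on log2 values.  ``use_fdr=False`` drops
    the FDR gate (keeping |FC| and p), exposing both gate configurations.
    """
    g0 = dataset.samples_at(0)
    gt = dataset.samples_at(timepoint_t)
    if not g0 or not gt:
        raise ValueError(f"missing samples for 0 vs {timepoint_t} comparison")
    a = dataset.matrix[g0].to_numpy()
    b = dataset.matrix[gt].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(pvals)
    for i in np.flatnonzero(degenerate):
        pvals[i] = _degenerate_p([a[i], b[i]])
    fdr_vals = multipletests(pvals, method="fdr_bh")[1]
    delta = b.mean(axis=1) - a.mean(axis=1)
    fold = pd.Series([_signed_fc(d) for d in delta], index=dataset.matrix.index)
    table = pd.DataFrame({"fold_change": fold, "p_value": pvals, "fdr": fdr_vals},
                         index=dataset.matrix.index)
    table["passed"] = (table["fold_change"].abs() > fc) & (table["p_value"] < p)
    if use_fdr:
        table["passed"] &= table["fdr"] < fdr
    return DEResult(table, {"fc": fc, "p": p, "fdr": fdr if use_fdr else None,
                            "test": f"Welch t, 0 vs {timepoint_t} months"})


def venn_core(S2, S4, S6) -> VennPartition:
    """Partition three against-baseline sets into per-timepoint unique sets
    and the core signature present in all three."""
    S2, S4, S6 = set(S2), set(S4), set(S6)
    return VennPartition(
        S2=S2, S4=S4, S6=S6,
        unique2=S2 - S4 - S6,
        unique4=S4 - S2 - S6,
        unique6=S6 - S2 - S4,
        core=S2 & S4 & S6,
    )


def hierarchical_cluster(dataset: ExpressionDataset, genes=None,
                         metric: str = "correlation", method: str = "average"):
    """Agglomerative clustering of samples on the (optionally restricted)
    matrix; distance 1 − Pearson correlation, average linkage by default.

    Returns ``(linkage matrix, ordered sample names, newick string,
    provenance)``.  Sample order in the input does not affect the tree
    topology.
    """
    mat = dataset.matrix if genes is None else dataset.matrix.loc[sorted(genes)]
    if mat.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    cols = sorted(mat.columns)
    X = mat[cols].T.to_numpy()
    Z = hierarchy.linkage(X, method=method, metric=metric)
    order = [cols[i] for i in hierarchy.leaves_list(Z)]
    tree = hierarchy.to_tree(Z)

    def _newick(node):
        if node.is_leaf():
            return cols[node.id]
        left, right = node.get_left(), node.get_right()
        return (f"({_newick(left)}:{node.dist - left.dist:.6g},"
                f"{_newick(right)}:{node.dist - right.dist:.6g})")

    newick = _newick(tree) + ";"
    prov = {"metric": metric, "method": method, "n_genes": mat.shape[0]}
    return Z, order, newick, prov


def relative_quantification(ct_table: pd.DataFrame, baseline: str,
                            target_col: str = "ct_target",
                            reference_col: str = "ct_reference",
                            condition_col: str = "condition") -> pd.Series:
    """qPCR relative quantification: RQ = 2^(−ΔΔCt) against a reference gene
    and a baseline condition (RQ = 1 at baseline by construction).

    ``ct_table`` has one row per sample with target and reference Ct values
    and a condition label; samples missing the reference Ct are excluded
    (and logged).  Returns mean RQ per condition.
    """
    df = ct_table.copy()
    missing = df[reference_col].isna()
    if missing.any():
        logger.warning("excluding %d samples with missing reference Ct", missing.sum())
        df = df[~missing]
    if baseline not in set(df[condition_col]):
        raise ValueError(f"baseline condition {baseline!r} absent from the table")
    df["dct"] = df[target_col] - df[reference_col]
    base_dct = df.loc[df[condition_col] == baseline, "dct"].mean()
    df["rq"] = 2.0 ** (-(df["dct"] - base_dct))
    return df.groupby(condition_col)["rq"].mean()


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

def read_series_matrix(path) -> pd.DataFrame:
    """Read the expression table from a GEO series-matrix file (the
    tab-separated block between !series_matrix_table_begin/end)."""
    lines = []
    inside = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if inside:
                lines.append(line)
    if not lines:
        raise ValueError("no !series_matrix_table_begin block found")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def read_expression_tsv(path, sep: str | None = None) -> pd.DataFrame:
    """Read a plain genes × samples table (TSV by default, CSV autodetected)."""
    if sep is None:
        with open(path) as fh:
            head = fh.readline()
        sep = "\t" if "\t" in head else ","
    return pd.read_csv(path, sep=sep, index_col=0)
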