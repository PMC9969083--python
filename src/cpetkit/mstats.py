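"""Cohort-level statistics: z-score standardization, Pearson correlation
matrix, eigen-PCA with Kaiser retention, variance attribution, biplot
export, and distribution-gated two-group comparisons.

PCA is performed on the correlation matrix (eigendecomposition of the
covariance of z-scored columns), matching the standardize-then-decompose
workflow; loadings are eigenvectors scaled by the square root of their
eigenvalue, which makes each loading equal to the Pearson correlation
between the component scores and the standardized variable.  With more
variables than subjects the correlation matrix is rank deficient; near-zero
eigenvalues are clamped to zero and the effective rank reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

EIGEN_CLAMP = 1e-10


@dataclass
class FeatureMatrix:
    """n subjects × m variables with optional group (sex) labels."""

    values: pd.DataFrame
    groups: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        df = self.values
        if df.columns.duplicated().any():
            raise DataError("duplicate variable names in feature matrix")
        if df.shape[1] < 2 or df.shape[0] < 3:
            raise DataError("feature matrix needs at least 3 subjects and 2 variables")
        if df.isna().any().any():
            cols = df.columns[df.isna().any()].tolist()
            raise DataError(f"feature matrix has missing entries in: {cols}")
        if self.groups is not None and not self.groups.index.equals(df.index):
            self.groups = self.groups.reindex(df.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _column_sd(df: pd.DataFrame, divisor: str) -> pd.Series:
    ddof = 0 if divisor == "n" else 1
    return df.std(ddof=ddof)


def zscore(matrix: FeatureMatrix, divisor: str = "n") -> FeatureMatrix:
    """Column-wise z-scores (x − μ)/σ with population σ by default."""
    df = matrix.values
    sd = _column_sd(df, divisor)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise DataError(f"zero-variance column(s) cannot be standardized: {zero}")
    z = (df - df.mean()) / sd
    return FeatureMatrix(values=z, groups=matrix.groups)


def pearson_matrix(matrix: FeatureMatrix) -> pd.DataFrame:
    """Symmetric m × m Pearson correlation matrix with variable labels."""
    df = matrix.values
    if df.shape[0] < 3:
        raise DataError("Pearson matrix needs at least 3 subjects")
    sd = _column_sd(df, "n")
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise DataError(f"zero-variance column(s): {zero}")
    corr = np.corrcoef(df.to_numpy(float), rowvar=False)
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)


@dataclass
class PcaResult:
    """Eigen-PCA of a standardized matrix."""

    eigenvalues: np.ndarray          # descending, length m
    variance_fraction: np.ndarray    # eigenvalue / m
    loadings: pd.DataFrame           # m × k, PC columns
    scores: pd.DataFrame             # n × k
    retained_k: int                  # Kaiser count (eigenvalue > 1)
    effective_rank: int              # eigenvalues above the clamp
    eigenvectors: pd.DataFrame = field(repr=False, default=None)


def pca_eigen(standardized: FeatureMatrix, tol: float = 1e-6) -> PcaResult:
    """Eigendecomposition of the correlation matrix of a z-scored matrix.

    Rejects input whose columns are not standardized (mean ≈ 0, population
    SD ≈ 1).  Components are ordered by descending eigenvalue; within each
    component the sign is fixed so the largest-magnitude loading is positive.
    """
    df = standardized.values
    mu = df.mean().abs().max()
    sd_dev = (_column_sd(df, "n") - 1.0).abs().max()
    if mu > tol or sd_dev > tol:
        raise DataError(
            "pca_eigen expects standardized input "
            f"(max |mean| = {mu:.2e}, max |SD−1| = {sd_dev:.2e})"
        )
    n, m = df.shape
    Z = df.to_numpy(float)
    corr = (Z.T @ Z) / n
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    eigval = np.where(eigval < EIGEN_CLAMP, 0.0, eigval)

    loadings = eigvec * np.sqrt(eigval)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(m):
        col = loadings[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            eigvec[:, j] = -eigvec[:, j]

    scores = Z @ eigvec
    pcs = [f"PC{j+1}" for j in range(m)]
    return PcaResult(
        eigenvalues=eigval,
        variance_fraction=eigval / m,
        loadings=pd.DataFrame(loadings, index=df.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=df.index, columns=pcs),
        retained_k=kaiser_retain(eigval),
        effective_rank=int((eigval > EIGEN_CLAMP).sum()),
        eigenvectors=pd.DataFrame(eigvec, index=df.columns, columns=pcs),
    )


def kaiser_retain(eigenvalues) -> int:
    """Kaiser's rule: number of eigenvalues strictly greater than one."""
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-12):
        raise DataError("eigenvalues must be sorted in descending order")
    return int((ev > 1.0).sum())


def variance_attribution(pca: PcaResult, target_column: str) -> pd.DataFrame:
    """Per retained component: variance share, the dominant variable (largest
    |loading|), and the target variable's loading — the attribution summary
    behind statements like "variable X majorly contributed to PC1"."""
    if target_column not in pca.loadings.index:
        raise DataError(f"unknown target column {target_column!r}")
    k = max(pca.retained_k, 1)
    rows = []
    for j in range(k):
        pc = f"PC{j+1}"
        col = pca.loadings[pc]
        top = col.abs().idxmax()
        tload = float(col.loc[target_column])
        rows.append({
            "component": pc,
            "eigenvalue": float(pca.eigenvalues[j]),
            "variance_fraction": float(pca.variance_fraction[j]),
            "top_contributor": top,
            "top_loading": float(col.loc[top]),
            "target_loading": tload,
            "target_sign": "+" if tload >= 0 else "-",
        })
    out = pd.DataFrame(rows).set_index("component")
    return out.sort_values("variance_fraction", ascending=False)


def biplot_export(pca: PcaResult, pc_x: int = 1, pc_y: int = 2,
                  groups: Optional[pd.Series] = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables for a biplot: subject scores (with group labels)
    and variable loading vectors for the chosen component pair."""
    m = pca.loadings.shape[1]
    for pc in (pc_x, pc_y):
        if not (1 <= pc <= m):
            raise DataError(f"component index {pc} out of range 1..{m}")
    cx, cy = f"PC{pc_x}", f"PC{pc_y}"
    score_tab = pca.scores[[cx, cy]].copy()
    if groups is not None:
        score_tab["group"] = groups.reindex(score_tab.index)
    loading_tab = pca.loadings[[cx, cy]].copy()
    return score_tab, loading_tab


@dataclass
class GroupComparison:
    """Distribution-gated two-group test for one variable."""

    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    levene_p: float
    test: str          # "unpaired-t" | "welch-t" | "mann-whitney"
    statistic: float
    p_value: float


def group_compare(matrix: FeatureMatrix, group_labels: Optional[pd.Series] = None,
                  alpha: float = 0.05) -> list[GroupComparison]:
    """Per-variable two-group comparison with a normality/homoscedasticity
    gate: Shapiro-Wilk per group and Levene across groups select an unpaired
    t-test (Welch under unequal variances) when both groups are normal,
    otherwise Mann-Whitney."""
    labels = group_labels if group_labels is not None else matrix.groups
    if labels is None:
        raise DataError("group_compare requires group labels")
    labels = labels.reindex(matrix.values.index)
    names = sorted(labels.dropna().unique().tolist())
    if len(names) != 2:
        raise DataError(f"group_compare requires exactly two groups, got {names}")
    a_idx = labels == names[0]
    b_idx = labels == names[1]
    if a_idx.sum() < 3 or b_idx.sum() < 3:
        raise DataError("each group needs at least 3 subjects")

    results = []
    for col in matrix.values.columns:
        a = matrix.values.loc[a_idx, col].to_numpy(float)
        b = matrix.values.loc[b_idx, col].to_numpy(float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            sw_a = sw_b = lev_p = 1.0
        else:
            sw_a = float(sps.shapiro(a).pvalue) if np.ptp(a) > 0 else 0.0
            sw_b = float(sps.shapiro(b).pvalue) if np.ptp(b) > 0 else 0.0
            lev_p = float(sps.levene(a, b).pvalue)
        normal = sw_a >= alpha and sw_b >= alpha
        if not normal:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
        elif lev_p < alpha:
            stat, p = sps.ttest_ind(a, b, equal_var=False)
            test = "welch-t"
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=True)
            test = "unpaired-t"
        results.append(GroupComparison(
            variable=str(col),
            mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
            mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
            shapiro_p_a=sw_a, shapiro_p_b=sw_b, levene_p=lev_p,
            test=test, statistic=float(stat), p_value=float(p),
        ))
    return results
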