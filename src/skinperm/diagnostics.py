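"""Applicability-domain and dimensionality diagnostics.

Influence screening flags training records whose studentized residual,
leverage (hat value) or Cook's distance exceeds configurable cutoffs —
the standard delineation of a QSAR's applicability domain. Flagged
records are reported for a human exclusion-or-retain decision; nothing
is removed automatically.

PCA on the descriptor matrix (correlation-matrix PCA by default, since
Abraham descriptors and log K columns live on incommensurate scales)
quantifies how many effective dimensions the descriptor set carries;
cos2 — the squared correlation between a variable and a component —
measures each variable's quality of representation per dimension.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import FitResult
from .errors import SampleSizeError, ZeroVarianceError

_VAR_TOL = 1e-12


@dataclass
class DiagnosticsResult:
    """Per-record influence measures and applicability-domain flags."""

    table: pd.DataFrame  # studentized, hat, cooks + boolean flag columns
    thresholds: dict[str, float]
    n_parameters: int

    @property
    def flagged_ids(self) -> list:
        any_flag = (
            self.table["residual_outlier"]
            | self.table["high_leverage"]
            | self.table["influential"]
        )
        return list(self.table.index[any_flag])


def influence_diagnostics(
    fit: FitResult,
    resid_threshold: float = 3.0,
    hat_multiplier: float = 3.0,
    cooks_threshold: float | None = None,
) -> DiagnosticsResult:
    """Externally studentized residuals, leverage and Cook's distance.

    Default cutoffs: |studentized residual| > 3, hat > 3(p+1)/n,
    Cook's D > 4/n (all configurable). Requires the fit's stored design
    context and n > p + 2 so studentization is defined.
    """
    res = fit._sm_results
    if res is None:
        raise ValueError("fit carries no stored design context")
    n, p1 = fit._X.shape
    if n <= p1 + 1:
        raise SampleSizeError(
            f"externally studentized residuals need n > p + 2; got n={n}, p+1={p1}"
        )
    infl = res.get_influence()
    hat = infl.hat_matrix_diag
    # exact fits studentize to 0/0 round-off noise; report 0 (no evidence
    # of outlyingness) when the residual scale is numerically zero
    resid_scale = float(np.sqrt(np.mean(res.resid**2)))
    y_scale = max(1.0, float(np.max(np.abs(fit._y))))
    if resid_scale < 1e-10 * y_scale:
        student = np.zeros(n)
        cooks = np.zeros(n)
    else:
        student = infl.resid_studentized_external
        cooks = infl.cooks_distance[0]
        student = np.where(np.isfinite(student), student, 0.0)

    hat_cut = hat_multiplier * p1 / n
    cooks_cut = 4.0 / n if cooks_threshold is None else cooks_threshold
    table = pd.DataFrame(
        {
            "studentized_residual": student,
            "hat": hat,
            "cooks_distance": cooks,
        },
        index=fit._index,
    )
    table["residual_outlier"] = np.abs(student) > resid_threshold
    table["high_leverage"] = hat > hat_cut
    table["influential"] = cooks > cooks_cut
    return DiagnosticsResult(
        table=table,
        thresholds={
            "studentized_residual": resid_threshold,
            "hat": hat_cut,
            "cooks_distance": cooks_cut,
        },
        n_parameters=p1,
    )


@dataclass
class PCAResult:
    """Eigenstructure of a descriptor matrix."""

    eigenvalues: np.ndarray          # descending
    variance_fraction: np.ndarray
    cumulative_variance: np.ndarray
    loadings: pd.DataFrame           # variables x dimensions
    cos2: pd.DataFrame               # same shape; quality of representation
    scaled: bool

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "cumulative_variance": self.cumulative_variance.tolist(),
            "loadings": {
                c: self.loadings[c].tolist() for c in self.loadings.columns
            },
            "cos2": {c: self.cos2[c].tolist() for c in self.cos2.columns},
            "variables": list(self.loadings.index),
            "scaled": self.scaled,
        }


def pca(data: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of a numeric matrix via eigendecomposition.

    With ``scale=True`` (default) the correlation matrix is decomposed:
    eigenvalues sum to the number of variables, loadings are
    variable-component correlations and cos2 (squared loadings) sums to
    one per variable across all dimensions. With ``scale=False`` the
    covariance matrix is decomposed instead.

    Loading signs are fixed deterministically: within each dimension the
    largest-magnitude loading is made positive.
    """
    df = pd.DataFrame(data).apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        raise ValueError("PCA input must not contain missing entries")
    n, m = df.shape
    if m < 2 or n < 3:
        raise SampleSizeError("PCA needs at least 2 columns and 3 rows")
    variances = df.var(ddof=1)
    if scale:
        dead = variances[variances < _VAR_TOL]
        if len(dead):
            raise ZeroVarianceError(str(dead.index[0]))
        C = np.corrcoef(df.to_numpy(float), rowvar=False)
    else:
        C = np.cov(df.to_numpy(float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign convention
    for j in range(m):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = eigvec * np.sqrt(eigval)
    if scale:
        cos2 = loadings**2
    else:
        with np.errstate(invalid="ignore"):
            cos2 = loadings**2 / np.diag(C)[:, None]
    frac = eigval / eigval.sum()
    dims = [f"dim{j + 1}" for j in range(m)]
    return PCAResult(
        eigenvalues=eigval,
        variance_fraction=frac,
        cumulative_variance=np.cumsum(frac),
        loadings=pd.DataFrame(loadings, index=df.columns, columns=dims),
        cos2=pd.DataFrame(cos2, index=df.columns, columns=dims),
        scaled=scale,
    )


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with significance and per-pair n."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    undefined_pairs: list[tuple[str, str]]


def correlation_matrix(data: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation matrix with p-values.

    Each pair uses its complete rows (n reported per pair; at least 3
    required). Pairs involving a constant column are flagged undefined
    rather than silently set to NaN.
    """
    df = pd.DataFrame(data).apply(pd.to_numeric, errors="coerce")
    cols = list(df.columns)
    m = len(cols)
    r = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    nmat = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    undefined: list[tuple[str, str]] = []
    for i in range(m):
        nmat.iloc[i, i] = int(df[cols[i]].notna().sum())
    for i in range(m):
        for j in range(i + 1, m):
            sub = df[[cols[i], cols[j]]].dropna()
            n_ij = len(sub)
            nmat.iloc[i, j] = nmat.iloc[j, i] = n_ij
            if n_ij < 3:
                raise SampleSizeError(
                    f"pair ({cols[i]}, {cols[j]}) has {n_ij} complete rows; need >= 3"
                )
            x = sub[cols[i]].to_numpy(float)
            y = sub[cols[j]].to_numpy(float)
            if np.std(x) < _VAR_TOL or np.std(y) < _VAR_TOL:
                undefined.append((cols[i], cols[j]))
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = float(res.statistic)
            p.iloc[i, j] = p.iloc[j, i] = float(res.pvalue)
    return CorrelationMatrix(r=r, p=p, n=nmat, undefined_pairs=undefined)
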