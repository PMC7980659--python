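"""OLS calibration and validation of two-parameter LFERs.

Fits log Kp on a chosen descriptor pair (or any predictor set) by
ordinary least squares and reports the full validation battery used in
QSAR practice: R^2, adjusted R^2, leave-one-out Q^2 and PRESS RMSE,
bootstrap coefficient standard errors, k-fold / repeated k-fold / LOO /
bootstrap cross-validation, AIC/t-test/VIF stepwise descriptor
selection, seeded train/validation splitting, and model-vs-model RMSE
comparison.

Conventions (recorded because the field is not unanimous):

* RMSE uses denominator n (not n - p - 1) for both fit and comparison
  RMSEs, so resubstitution, cross-validated and cross-model errors are
  commensurable.
* Q^2 = 1 - PRESS / TSS with TSS about the training mean; PRESS RMSE =
  sqrt(PRESS / n). The hat-matrix shortcut e_i / (1 - h_i) is used and
  equals an explicit leave-one-out refit loop to numerical precision.
* Comparison R^2 is reported both as squared Pearson correlation
  (``r2``) and as coefficient of determination about the 1:1 line
  (``r2_identity``).
* k-fold folds are formed by seeded shuffle followed by chunking;
  k = n reproduces leave-one-out exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import (
    CollinearityError,
    DegenerateDataError,
    FoldError,
    SampleSizeError,
    SplitError,
    UnitError,
)
from .types import LFERCoefficients, UNIT_CM_S

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def _prepare(
    data: pd.DataFrame, response: str, predictors: Sequence[str]
) -> tuple[pd.DataFrame, int]:
    """Select complete cases for the given columns; return (subframe, n_dropped)."""
    cols = [response, *predictors]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise KeyError(f"columns not in data: {', '.join(missing_cols)}")
    sub = data[cols].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info(
            "dropped %d of %d records with missing values in %s",
            n_dropped, len(sub), cols,
        )
    return complete, n_dropped


def _find_dependent_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that are (numerically) linear combinations of earlier ones."""
    dependent = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        if not kept:
            if np.allclose(X[:, j], 0.0):
                dependent.append(names[j])
            else:
                kept.append(j)
            continue
        A = X[:, kept]
        coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ coef
        scale = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(resid) < 1e-8 * scale:
            dependent.append(names[j])
        else:
            kept.append(j)
    return dependent


# ---------------------------------------------------------------------------
# fit result container
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A fitted OLS regression with its QSAR validation statistics."""

    coefficients: LFERCoefficients
    n: int
    r2: float
    adj_r2: float
    q2_loo: float
    rmse: float
    press_rmse: float
    residuals: pd.Series
    fitted: pd.Series
    response: str
    predictors: list[str]
    bootstrap_standard_errors: dict[str, float] | None = None
    r2_undefined: bool = False
    n_dropped: int = 0
    rmse_denominator: str = "n"
    # regression context retained for diagnostics / LOO shortcuts
    _sm_results: object = field(default=None, repr=False)
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)
    _index: pd.Index = field(default=None, repr=False)

    @property
    def params(self) -> dict[str, float]:
        d = {"intercept": self.coefficients.intercept}
        d.update(self.coefficients.coefficients)
        return d

    def predict(self, data: pd.DataFrame) -> pd.Series:
        vals = self.coefficients.intercept + sum(
            c * pd.to_numeric(data[k], errors="coerce")
            for k, c in self.coefficients.coefficients.items()
        )
        return pd.Series(np.asarray(vals, dtype=float), index=data.index)

    def to_dict(self) -> dict:
        return {
            "model": self.coefficients.to_dict(),
            "n": self.n,
            "n_dropped": self.n_dropped,
            "response": self.response,
            "predictors": list(self.predictors),
            "r2": None if self.r2_undefined else self.r2,
            "adj_r2": None if self.r2_undefined else self.adj_r2,
            "q2_loo": None if self.r2_undefined else self.q2_loo,
            "rmse": self.rmse,
            "press_rmse": self.press_rmse,
            "r2_undefined": self.r2_undefined,
            "rmse_denominator": self.rmse_denominator,
            "bootstrap_standard_errors": self.bootstrap_standard_errors,
        }


def fit_ols(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    model_name: str = "ols_fit",
    output_unit: str = UNIT_CM_S,
) -> FitResult:
    """Fit response ~ intercept + predictors by ordinary least squares.

    Records with missing values in any selected column are excluded (the
    count is logged and stored on the result). Raises a collinearity
    error naming the dependent columns on a rank-deficient design, and a
    sample-size error when n <= p + 1.
    """
    predictors = list(predictors)
    complete, n_dropped = _prepare(data, response, predictors)
    n, p = len(complete), len(predictors)
    if n <= p + 1:
        raise SampleSizeError(
            f"need more than {p + 1} complete records to fit {p} predictors; got {n}"
        )
    X = complete[predictors].to_numpy(dtype=float)
    y = complete[response].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        dep = _find_dependent_columns(Xc[:, 1:], predictors)
        raise CollinearityError(dep or predictors)

    res = sm.OLS(y, Xc).fit()
    resid = pd.Series(res.resid, index=complete.index)
    fitted = pd.Series(res.fittedvalues, index=complete.index)
    rmse = float(np.sqrt(np.mean(res.resid**2)))

    tss = float(np.sum((y - y.mean()) ** 2))
    r2_undefined = tss < _RANK_TOL
    h = res.get_influence().hat_matrix_diag
    e_loo = res.resid / (1.0 - h)
    press = float(np.sum(e_loo**2))
    press_rmse = float(np.sqrt(press / n))
    if r2_undefined:
        r2 = adj_r2 = q2 = float("nan")
    else:
        r2 = float(res.rsquared)
        adj_r2 = float(res.rsquared_adj)
        q2 = 1.0 - press / tss

    coeffs = LFERCoefficients(
        model_name=model_name,
        intercept=float(res.params[0]),
        coefficients={name: float(b) for name, b in zip(predictors, res.params[1:])},
        standard_errors={
            "intercept": float(res.bse[0]),
            **{name: float(se) for name, se in zip(predictors, res.bse[1:])},
        },
        output_unit=output_unit,
        n_train=n,
        notes=f"OLS fit of {response} on {', '.join(predictors)}",
    )
    return FitResult(
        coefficients=coeffs,
        n=n,
        r2=r2,
        adj_r2=adj_r2,
        q2_loo=q2,
        rmse=rmse,
        press_rmse=press_rmse,
        residuals=resid,
        fitted=fitted,
        response=response,
        predictors=predictors,
        r2_undefined=r2_undefined,
        n_dropped=n_dropped,
        _sm_results=res,
        _X=Xc,
        _y=y,
        _index=complete.index,
    )


def press_q2(fit: FitResult) -> tuple[float, float]:
    """Leave-one-out Q^2 and PRESS RMSE via the hat-matrix shortcut.

    PRESS = sum of squared LOO prediction errors e_i / (1 - h_i);
    press_rmse = sqrt(PRESS / n); Q^2 = 1 - PRESS / TSS.
    """
    res = fit._sm_results
    n, p1 = fit._X.shape
    if n <= p1:
        raise SampleSizeError("leave-one-out undefined: n <= number of parameters")
    h = res.get_influence().hat_matrix_diag
    e_loo = res.resid / (1.0 - h)
    press = float(np.sum(e_loo**2))
    tss = float(np.sum((fit._y - fit._y.mean()) ** 2))
    press_rmse = float(np.sqrt(press / n))
    q2 = float("nan") if tss < _RANK_TOL else 1.0 - press / tss
    return q2, press_rmse


def loo_predictions_explicit(
    data: pd.DataFrame, response: str, predictors: Sequence[str]
) -> pd.Series:
    """Leave-one-out predictions by n explicit refits (oracle path).

    Kept deliberately independent of the hat-matrix shortcut so the two
    can be cross-checked.
    """
    complete, _ = _prepare(data, response, predictors)
    X = sm.add_constant(complete[list(predictors)].to_numpy(float), has_constant="add")
    y = complete[response].to_numpy(float)
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        preds[i] = X[i] @ beta
    return pd.Series(preds, index=complete.index)


# ---------------------------------------------------------------------------
# bootstrap standard errors
# ---------------------------------------------------------------------------


def bootstrap_se(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict[str, float]:
    """Case-resampling bootstrap standard errors of OLS coefficients.

    Each replicate resamples n records with replacement and refits;
    the SE is the standard deviation of each coefficient across
    replicates. Rank-deficient resamples are redrawn (the count is
    logged); if redraws exceed half of n_boot the data are declared
    degenerate.
    """
    if n_boot < 2:
        raise SampleSizeError(f"n_boot must be >= 2, got {n_boot}")
    predictors = list(predictors)
    complete, _ = _prepare(data, response, predictors)
    X = sm.add_constant(complete[predictors].to_numpy(float), has_constant="add")
    y = complete[response].to_numpy(float)
    n, p1 = X.shape
    if n <= p1:
        raise SampleSizeError("too few complete records for bootstrap")
    rng = np.random.default_rng(seed)

    betas = np.empty((n_boot, p1))
    filled = 0
    redraws = 0
    while filled < n_boot:
        want = n_boot - filled
        idx = rng.integers(0, n, size=(want, n))
        Xb = X[idx]                      # (want, n, p1)
        yb = y[idx]                      # (want, n)
        XtX = np.einsum("bni,bnj->bij", Xb, Xb)
        Xty = np.einsum("bni,bn->bi", Xb, yb)
        eig = np.linalg.eigvalsh(XtX)
        ok = eig[:, 0] > _RANK_TOL * np.maximum(eig[:, -1], 1.0)
        good = int(ok.sum())
        if good:
            betas[filled : filled + good] = np.linalg.solve(
                XtX[ok], Xty[ok][..., None]
            )[..., 0]
            filled += good
        redraws += want - good
        if redraws > n_boot / 2:
            raise DegenerateDataError(
                f"more than half of bootstrap resamples ({redraws}) were "
                "rank deficient"
            )
    if redraws:
        logger.info("redrew %d rank-deficient bootstrap resamples", redraws)
    ses = betas.std(axis=0, ddof=1)
    return {"intercept": float(ses[0]), **{
        name: float(se) for name, se in zip(predictors, ses[1:])
    }}


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Held-out performance under one cross-validation scheme."""

    scheme: str
    params: dict
    fold_metrics: list[dict]
    rmse: float
    r2: float
    predictions: pd.Series | None = None  # per-record held-out predictions
    r2_undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "params": dict(self.params),
            "rmse": self.rmse,
            "r2": None if self.r2_undefined else self.r2,
            "folds": self.fold_metrics,
        }


def _pooled_metrics(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float, bool]:
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.std(obs) < _RANK_TOL or np.std(pred) < _RANK_TOL:
        return rmse, float("nan"), True
    r = float(np.corrcoef(obs, pred)[0, 1])
    return rmse, r * r, False


def cross_validate(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    scheme: str = "kfold",
    k: int = 10,
    repeats: int = 3,
    n_boot: int = 1000,
    seed: int | None = None,
) -> CVResult:
    """Cross-validate an OLS model under kfold / repeated_kfold / loo / bootstrap.

    Folds are formed by seeded shuffle-then-chunk; aggregate RMSE is the
    root of the mean squared held-out error pooled over all folds (and
    repeats / replicates). ``kfold`` with k = n is exactly leave-one-out.
    For the bootstrap scheme each replicate trains on an n-sized
    resample with replacement and tests on the out-of-bag records.
    """
    predictors = list(predictors)
    complete, _ = _prepare(data, response, predictors)
    X = sm.add_constant(complete[predictors].to_numpy(float), has_constant="add")
    y = complete[response].to_numpy(float)
    n, p1 = X.shape
    rng = np.random.default_rng(seed)

    def fit_predict(train: np.ndarray, test: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
        return X[test] @ beta

    fold_metrics: list[dict] = []

    if scheme in ("kfold", "repeated_kfold", "loo"):
        if scheme == "loo":
            k_eff, n_rep = n, 1
        elif scheme == "kfold":
            k_eff, n_rep = k, 1
        else:
            k_eff, n_rep = k, repeats
        if k_eff > n:
            raise FoldError(f"k={k_eff} exceeds n={n}")
        if k_eff < 2:
            raise FoldError("k must be at least 2")
        all_obs, all_pred = [], []
        per_record = np.full(n, np.nan) if n_rep == 1 else None
        for rep in range(n_rep):
            order = rng.permutation(n)
            for f, test in enumerate(np.array_split(order, k_eff)):
                train = np.setdiff1d(np.arange(n), test)
                pred = fit_predict(train, test)
                all_obs.append(y[test])
                all_pred.append(pred)
                if per_record is not None:
                    per_record[test] = pred
                fold_metrics.append({
                    "repeat": rep,
                    "fold": f,
                    "n_test": int(len(test)),
                    "rmse": float(np.sqrt(np.mean((y[test] - pred) ** 2))),
                })
        if per_record is not None:
            # pool in record order so kfold with k = n equals LOO bit-for-bit
            obs, pred = y, per_record
            predictions = pd.Series(per_record, index=complete.index)
        else:
            obs = np.concatenate(all_obs)
            pred = np.concatenate(all_pred)
            predictions = None
        params = {"k": k_eff, "repeats": n_rep, "seed": seed}
    elif scheme == "bootstrap":
        if n_boot < 2:
            raise FoldError("bootstrap cross-validation needs n_boot >= 2")
        all_obs, all_pred = [], []
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), np.unique(idx))
            if len(oob) == 0:
                continue
            try:
                pred = fit_predict(idx, oob)
            except np.linalg.LinAlgError:  # pragma: no cover - lstsq rarely raises
                continue
            all_obs.append(y[oob])
            all_pred.append(pred)
            fold_metrics.append({
                "replicate": b,
                "n_test": int(len(oob)),
                "rmse": float(np.sqrt(np.mean((y[oob] - pred) ** 2))),
            })
        obs = np.concatenate(all_obs)
        pred = np.concatenate(all_pred)
        predictions = None
        params = {"n_boot": n_boot, "seed": seed}
    else:
        raise FoldError(
            f"unknown scheme '{scheme}'; expected kfold, repeated_kfold, loo or bootstrap"
        )

    rmse, r2, undef = _pooled_metrics(obs, pred)
    return CVResult(
        scheme=scheme,
        params=params,
        fold_metrics=fold_metrics,
        rmse=rmse,
        r2=r2,
        predictions=predictions,
        r2_undefined=undef,
    )


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    selected: list[str]
    fit: FitResult | None
    trace: list[str]
    empty_model: bool = False


def stepwise_select(
    data: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    p_out: float = 0.05,
    vif_max: float = 10.0,
) -> StepwiseResult:
    """Bidirectional stepwise MLR driven by AIC entry and t-test/VIF removal.

    Forward step: admit the candidate that most lowers AIC (candidates
    whose entry would push any VIF above ``vif_max`` — e.g. a perfect
    duplicate of a term already in the model — are rejected with a trace
    entry). Backward step: drop terms with coefficient p-value > p_out
    or VIF > vif_max, worst first. Iterate to a fixed point. An empty
    final model is returned flagged, not raised.
    """
    if not candidates:
        raise SampleSizeError("stepwise selection needs at least one candidate")
    candidates = list(candidates)
    complete, _ = _prepare(data, response, candidates)
    y = complete[response].to_numpy(float)

    def aic_of(cols: list[str]) -> float:
        X = sm.add_constant(
            complete[cols].to_numpy(float) if cols else np.empty((len(y), 0)),
            has_constant="add",
        )
        return float(sm.OLS(y, X).fit().aic)

    def vifs_of(cols: list[str]) -> dict[str, float]:
        if len(cols) < 2:
            return {c: 1.0 for c in cols}
        X = sm.add_constant(complete[cols].to_numpy(float), has_constant="add")
        out = {}
        for j, c in enumerate(cols):
            with np.errstate(divide="ignore"):
                out[c] = float(variance_inflation_factor(X, j + 1))
        return out

    selected: list[str] = []
    trace: list[str] = []
    # a term dropped by backward elimination may not re-enter; without this
    # bar, a candidate with AIC-worthy but t-test-unworthy support
    # (0.05 < p < ~0.157) would cycle in and out forever
    banned: set[str] = set()
    changed = True
    while changed:
        changed = False
        # forward: best AIC improvement among remaining candidates
        current_aic = aic_of(selected)
        best_gain, best_cand = 0.0, None
        for c in candidates:
            if c in selected or c in banned:
                continue
            trial = selected + [c]
            v = vifs_of(trial)
            if max(v.values(), default=0.0) > vif_max or not np.isfinite(
                max(v.values(), default=0.0)
            ):
                trace.append(f"reject {c}: entry VIF exceeds {vif_max}")
                continue
            gain = current_aic - aic_of(trial)
            if gain > best_gain + 1e-9:
                best_gain, best_cand = gain, c
        if best_cand is not None:
            selected.append(best_cand)
            trace.append(f"add {best_cand}: AIC -{best_gain:.3f}")
            changed = True
        # backward: prune by VIF then by p-value
        while selected:
            v = vifs_of(selected)
            worst_vif = max(selected, key=lambda c: v[c])
            if v[worst_vif] > vif_max:
                selected.remove(worst_vif)
                banned.add(worst_vif)
                trace.append(f"drop {worst_vif}: VIF {v[worst_vif]:.2f} > {vif_max}")
                changed = True
                continue
            X = sm.add_constant(complete[selected].to_numpy(float), has_constant="add")
            pvals = sm.OLS(y, X).fit().pvalues[1:]
            worst_j = int(np.argmax(pvals))
            if pvals[worst_j] > p_out:
                dropped = selected.pop(worst_j)
                banned.add(dropped)
                trace.append(f"drop {dropped}: p={pvals[worst_j]:.4f} > {p_out}")
                changed = True
                continue
            break

    if not selected:
        trace.append("no candidate admitted: empty model")
        return StepwiseResult(selected=[], fit=None, trace=trace, empty_model=True)
    fit = fit_ols(complete, response, selected, model_name="stepwise_fit")
    return StepwiseResult(selected=selected, fit=fit, trace=trace)


# ---------------------------------------------------------------------------
# splitting and model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """A reproducible train/validation partition of record ids."""

    train_ids: tuple
    validation_ids: tuple
    train_fraction: float
    seed: int | None

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.train_ids), len(self.validation_ids)


def split_train_validation(
    ids: Sequence, train_fraction: float, seed: int | None = None
) -> SplitSpec:
    """Uniform random split without replacement, reproducible by seed.

    Train size is round(fraction * n); e.g. 175 records at 0.8 give
    140/35 and 79 records at 64/79 give 64/15.
    """
    if not 0.0 < train_fraction < 1.0:
        raise SplitError(f"train fraction must be in (0, 1), got {train_fraction}")
    ids = list(ids)
    n = len(ids)
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise SplitError(
            f"fraction {train_fraction} leaves an empty side for n={n}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    valid = tuple(ids[i] for i in sorted(order[n_train:]))
    return SplitSpec(train, valid, train_fraction, seed)


@dataclass
class ComparisonResult:
    """Paired comparison of two log Kp series (reference vs candidate)."""

    reference_name: str
    candidate_name: str
    n: int
    rmse: float
    r2: float                 # squared Pearson correlation
    r2_identity: float        # coefficient of determination about the 1:1 line
    pairs: pd.DataFrame
    r2_undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "reference": self.reference_name,
            "candidate": self.candidate_name,
            "n": self.n,
            "rmse": self.rmse,
            "r2": None if self.r2_undefined else self.r2,
            "r2_identity": None if self.r2_undefined else self.r2_identity,
        }


def compare_models(
    reference: pd.Series,
    candidate: pd.Series,
    reference_unit: str | None = None,
    candidate_unit: str | None = None,
    reference_name: str = "reference",
    candidate_name: str = "candidate",
) -> ComparisonResult:
    """RMSE and R^2 between paired log Kp series.

    Units, when provided, must match exactly — there is no silent
    conversion. Incomplete pairs are dropped; at least two complete
    pairs are required. RMSE is symmetric in its arguments.
    """
    if (
        reference_unit is not None
        and candidate_unit is not None
        and reference_unit != candidate_unit
    ):
        raise UnitError(
            f"unit mismatch: reference in {reference_unit}, candidate in "
            f"{candidate_unit}; convert explicitly before comparing"
        )
    ref = pd.to_numeric(pd.Series(reference), errors="coerce")
    cand = pd.to_numeric(pd.Series(candidate), errors="coerce")
    pairs = pd.DataFrame({"reference": ref, "candidate": cand}).dropna()
    n = len(pairs)
    if n < 2:
        raise SampleSizeError(f"need at least 2 complete pairs, got {n}")
    diff = pairs["candidate"] - pairs["reference"]
    rmse = float(np.sqrt(np.mean(diff**2)))
    r_obs = pairs["reference"].to_numpy()
    r_pred = pairs["candidate"].to_numpy()
    undef = np.std(r_obs) < _RANK_TOL or np.std(r_pred) < _RANK_TOL
    if undef:
        r2 = r2_id = float("nan")
    else:
        r = float(np.corrcoef(r_obs, r_pred)[0, 1])
        r2 = r * r
        tss = float(np.sum((r_obs - r_obs.mean()) ** 2))
        r2_id = 1.0 - float(np.sum(diff**2)) / tss
    pairs = pairs.assign(residual=diff)
    return ComparisonResult(
        reference_name=reference_name,
        candidate_name=candidate_name,
        n=n,
        rmse=rmse,
        r2=r2,
        r2_identity=r2_id,
        pairs=pairs,
        r2_undefined=undef,
    )
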