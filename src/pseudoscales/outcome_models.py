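"""Per-scale logistic outcome models.

One model is fitted per (scale, outcome): the standardized annual burden
score, residual polypharmacy, and the confounder set predict the binary
outcome.  Before fitting, the per-model pipeline applies complete-case
filtering, one-sided >k SD outlier removal on burden and residual
polypharmacy, standardization of numeric columns, and (optionally) SMOTE
rebalancing of the minority class.  Effects are reported as the odds ratio
per 1 SD of the burden score, with a 95% Wald interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.neighbors import NearestNeighbors

from .burden_scoring import remove_outliers, standardize
from .scale_registry import ScaleDefinition, ValidationError
from .synthetic_cohort import covariate_matrix

__all__ = [
    "ModelResult",
    "ModelConfig",
    "smote_resample",
    "fit_logistic",
    "run_scale_models",
    "results_frame",
]

logger = logging.getLogger(__name__)

_WALD_Z = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class ModelResult:
    """Effect of one scale's burden score on one outcome."""

    scale_id: str
    outcome: str
    or_per_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    scale_size: int
    kind: str = "pseudoscale"
    mode: str = "none"
    pool: str = "none"
    template_scale_id: str = ""
    converged: bool = True
    reason: str = ""


@dataclass
class ModelConfig:
    """Per-model pipeline switches (adjusted/unadjusted, SMOTE on/off)."""

    adjusted: bool = True
    smote: bool = True
    smote_ratio: float = 1.0
    k_neighbors: int = 5
    outlier_k: float = 4.0
    seed: int = 0


def smote_resample(
    features,
    labels,
    k_neighbors: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
    categorical_cols=None,
):
    """Synthetic minority oversampling (SMOTE).

    New minority points are drawn uniformly on the segment between a random
    minority sample and one of its ``k_neighbors`` nearest minority
    neighbors (Euclidean distance).  Columns listed in ``categorical_cols``
    (indices or column names) are not interpolated: synthetic rows copy the
    seed sample's values.  Originals are always retained; the minority
    class is grown to ``target_ratio`` times the majority count.
    """
    is_frame = isinstance(features, pd.DataFrame)
    X = features.to_numpy(dtype=float) if is_frame else np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("features must be 2-D and aligned with labels")
    if not np.isfinite(X).all():
        raise ValidationError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("labels must be binary")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(round(target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return features, labels
    if n_min <= k_neighbors:
        raise ValidationError(
            f"minority class has {n_min} samples; needs > k_neighbors "
            f"({k_neighbors}) — use a smaller k"
        )
    cat_idx = np.array([], dtype=int)
    if categorical_cols is not None:
        if is_frame and len(categorical_cols) and isinstance(
            next(iter(categorical_cols)), str
        ):
            cat_idx = np.array(
                [features.columns.get_loc(c) for c in categorical_cols], dtype=int
            )
        else:
            cat_idx = np.asarray(list(categorical_cols), dtype=int)

    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, neigh = nn.kneighbors(Xm)  # first column is the point itself
    base = rng.integers(0, len(Xm), size=n_new)
    pick = neigh[base, rng.integers(1, k_neighbors + 1, size=n_new)]
    lam = rng.random(n_new)[:, None]
    synth = Xm[base] + lam * (Xm[pick] - Xm[base])
    if cat_idx.size:
        synth[:, cat_idx] = Xm[base][:, cat_idx]

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    if is_frame:
        X_out = pd.DataFrame(X_out, columns=features.columns)
        y_out = pd.Series(y_out, name=getattr(labels, "name", None))
    return X_out, y_out


def fit_logistic(
    features: pd.DataFrame, labels, burden_col: str = "burden"
) -> ModelResult:
    """Maximum-likelihood logistic fit; OR per 1 SD of ``burden_col``.

    Degenerate fits (separation, non-convergence, unidentified standard
    errors) return a flagged result rather than raising.
    """
    if burden_col not in features.columns:
        raise ValidationError(f"missing burden column {burden_col!r}")
    X = sm.add_constant(features.astype(float), has_constant="add")
    y = np.asarray(labels, dtype=float)

    def _flagged(reason: str) -> ModelResult:
        return ModelResult(
            scale_id="",
            outcome="",
            or_per_sd=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
            n_used=len(y),
            scale_size=0,
            converged=False,
            reason=reason,
        )

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence reported via retvals
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, method="newton")
    except Exception as exc:  # separation, singular Hessian, ...
        return _flagged(f"{type(exc).__name__}: {exc}")
    if not fit.mle_retvals.get("converged", False):
        return _flagged("did not converge")
    coef = float(fit.params[burden_col])
    se = float(fit.bse[burden_col])
    if not (np.isfinite(coef) and np.isfinite(se)) or se > 1e3:
        return _flagged("unstable standard error")
    p = float(fit.pvalues[burden_col])
    return ModelResult(
        scale_id="",
        outcome="",
        or_per_sd=float(np.exp(coef)),
        ci_low=float(np.exp(coef - _WALD_Z * se)),
        ci_high=float(np.exp(coef + _WALD_Z * se)),
        p_value=p,
        n_used=len(y),
        scale_size=0,
    )


def _design_for_scale(
    sub: pd.Series,
    resid: pd.Series,
    covariates: pd.DataFrame | None,
    events: pd.Series,
    config: ModelConfig,
):
    """Complete-case filter, outlier removal, standardization; returns the
    design matrix, labels, and the list of non-interpolable columns."""
    keep = np.isfinite(sub.to_numpy()) & np.isfinite(resid.to_numpy())
    if covariates is not None:
        keep &= ~covariates.isna().any(axis=1).to_numpy()
    keep &= remove_outliers(sub.to_numpy(), config.outlier_k)
    keep &= remove_outliers(resid.to_numpy(), config.outlier_k)
    burden = sub.to_numpy()[keep]
    residual = resid.to_numpy()[keep]
    y = events.to_numpy()[keep]
    if burden.std(ddof=1) == 0:
        raise ValidationError("constant burden after filtering")
    X = pd.DataFrame({"burden": standardize(burden)})
    X["residual_polypharmacy"] = (
        standardize(residual) if residual.std(ddof=1) > 0 else 0.0
    )
    categorical: list[str] = []
    if covariates is not None:
        cov = covariates.loc[keep].reset_index(drop=True)
        for col in cov.columns:
            vals = cov[col].to_numpy(dtype=float)
            uniq = np.unique(vals)
            if set(uniq) <= {0.0, 1.0}:
                # Binary/dummy: skip if constant or quasi-separated (a zero
                # cell in the outcome cross-tab makes the MLE diverge).
                cells = [
                    ((vals == a) & (y == b)).sum() for a in (0, 1) for b in (0, 1)
                ]
                if min(cells) == 0:
                    continue
                X[col] = vals  # copied, not interpolated, by SMOTE
                categorical.append(col)
            elif vals.std(ddof=1) > 0:
                X[col] = standardize(vals)
            # constant covariates are dropped
    return X, y, categorical


def run_scale_models(
    scales,
    burden: pd.DataFrame,
    participants: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: ModelConfig | None = None,
) -> list[ModelResult]:
    """Fit one logistic model per (scale, outcome).

    ``burden`` is the long table from :func:`burden_scoring.burden_table`;
    ``outcomes`` the long (participant_id, outcome, event) table.  In the
    adjusted variant the confounder set is every generated covariate.
    """
    scales = list(scales)
    if not scales:
        raise ValidationError("empty scale list")
    cfg = config or ModelConfig()
    ids = participants["participant_id"]
    cov = covariate_matrix(participants).set_axis(ids, axis=0) if cfg.adjusted else None

    burden_wide_b = burden.pivot(
        index="participant_id", columns="scale_id", values="annual_burden"
    ).reindex(ids)
    burden_wide_r = burden.pivot(
        index="participant_id", columns="scale_id", values="residual_polypharmacy"
    ).reindex(ids)

    results: list[ModelResult] = []
    n_failed = 0
    for outcome, group in outcomes.groupby("outcome", sort=True):
        events = group.set_index("participant_id")["event"].reindex(ids)
        for scale in scales:
            sub = burden_wide_b[scale.scale_id]
            resid = burden_wide_r[scale.scale_id]
            try:
                X, y, categorical = _design_for_scale(sub, resid, cov, events, cfg)
                if cfg.smote:
                    X, y = smote_resample(
                        X,
                        y,
                        k_neighbors=cfg.k_neighbors,
                        target_ratio=cfg.smote_ratio,
                        seed=cfg.seed,
                        categorical_cols=categorical,
                    )
                res = fit_logistic(X, y, burden_col="burden")
            except ValidationError as exc:
                res = ModelResult(
                    scale_id="",
                    outcome="",
                    or_per_sd=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    p_value=float("nan"),
                    n_used=0,
                    scale_size=0,
                    converged=False,
                    reason=str(exc),
                )
            if not res.converged:
                n_failed += 1
                logger.warning(
                    "model for scale %s / outcome %s excluded: %s",
                    scale.scale_id,
                    outcome,
                    res.reason,
                )
            results.append(
                replace(
                    res,
                    scale_id=scale.scale_id,
                    outcome=str(outcome),
                    scale_size=scale.size,
                    kind=scale.kind,
                    mode=scale.provenance.mode,
                    pool=scale.provenance.pool,
                    template_scale_id=scale.provenance.template_scale_id,
                )
            )
    if n_failed:
        logger.info("%d of %d models flagged non-converged", n_failed, len(results))
    return results


def results_frame(results) -> pd.DataFrame:
    """Model results as a flat DataFrame (one row per scale x outcome)."""
    return pd.DataFrame([vars(r) for r in results])
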