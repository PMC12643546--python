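"""Per-participant annual cumulative burden scores.

For a given scale, every in-period prescription contributes the potency
score of its drug (0 if the drug is not on the scale, and 0 for
ophthalmic/otic/nasal/topical routes, which are assumed not to reach
systemic circulation); the sum is divided by the period length in years.
Residual polypharmacy (B0) is the annualized count of in-period
prescription records whose drug is *not* on the scale — a cumulative
prescription count, not a unique-drug count — used as a covariate so the
scale's coefficient estimates burden beyond mere drug quantity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scale_registry import (
    NON_SYSTEMIC_ROUTES,
    ROUTES,
    ScaleDefinition,
    ValidationError,
)

__all__ = [
    "period_years",
    "annual_burden",
    "residual_polypharmacy",
    "burden_table",
    "remove_outliers",
    "standardize",
]


def period_years(period: tuple[str, str]) -> float:
    """Length of a period in years: days/365.25, snapped to the nearest
    whole number of years when within 1% (so one calendar year divides by
    exactly 1)."""
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    days = (end - start).days + 1
    if days <= 0:
        raise ValidationError(f"period {period} has non-positive length")
    years = days / 365.25
    nearest = round(years)
    if nearest >= 1 and abs(years - nearest) < 0.01:
        return float(nearest)
    return years


def _in_period(prescriptions: pd.DataFrame, period: tuple[str, str]) -> pd.DataFrame:
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    dates = pd.to_datetime(prescriptions["issue_date"])
    return prescriptions.loc[(dates >= start) & (dates <= end)]


def _check_routes(prescriptions: pd.DataFrame) -> None:
    bad = set(prescriptions["route"].unique()) - set(ROUTES)
    if bad:
        raise ValidationError(f"unknown route labels: {sorted(bad)}")


def annual_burden(
    prescriptions: pd.DataFrame,
    scale: ScaleDefinition,
    period: tuple[str, str],
    participants=None,
) -> pd.Series:
    """Annual cumulative burden per participant under ``scale``.

    ``participants``: optional iterable of participant ids fixing the output
    index (ids without prescriptions get 0).  Defaults to the participants
    present in ``prescriptions``.
    """
    _check_routes(prescriptions)
    years = period_years(period)
    sub = _in_period(prescriptions, period)
    scores = sub["drug_id"].map(scale.potency_map).fillna(0.0)
    scores = scores.where(~sub["route"].isin(NON_SYSTEMIC_ROUTES), 0.0)
    totals = scores.groupby(sub["participant_id"]).sum() / years
    index = (
        pd.Index(participants, name="participant_id")
        if participants is not None
        else totals.index
    )
    return totals.reindex(index, fill_value=0.0).rename("annual_burden")


def residual_polypharmacy(
    prescriptions: pd.DataFrame,
    scale: ScaleDefinition,
    period: tuple[str, str],
    participants=None,
) -> pd.Series:
    """Annualized count of in-period prescriptions for drugs off the scale.

    Route is irrelevant here: membership of the drug on the scale is what
    counts.  Annualized with the same divisor as the burden score.
    """
    _check_routes(prescriptions)
    years = period_years(period)
    sub = _in_period(prescriptions, period)
    off = (~sub["drug_id"].isin(scale.potency_map)).astype(float)
    totals = off.groupby(sub["participant_id"]).sum() / years
    index = (
        pd.Index(participants, name="participant_id")
        if participants is not None
        else totals.index
    )
    return totals.reindex(index, fill_value=0.0).rename("residual_polypharmacy")


def burden_table(
    prescriptions: pd.DataFrame,
    scales,
    period: tuple[str, str],
    participants,
) -> pd.DataFrame:
    """Long table (participant_id, scale_id, annual_burden,
    residual_polypharmacy) for many scales over one cohort.

    Equivalent to calling :func:`annual_burden` and
    :func:`residual_polypharmacy` per scale, but factorizes the
    prescription stream once so scoring hundreds of scales stays fast.
    """
    _check_routes(prescriptions)
    years = period_years(period)
    sub = _in_period(prescriptions, period)
    pid_index = pd.Index(participants, name="participant_id")
    pcodes = pid_index.get_indexer(sub["participant_id"])
    valid = pcodes >= 0
    pcodes = pcodes[valid]
    drug_codes, drug_uniques = pd.factorize(sub.loc[valid, "drug_id"])
    systemic = (~sub.loc[valid, "route"].isin(NON_SYSTEMIC_ROUTES)).to_numpy(float)
    n = len(pid_index)
    frames = []
    for scale in scales:
        svec = np.array([scale.potency_map.get(d, 0.0) for d in drug_uniques])
        member = np.array([d in scale.potency_map for d in drug_uniques], dtype=float)
        b = np.bincount(pcodes, weights=svec[drug_codes] * systemic, minlength=n) / years
        r = np.bincount(pcodes, weights=1.0 - member[drug_codes], minlength=n) / years
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid_index,
                    "scale_id": scale.scale_id,
                    "annual_burden": b,
                    "residual_polypharmacy": r,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def remove_outliers(values, k: float = 4.0) -> np.ndarray:
    """Retention mask: False exactly where value > mean + k*SD.

    One-sided (high tail only); mean and sample SD are computed on the full
    input.  Zero-variance input retains everything.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty input")
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd == 0 or not np.isfinite(sd):
        return np.ones(v.size, dtype=bool)
    return v <= v.mean() + k * sd


def standardize(values) -> np.ndarray:
    """Z-scores with sample SD (ddof=1): output mean 0, SD 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values to standardize")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("zero-variance input cannot be standardized")
    return (v - v.mean()) / sd
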