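"""Synthetic primary-care cohort generator.

Emulates the statistical structure of one year of linked primary-care
prescribing for a late-middle-aged population cohort: a 525-drug formulary
with long-tailed prescribing frequencies, 23 synthetic anticholinergic
burden scales (ABS) jointly covering 214 drugs, per-participant
prescription streams with realistic route mix and a small corrupted
fraction, and binary outcomes (death, dementia, delirium) driven by a
known, configurable data-generating model:

    logit P(event) = b0 + covariates'gamma
                     + beta_polypharmacy * (annual prescription count)
                     + beta_anticholinergic * (true anticholinergic burden)

The *true* anticholinergic burden is the annual cumulative burden under a
designated generator-truth scale, so parameter-recovery experiments have a
known ground truth — something the observational study design this mimics
cannot provide.  The baseline logit ``b0`` is calibrated by bisection
against the realized event draws (common random numbers), so the marginal
prevalence matches its target to within 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .pseudoscale_sampler import normalized_potency_probs
from .scale_registry import (
    DrugEntry,
    Provenance,
    ROUTES,
    ScaleDefinition,
    ScaleRegistry,
    ValidationError,
)

__all__ = [
    "DEFAULT_PERIOD",
    "DEFAULT_EXTRACTION_DATE",
    "DEFAULT_COVARIATE_COEFFS",
    "ParticipantConfig",
    "PrescribingConfig",
    "EffectConfig",
    "CalibrationError",
    "generate_formulary",
    "generate_participants",
    "generate_prescriptions",
    "clean_prescriptions",
    "generate_outcomes",
    "covariate_matrix",
]

#: Default one-calendar-year prescribing period.
DEFAULT_PERIOD: tuple[str, str] = ("2015-01-01", "2015-12-31")

#: Date the synthetic record extract nominally ends; later issue dates are
#: "future-dated" and removed by cleaning.
DEFAULT_EXTRACTION_DATE = "2016-12-31"

#: Log-odds per unit of each covariate in the outcome model.  Age is the
#: main confounder: it raises both prescribing volume and outcome risk.
DEFAULT_COVARIATE_COEFFS: dict[str, float] = {
    "age_c": 0.085,  # per year above 65
    "female": -0.35,
    "education": -0.25,
    "deprivation": 0.04,
    "alcohol": 0.02,
    "waist_c": 0.012,  # per cm above 90
    "smoking": 0.28,
    "physical_activity": -0.22,
    "cerebrovascular_disease": 0.9,
    "provider_missing": 0.0,
    "provider_vision": 0.0,
    "provider_wales": 0.0,
    "provider_scotland": 0.1,
}

_PROVIDER_LEVELS = ("missing", "england_vision", "england_tpp", "wales", "scotland")
_PROVIDER_PROBS = (0.01, 0.09, 0.70, 0.09, 0.11)


class CalibrationError(ValidationError):
    """Raised when a prevalence target cannot be reached by the baseline."""


# ---------------------------------------------------------------------------
# Formulary and synthetic ABS registry
# ---------------------------------------------------------------------------

def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** exponent
    return w / w.sum()


def generate_formulary(
    n_drugs: int = 525,
    n_anticholinergic: int = 214,
    n_abs: int = 23,
    seed: int = 0,
    zipf_exponent: float = 1.1,
    anticholinergic_exponent: float = 1.3,
    anticholinergic_weight_share: float = 0.05,
    abs_size_range: tuple[int, int] = (15, 150),
    nonsystemic_target: float = 0.125,
    potency_probs: dict[float, float] | None = None,
) -> tuple[list[DrugEntry], ScaleRegistry]:
    """Generate the drug formulary and a registry of ``n_abs`` synthetic ABS.

    Prescribing weights are Zipf-like (``zipf_exponent``) for non-scored
    drugs; the ``n_anticholinergic`` scored drugs form their own long tail
    (``anticholinergic_exponent``) carrying ``anticholinergic_weight_share``
    of total prescribing volume — anticholinergics are prescribed, but are
    not the most dispensed drugs.  ABS sizes are uniform on
    ``abs_size_range``; within each ABS, drugs are drawn from the scored
    pool with probability proportional to prescribing weight (popular
    anticholinergics appear on most scales, as real scales do), every pool
    drug is covered by at least one ABS, and potency scores follow the
    normalized across-sampling probabilities.  Route profiles are drawn so
    the prescription-weighted expected fraction of non-systemic
    (ophthalmic/otic/nasal/topical) prescriptions equals
    ``nonsystemic_target``.
    """
    if n_anticholinergic > n_drugs:
        raise ValidationError(
            f"n_anticholinergic ({n_anticholinergic}) > n_drugs ({n_drugs})"
        )
    if n_abs < 1:
        raise ValidationError("n_abs must be >= 1")
    lo, hi = abs_size_range
    if not (1 <= lo <= hi <= n_anticholinergic):
        raise ValidationError(
            f"abs_size_range {abs_size_range} incompatible with pool of "
            f"{n_anticholinergic} drugs"
        )
    rng = np.random.default_rng(seed)

    drug_ids = np.array([f"d{i:04d}" for i in range(n_drugs)], dtype=object)
    anti_idx = rng.choice(n_drugs, size=n_anticholinergic, replace=False)
    anti_mask = np.zeros(n_drugs, dtype=bool)
    anti_mask[anti_idx] = True

    # Prescribing weights: two shuffled Zipf tails sharing total mass 1.
    weights = np.empty(n_drugs)
    n_other = n_drugs - n_anticholinergic
    w_other = _zipf_weights(n_other, zipf_exponent) * (1 - anticholinergic_weight_share)
    w_anti = _zipf_weights(n_anticholinergic, anticholinergic_exponent) * (
        anticholinergic_weight_share
    )
    weights[~anti_mask] = rng.permutation(w_other)
    weights[anti_mask] = rng.permutation(w_anti)

    # Route profiles: a minority of "local" drugs (creams, drops, sprays) are
    # mostly non-systemic; everything else nearly always systemic.  The
    # propensities are rescaled so the prescription-weighted mean equals the
    # target exactly.
    local = rng.random(n_drugs) < 0.15
    q = np.where(local, rng.beta(5.0, 2.0, n_drugs), rng.beta(1.0, 40.0, n_drugs))
    for _ in range(8):
        m = float(np.average(q, weights=weights))
        if abs(m - nonsystemic_target) < 1e-12:
            break
        q = np.clip(q * (nonsystemic_target / m), 0.0, 0.98)
    split = rng.dirichlet(np.full(4, 0.5), size=n_drugs)  # among the 4 local routes
    profiles = np.column_stack([1.0 - q, split * q[:, None]])
    profiles /= profiles.sum(axis=1, keepdims=True)

    formulary = [
        DrugEntry(
            drug_id=str(drug_ids[i]),
            name=f"drug-{i:04d}",
            prescribing_weight=float(weights[i]),
            route_profile=tuple(float(p) for p in profiles[i]),
        )
        for i in range(n_drugs)
    ]

    # Synthetic ABS: sizes uniform on [lo, hi]; guarantee joint coverage of
    # the pool, then fill remaining slots by prescribing-weight-biased draws.
    pool_ids = drug_ids[anti_mask]
    pool_w = weights[anti_mask]
    sizes = rng.integers(lo, hi + 1, size=n_abs)
    for _ in range(100):
        if sizes.sum() >= n_anticholinergic:
            break
        sizes = rng.integers(lo, hi + 1, size=n_abs)
    else:
        raise ValidationError(
            "ABS sizes cannot jointly cover the anticholinergic pool"
        )
    members: list[set[int]] = [set() for _ in range(n_abs)]
    capacity = sizes.copy()
    for j in rng.permutation(n_anticholinergic):  # coverage pass
        open_scales = np.flatnonzero(capacity > 0)
        k = int(rng.choice(open_scales, p=capacity[open_scales] / capacity[open_scales].sum()))
        members[k].add(int(j))
        capacity[k] -= 1
    for k in range(n_abs):  # weight-biased fill pass
        free = np.array(sorted(set(range(n_anticholinergic)) - members[k]))
        need = int(capacity[k])
        if need > 0:
            p = pool_w[free] / pool_w[free].sum()
            members[k].update(int(j) for j in rng.choice(free, size=need, replace=False, p=p))

    scores, probs = normalized_potency_probs(potency_probs)
    registry = ScaleRegistry()
    for k in range(n_abs):
        idx = sorted(members[k])
        assigned = rng.choice(scores, size=len(idx), p=probs)
        registry.add(
            ScaleDefinition(
                scale_id=f"SABS{k + 1:02d}",
                kind="abs",
                potency_map={str(pool_ids[j]): float(s) for j, s in zip(idx, assigned)},
                provenance=Provenance(seed=str(seed)),
            )
        )
    return formulary, registry


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------

@dataclass
class ParticipantConfig:
    """Marginal covariate distributions, loosely matching a late-middle-aged
    primary-care cohort (median age ~65, ~55% female)."""

    age_range: tuple[float, float] = (45.0, 80.0)
    age_beta: tuple[float, float] = (1.9, 1.5)  # Beta shape over age_range
    female_fraction: float = 0.55
    education_fraction: float = 0.32  # graduate degree
    deprivation_loc: float = -2.0
    deprivation_scale: float = 3.0
    alcohol_probs: tuple[float, ...] = (0.197, 0.236, 0.267, 0.114, 0.111, 0.075)
    waist_mean: float = 90.0
    waist_sd: float = 13.0
    smoking_probs: tuple[float, ...] = (0.566, 0.337, 0.097)
    activity_probs: tuple[float, ...] = (0.061, 0.036, 0.798, 0.105)
    cerebrovascular_base: float = 0.03
    cerebrovascular_age_slope: float = 0.06  # log-odds per year above 65
    provider_probs: tuple[float, ...] = _PROVIDER_PROBS


def _categorical(rng: np.random.Generator, probs, n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return rng.choice(len(p), size=n, p=p / p.sum())


def generate_participants(
    n: int,
    seed: int = 0,
    config: ParticipantConfig | None = None,
    period_end: str = DEFAULT_PERIOD[1],
) -> pd.DataFrame:
    """Generate ``n`` participants with demographic and lifestyle covariates."""
    if n < 0:
        raise ValidationError("n must be >= 0")
    cfg = config or ParticipantConfig()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.age_range
    age = lo + (hi - lo) * rng.beta(*cfg.age_beta, size=n)
    end = pd.Timestamp(period_end)
    birth = end - pd.to_timedelta(np.round(age * 365.25), unit="D")
    cere_p = expit(
        np.log(cfg.cerebrovascular_base / (1 - cfg.cerebrovascular_base))
        + cfg.cerebrovascular_age_slope * (age - 65.0)
    )
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i:06d}" for i in range(n)],
            "birth_date": birth,
            "age_at_period_end": age,
            "sex": (rng.random(n) < cfg.female_fraction).astype(int),  # 1 = female
            "data_provider": np.array(_PROVIDER_LEVELS, dtype=object)[
                _categorical(rng, cfg.provider_probs, n)
            ],
            "education": (rng.random(n) < cfg.education_fraction).astype(int),
            "deprivation": rng.normal(cfg.deprivation_loc, cfg.deprivation_scale, n),
            "alcohol": _categorical(rng, cfg.alcohol_probs, n),
            "waist": np.clip(rng.normal(cfg.waist_mean, cfg.waist_sd, n), 55, 165),
            "smoking": _categorical(rng, cfg.smoking_probs, n),
            "physical_activity": _categorical(rng, cfg.activity_probs, n),
            "cerebrovascular_disease": (rng.random(n) < cere_p).astype(int),
        }
    )
    return df


def covariate_matrix(participants: pd.DataFrame) -> pd.DataFrame:
    """Numeric confounder design shared by the outcome generator and the
    analysis models: ordinals as integer codes, provider as dummies
    (reference: the largest provider)."""
    X = pd.DataFrame(index=participants.index)
    X["age_c"] = participants["age_at_period_end"] - 65.0
    X["female"] = participants["sex"]
    X["education"] = participants["education"]
    X["deprivation"] = participants["deprivation"]
    X["alcohol"] = participants["alcohol"]
    X["waist_c"] = participants["waist"] - 90.0
    X["smoking"] = participants["smoking"]
    X["physical_activity"] = participants["physical_activity"]
    X["cerebrovascular_disease"] = participants["cerebrovascular_disease"]
    prov = participants["data_provider"]
    for level, col in [
        ("missing", "provider_missing"),
        ("england_vision", "provider_vision"),
        ("wales", "provider_wales"),
        ("scotland", "provider_scotland"),
    ]:
        X[col] = (prov == level).astype(int)
    return X.astype(float)


# ---------------------------------------------------------------------------
# Prescriptions
# ---------------------------------------------------------------------------

@dataclass
class PrescribingConfig:
    """Annual prescription-count model: negative binomial with mean rising
    with age and an individual morbidity frailty, plus a small corrupted
    fraction to exercise record cleaning."""

    mean_count: float = 12.0
    dispersion: float = 1.5  # NB size parameter; smaller = more overdispersed
    age_log_slope: float = 0.02  # log-mean per year above 65
    frailty_shape: float = 2.0  # Gamma(shape, 1/shape): mean 1
    corruption_fraction: float = 0.005
    extraction_date: str = DEFAULT_EXTRACTION_DATE


def generate_prescriptions(
    participants: pd.DataFrame,
    formulary: list[DrugEntry],
    period: tuple[str, str] = DEFAULT_PERIOD,
    seed: int = 0,
    config: PrescribingConfig | None = None,
) -> pd.DataFrame:
    """Simulate one prescribing period of issued prescriptions."""
    if len(participants) == 0 or len(formulary) == 0:
        raise ValidationError("participants and formulary must be non-empty")
    cfg = config or PrescribingConfig()
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    if start > end:
        raise ValidationError(f"period start {period[0]} after end {period[1]}")
    if (participants["birth_date"] > end).any():
        raise ValidationError("period ends before some participants are born")
    rng = np.random.default_rng(seed)
    n = len(participants)

    frailty = rng.gamma(cfg.frailty_shape, 1.0 / cfg.frailty_shape, size=n)
    mult = np.exp(cfg.age_log_slope * (participants["age_at_period_end"].to_numpy() - 65.0))
    mult = mult * frailty
    mu = cfg.mean_count * mult / mult.mean()
    r = cfg.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    total = int(counts.sum())
    pid = np.repeat(participants["participant_id"].to_numpy(), counts)
    birth = np.repeat(participants["birth_date"].to_numpy(), counts)

    weights = np.array([d.prescribing_weight for d in formulary])
    weights = weights / weights.sum()
    drug_idx = rng.choice(len(formulary), size=total, p=weights)
    drug_ids = np.array([d.drug_id for d in formulary], dtype=object)[drug_idx]

    cum = np.cumsum(np.array([d.route_profile for d in formulary]), axis=1)[drug_idx]
    route_idx = np.minimum((cum < rng.random(total)[:, None]).sum(axis=1), len(ROUTES) - 1)
    routes = np.array(ROUTES, dtype=object)[route_idx]

    n_days = (end - start).days + 1
    issue = start.to_numpy() + rng.integers(0, n_days, size=total).astype("timedelta64[D]")
    content = np.ones(total, dtype=bool)

    if cfg.corruption_fraction > 0 and total > 0:
        bad = rng.random(total) < cfg.corruption_fraction
        kind = rng.integers(0, 3, size=total)
        content[bad & (kind == 0)] = False
        pre = bad & (kind == 1)
        issue[pre] = birth[pre] - rng.integers(30, 2000, size=int(pre.sum())).astype(
            "timedelta64[D]"
        )
        fut = bad & (kind == 2)
        issue[fut] = pd.Timestamp(cfg.extraction_date).to_numpy() + rng.integers(
            1, 400, size=int(fut.sum())
        ).astype("timedelta64[D]")

    return pd.DataFrame(
        {
            "participant_id": pid,
            "drug_id": drug_ids,
            "issue_date": issue,
            "route": routes,
            "content_flag": content,
        }
    )


def clean_prescriptions(
    prescriptions: pd.DataFrame,
    participants: pd.DataFrame,
    extraction_date: str = DEFAULT_EXTRACTION_DATE,
) -> tuple[pd.DataFrame, int]:
    """Drop records lacking content, issued before birth, or future-dated.

    Returns the retained records and the number removed.
    """
    known = participants.set_index("participant_id")["birth_date"]
    unknown = ~prescriptions["participant_id"].isin(known.index)
    if unknown.any():
        bad = prescriptions.loc[unknown, "participant_id"].iloc[0]
        raise ValidationError(f"prescription references unknown participant {bad!r}")
    birth = prescriptions["participant_id"].map(known)
    keep = (
        prescriptions["content_flag"]
        & (prescriptions["issue_date"] >= birth)
        & (prescriptions["issue_date"] <= pd.Timestamp(extraction_date))
    )
    return prescriptions.loc[keep].reset_index(drop=True), int((~keep).sum())


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

@dataclass
class EffectConfig:
    """True effect parameters of the outcome-generating model."""

    beta_polypharmacy: float = 0.01  # log-odds per annual prescription
    beta_anticholinergic: float = 0.10  # log-odds per unit of true burden
    covariate_coeffs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_COEFFS)
    )
    prevalence_targets: dict[str, float] = field(
        default_factory=lambda: {"death": 0.062, "dementia": 0.016, "delirium": 0.016}
    )
    baseline_logit: dict[str, float] | None = None  # None: calibrate by bisection
    truth_scale_id: str = ""  # resolved by the pipeline against the registry

    def __post_init__(self) -> None:
        for name, p in self.prevalence_targets.items():
            if not 0 < p < 1:
                raise ValidationError(f"prevalence target for {name} not in (0,1)")


def _calibrate_baseline(
    eta: np.ndarray, u: np.ndarray, target: float, max_iter: int = 80
) -> float:
    """Bisect b0 so that mean(u < expit(b0 + eta)) hits ``target``.

    Uses the realized uniforms (common random numbers), so the function is a
    monotone step function of b0 and the achieved prevalence is within 1/n
    of the target.
    """
    lo, hi = -35.0, 15.0
    prev = lambda b: float(np.mean(u < expit(b + eta)))
    if prev(lo) > target or prev(hi) < target:
        raise CalibrationError(f"prevalence target {target} unattainable")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
    b0 = hi
    if abs(prev(b0) - target) > max(1e-3, 2.0 / len(eta)):
        raise CalibrationError(
            f"calibration failed: achieved {prev(b0):.5f} vs target {target}"
        )
    return b0


def generate_outcomes(
    participants: pd.DataFrame,
    prescriptions: pd.DataFrame,
    effects: EffectConfig,
    seed: int = 0,
    truth_scale: ScaleDefinition | None = None,
    period: tuple[str, str] = DEFAULT_PERIOD,
    max_follow_up: float = 6.8,
) -> pd.DataFrame:
    """Draw binary outcomes from the logistic data-generating model.

    ``truth_scale`` defines the true anticholinergic burden; when None the
    anticholinergic effect is structurally zero.  Follow-up time is
    generated for reporting only.
    """
    from .burden_scoring import annual_burden  # deferred: avoid import cycle

    rng = np.random.default_rng(seed)
    ids = participants["participant_id"]
    counts = (
        prescriptions.groupby("participant_id").size().reindex(ids, fill_value=0)
    ).to_numpy(dtype=float)
    if truth_scale is not None:
        burden = annual_burden(
            prescriptions, truth_scale, period, participants=ids
        ).to_numpy()
    else:
        burden = np.zeros(len(ids))

    X = covariate_matrix(participants)
    coeffs = effects.covariate_coeffs
    unknown = set(coeffs) - set(X.columns)
    if unknown:
        raise ValidationError(f"unknown covariate coefficients: {sorted(unknown)}")
    eta = X.to_numpy() @ np.array([coeffs.get(c, 0.0) for c in X.columns])
    eta = eta + effects.beta_polypharmacy * counts + effects.beta_anticholinergic * burden

    frames = []
    for outcome, target in effects.prevalence_targets.items():
        u = rng.random(len(ids))
        if effects.baseline_logit is not None and outcome in effects.baseline_logit:
            b0 = effects.baseline_logit[outcome]
        else:
            b0 = _calibrate_baseline(eta, u, target)
        event = (u < expit(b0 + eta)).astype(int)
        follow = np.where(
            event == 1,
            rng.uniform(0.25, max_follow_up, len(ids)),
            max_follow_up,
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": ids.to_numpy(),
                    "outcome": outcome,
                    "event": event,
                    "follow_up": follow,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
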