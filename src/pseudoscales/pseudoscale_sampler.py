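"""Random construction of pseudoscales.

Pseudoscales are drug-burden scales with no pharmacological rationale,
built by random sampling so that their effect estimates form a
"polypharmacy null": the distribution of effects attributable to drug
quantity alone.  Two procedures are implemented:

across-sampling
    Generic scales: size drawn uniformly on [15, 150], drugs drawn without
    replacement from a pool (all drugs, or only putatively anticholinergic
    ones), each drug independently assigned a potency score from the
    empirical score-frequency distribution of real anticholinergic scales.

within-sampling
    Scales matched to one template ABS: same number of drugs and exactly
    the template's multiset of potency scores, randomly permuted over a
    fresh random draw of drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scale_registry import (
    Provenance,
    ScaleDefinition,
    ValidationError,
)

__all__ = [
    "POTENCY_PROBS",
    "DEFAULT_SIZE_RANGE",
    "SamplingConfig",
    "normalized_potency_probs",
    "draw_scale_size",
    "sample_across",
    "sample_within",
]

#: Probability of each potency score for a drug entering an across-sampling
#: pseudoscale, estimated from score frequencies across 23 published
#: anticholinergic burden scales.  The published values sum to 0.996 — read
#: as rounding — and are renormalized before any sampling.
POTENCY_PROBS: dict[float, float] = {4.0: 0.017, 3.0: 0.25, 2.0: 0.20, 1.0: 0.52, 0.5: 0.009}

#: Bounds on the number of drugs per across-sampling pseudoscale (the range
#: of anticholinergic drug-list sizes seen in one prescribing year).
DEFAULT_SIZE_RANGE: tuple[int, int] = (15, 150)


def normalized_potency_probs(
    probs: dict[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (scores, probabilities) with probabilities rescaled to sum to 1."""
    probs = dict(POTENCY_PROBS) if probs is None else dict(probs)
    if any(p <= 0 for p in probs.values()):
        raise ValidationError("potency probabilities must be positive")
    scores = np.array(sorted(probs), dtype=float)
    p = np.array([probs[s] for s in scores], dtype=float)
    return scores, p / p.sum()


@dataclass
class SamplingConfig:
    """Parameters of one pseudoscale-construction run."""

    mode: str = "across"  # across | within
    pool: str = "general"  # general | anticholinergic
    n_scales: int = 1000
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE
    potency_probs: dict[float, float] = field(
        default_factory=lambda: dict(POTENCY_PROBS)
    )
    template_scale_id: str = ""  # within mode only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("across", "within"):
            raise ValidationError(f"unknown sampling mode {self.mode!r}")
        if self.pool not in ("general", "anticholinergic"):
            raise ValidationError(f"unknown pool {self.pool!r}")
        if self.n_scales < 1:
            raise ValidationError("n_scales must be >= 1")
        lo, hi = self.size_range
        if lo > hi:
            raise ValidationError(f"size_range min {lo} > max {hi}")


def draw_scale_size(
    size_range: tuple[int, int], rng: np.random.Generator
) -> int:
    """Integer uniform on [min, max] inclusive."""
    lo, hi = size_range
    if lo > hi:
        raise ValidationError(f"size_range min {lo} > max {hi}")
    return int(rng.integers(lo, hi + 1))


def sample_across(
    pool_drugs: set[str] | frozenset[str], config: SamplingConfig
) -> list[ScaleDefinition]:
    """Draw ``config.n_scales`` across-sampling pseudoscales from a pool.

    Drug selection is uniform without replacement; potency scores are
    independent draws from the normalized potency probabilities.  The pool
    must be at least as large as the maximum scale size (error, not
    clipping).
    """
    pool = sorted(pool_drugs)
    if len(pool) < config.size_range[1]:
        raise ValidationError(
            f"pool of {len(pool)} drugs is smaller than the maximum "
            f"scale size {config.size_range[1]}"
        )
    rng = np.random.default_rng(config.seed)
    scores, probs = normalized_potency_probs(config.potency_probs)
    pool_arr = np.array(pool, dtype=object)
    out: list[ScaleDefinition] = []
    for i in range(config.n_scales):
        size = draw_scale_size(config.size_range, rng)
        drugs = rng.choice(pool_arr, size=size, replace=False)
        assigned = rng.choice(scores, size=size, p=probs)
        out.append(
            ScaleDefinition(
                scale_id=f"across_{config.pool}_{i:04d}",
                kind="pseudoscale",
                potency_map=dict(zip(drugs.tolist(), assigned.tolist())),
                provenance=Provenance(
                    mode="across", pool=config.pool, seed=str(config.seed)
                ),
            )
        )
    return out


def sample_within(
    pool_drugs: set[str] | frozenset[str],
    template: ScaleDefinition,
    n_scales: int,
    seed: int,
    pool_label: str = "general",
) -> list[ScaleDefinition]:
    """Draw pseudoscales matched to ``template`` in size and score multiset.

    Each replicate samples ``template.size`` drugs uniformly without
    replacement from the pool (template drugs remain eligible) and permutes
    the template's potency multiset over them.
    """
    pool = sorted(pool_drugs)
    if len(pool) < template.size:
        raise ValidationError(
            f"pool of {len(pool)} drugs is smaller than template "
            f"{template.scale_id!r} (size {template.size})"
        )
    rng = np.random.default_rng(seed)
    template_scores = np.array(sorted(template.potency_map.values()))
    pool_arr = np.array(pool, dtype=object)
    out: list[ScaleDefinition] = []
    for i in range(n_scales):
        drugs = rng.choice(pool_arr, size=template.size, replace=False)
        assigned = rng.permutation(template_scores)
        out.append(
            ScaleDefinition(
                scale_id=f"within_{pool_label}_{template.scale_id}_{i:03d}",
                kind="pseudoscale",
                potency_map=dict(zip(drugs.tolist(), assigned.tolist())),
                provenance=Provenance(
                    mode="within",
                    pool=pool_label,
                    template_scale_id=template.scale_id,
                    seed=str(seed),
                ),
            )
        )
    return out
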