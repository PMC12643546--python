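import numpy as np
import pandas as pd
import pytest

from pseudoscales import (
    EffectConfig,
    anticholinergic_pool,
    clean_prescriptions,
    default_formulary,
    default_registry,
    generate_participants,
    generate_prescriptions,
    generate_outcomes,
)

PERIOD = ("2015-01-01", "2015-12-31")


@pytest.fixture(scope="session")
def bundled():
    """Bundled synthetic formulary and 23-scale ABS registry."""
    return default_formulary(), default_registry()


@pytest.fixture(scope="session")
def pools(bundled):
    formulary, registry = bundled
    return {
        "general": {d.drug_id for d in formulary},
        "anticholinergic": anticholinergic_pool(registry, formulary),
    }


@pytest.fixture(scope="session")
def small_cohort(bundled):
    """A 2,000-participant cohort with cleaned prescriptions and a death
    outcome driven by the default effect configuration."""
    formulary, registry = bundled
    participants = generate_participants(2000, seed=11)
    prescriptions = generate_prescriptions(participants, formulary, PERIOD, seed=12)
    clean, _ = clean_prescriptions(prescriptions, participants)
    truth = max(registry.abs_scales(), key=lambda s: s.size)
    outcomes = generate_outcomes(
        participants,
        clean,
        EffectConfig(prevalence_targets={"death": 0.062}),
        seed=13,
        truth_scale=truth,
    )
    return {
        "participants": participants,
        "prescriptions": clean,
        "outcomes": outcomes,
        "truth_scale": truth,
    }


def toy_prescriptions(rows):
    """Build a prescription table from (pid, drug, date, route) tuples."""
    return pd.DataFrame(
        [
            {
                "participant_id": pid,
                "drug_id": drug,
                "issue_date": pd.Timestamp(date),
                "route": route,
                "content_flag": True,
            }
            for pid, drug, date, route in rows
        ]
    )
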