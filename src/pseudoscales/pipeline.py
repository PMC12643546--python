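"""End-to-end orchestration: generate -> sample -> score -> fit -> summarize.

Every stage is a pure function of its input files and a stage seed derived
by hashing (master seed, stage name), so any stage can be re-run standalone
from the previous stage's outputs and identical configs give byte-identical
reports.  All tables are delimited text; the manifest and summary report
are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .burden_scoring import burden_table
from .outcome_models import ModelConfig, results_frame, run_scale_models
from .pseudoscale_sampler import SamplingConfig, sample_across, sample_within
from .scale_registry import (
    ScaleRegistry,
    ValidationError,
    anticholinergic_pool,
    load_formulary,
    load_scale_definitions,
    write_formulary,
    write_scale_definitions,
)
from .simulation_summary import summarize, table2_frame, write_report
from .synthetic_cohort import (
    DEFAULT_PERIOD,
    EffectConfig,
    ParticipantConfig,
    PrescribingConfig,
    clean_prescriptions,
    generate_formulary,
    generate_outcomes,
    generate_participants,
    generate_prescriptions,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate-data", "sample-scales", "score", "fit", "summarize")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, decoupled across stages."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    The defaults are the full study-scale conditions (200,000 participants,
    1000 across-sampling scales per pool); the ``smoke`` constructor gives a
    seconds-scale end-to-end run.
    """

    master_seed: int = 0
    n_participants: int = 200_000
    period: tuple[str, str] = DEFAULT_PERIOD
    pools: tuple[str, ...] = ("general", "anticholinergic")
    n_across_per_pool: int = 1000
    within_replicates: int = 250
    include_within: bool = True
    include_abs: bool = True
    outcomes: tuple[str, ...] = ("death", "dementia", "delirium")
    truth_scale_id: str = ""  # empty: largest bundled ABS
    alpha: float = 0.05
    participant_config: ParticipantConfig = field(default_factory=ParticipantConfig)
    prescribing_config: PrescribingConfig = field(default_factory=PrescribingConfig)
    effect_config: EffectConfig = field(default_factory=EffectConfig)
    model_config: ModelConfig = field(default_factory=ModelConfig)

    @classmethod
    def smoke(cls, master_seed: int = 0) -> "RunConfig":
        return cls(
            master_seed=master_seed,
            n_participants=500,
            n_across_per_pool=10,
            within_replicates=2,
            outcomes=("death",),
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        for key, sub_cls in (
            ("participant_config", ParticipantConfig),
            ("prescribing_config", PrescribingConfig),
            ("effect_config", EffectConfig),
            ("model_config", ModelConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub_cls(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in raw[key].items()
                    }
                )
        for key in ("period", "pools", "outcomes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _update_manifest(out_dir: Path, updates: dict) -> None:
    path = out_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest.update(updates)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def _require(out_dir: Path, *names: str) -> None:
    missing = [n for n in names if not (out_dir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing stage inputs in {out_dir}: {missing} — run earlier stages first"
        )


def stage_simulate(config: RunConfig, out_dir: Path) -> None:
    """Generate formulary, registry, participants, prescriptions, outcomes."""
    seed = stage_seed(config.master_seed, "simulate-data")
    formulary, registry = generate_formulary(seed=seed)
    participants = generate_participants(
        config.n_participants,
        seed=seed + 1,
        config=config.participant_config,
        period_end=config.period[1],
    )
    prescriptions = generate_prescriptions(
        participants,
        formulary,
        period=config.period,
        seed=seed + 2,
        config=config.prescribing_config,
    )
    clean, n_removed = clean_prescriptions(
        prescriptions, participants, config.prescribing_config.extraction_date
    )
    truth_id = config.truth_scale_id or max(registry.abs_scales(), key=lambda s: s.size).scale_id
    outcomes = generate_outcomes(
        participants,
        clean,
        config.effect_config,
        seed=seed + 3,
        truth_scale=registry[truth_id],
        period=config.period,
    )
    write_formulary(formulary, out_dir / "formulary.csv")
    write_scale_definitions(registry, out_dir / "abs_scales.csv")
    participants.to_csv(out_dir / "participants.csv", index=False)
    prescriptions.to_csv(out_dir / "prescriptions.csv", index=False)
    clean.to_csv(out_dir / "prescriptions_clean.csv", index=False)
    outcomes.to_csv(out_dir / "outcomes.csv", index=False)
    _update_manifest(
        out_dir,
        {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "version": __version__,
            "stage_seeds": {s: stage_seed(config.master_seed, s) for s in STAGES},
            "truth_scale_id": truth_id,
            "n_participants": len(participants),
            "n_prescriptions": len(prescriptions),
            "n_prescriptions_removed": n_removed,
        },
    )


def stage_sample(config: RunConfig, out_dir: Path) -> None:
    """Construct across- and within-sampling pseudoscales for each pool."""
    _require(out_dir, "formulary.csv", "abs_scales.csv")
    seed = stage_seed(config.master_seed, "sample-scales")
    formulary = load_formulary(out_dir / "formulary.csv")
    registry = load_scale_definitions(out_dir / "abs_scales.csv", kind="abs")
    pools = {
        "general": {d.drug_id for d in formulary},
        "anticholinergic": anticholinergic_pool(registry, formulary),
    }
    across, within = [], []
    provenance = {"seed": seed, "pools": {}}
    for i, pool_name in enumerate(config.pools):
        pool = pools[pool_name]
        provenance["pools"][pool_name] = len(pool)
        across.extend(
            sample_across(
                pool,
                SamplingConfig(
                    mode="across",
                    pool=pool_name,
                    n_scales=config.n_across_per_pool,
                    seed=seed + i,
                ),
            )
        )
        if config.include_within:
            for j, template in enumerate(registry.abs_scales()):
                within.extend(
                    sample_within(
                        pool,
                        template,
                        config.within_replicates,
                        seed=seed + 100 + 1000 * i + j,
                        pool_label=pool_name,
                    )
                )
    write_scale_definitions(across, out_dir / "pseudoscales_across.csv")
    (out_dir / "pseudoscales_across.provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )
    if config.include_within:
        write_scale_definitions(within, out_dir / "pseudoscales_within.csv")
        (out_dir / "pseudoscales_within.provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n"
        )
    _update_manifest(
        out_dir, {"n_across": len(across), "n_within": len(within)}
    )


def _all_scales(config: RunConfig, out_dir: Path) -> list:
    registry = load_scale_definitions(out_dir / "abs_scales.csv", kind="abs")
    across = load_scale_definitions(out_dir / "pseudoscales_across.csv", kind="pseudoscale")
    scales = list(across)
    prov = json.loads(
        (out_dir / "pseudoscales_across.provenance.json").read_text()
    )
    # restore provenance lost in the flat scale-file format
    from .scale_registry import Provenance, ScaleDefinition

    def reprovenance(s, mode):
        parts = s.scale_id.split("_")
        pool = parts[1]
        template = parts[2] if mode == "within" else ""
        return ScaleDefinition(
            scale_id=s.scale_id,
            kind="pseudoscale",
            potency_map=s.potency_map,
            provenance=Provenance(
                mode=mode, pool=pool, template_scale_id=template,
                seed=str(prov["seed"]),
            ),
        )

    scales = [reprovenance(s, "across") for s in scales]
    if config.include_within and (out_dir / "pseudoscales_within.csv").exists():
        within = load_scale_definitions(
            out_dir / "pseudoscales_within.csv", kind="pseudoscale"
        )
        scales.extend(reprovenance(s, "within") for s in within)
    if config.include_abs:
        scales.extend(registry.abs_scales())
    return scales


def stage_score(config: RunConfig, out_dir: Path) -> None:
    """Compute the burden table for every scale (ABS and pseudoscales)."""
    _require(
        out_dir, "prescriptions_clean.csv", "participants.csv", "pseudoscales_across.csv"
    )
    prescriptions = pd.read_csv(
        out_dir / "prescriptions_clean.csv", parse_dates=["issue_date"]
    )
    participants = pd.read_csv(out_dir / "participants.csv", parse_dates=["birth_date"])
    scales = _all_scales(config, out_dir)
    table = burden_table(
        prescriptions, scales, config.period, participants["participant_id"]
    )
    table.to_csv(out_dir / "burden.csv", index=False)
    _update_manifest(out_dir, {"n_scored_scales": len(scales)})


def stage_fit(config: RunConfig, out_dir: Path) -> None:
    """Fit the per-(scale, outcome) logistic models."""
    _require(out_dir, "burden.csv", "participants.csv", "outcomes.csv")
    participants = pd.read_csv(out_dir / "participants.csv", parse_dates=["birth_date"])
    burden = pd.read_csv(out_dir / "burden.csv")
    outcomes = pd.read_csv(out_dir / "outcomes.csv")
    outcomes = outcomes.loc[outcomes["outcome"].isin(config.outcomes)]
    scales = _all_scales(config, out_dir)
    cfg = dataclasses.replace(
        config.model_config, seed=stage_seed(config.master_seed, "fit")
    )
    results = run_scale_models(scales, burden, participants, outcomes, cfg)
    results_frame(results).to_csv(out_dir / "model_results.csv", index=False)
    n_bad = sum(not r.converged for r in results)
    _update_manifest(
        out_dir, {"n_models": len(results), "n_nonconverged": n_bad}
    )


def stage_summarize(config: RunConfig, out_dir: Path) -> None:
    """Aggregate model results into the summary report."""
    _require(out_dir, "model_results.csv")
    results = pd.read_csv(
        out_dir / "model_results.csv",
        dtype={"template_scale_id": str},
        keep_default_na=True,
    )
    results["template_scale_id"] = results["template_scale_id"].fillna("")
    report = summarize(results, alpha=config.alpha)
    write_report(report, out_dir / "summary.json")
    table2_frame(report).to_csv(out_dir / "table2.csv", index=False)


_STAGE_FUNCS = {
    "simulate-data": stage_simulate,
    "sample-scales": stage_sample,
    "score": stage_score,
    "fit": stage_fit,
    "summarize": stage_summarize,
}


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages into ``out_dir`` and return it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, out_dir)
        except Exception as exc:
            (out_dir / "FAILED").write_text(f"{stage}: {exc}\n")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %-14s done in %.1fs", stage, time.perf_counter() - t0)
    stale = out_dir / "FAILED"
    if stale.exists():
        stale.unlink()
    return out_dir
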