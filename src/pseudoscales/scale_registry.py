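"""Drug formulary and burden-scale registry.

A burden scale — real anticholinergic burden scale (ABS) or randomly
constructed pseudoscale — is a mapping from drug identifiers to potency
scores in {0.5, 1, 2, 3, 4}.  Drugs absent from a scale implicitly score 0
and are never stored.  The registry collects scales by id and derives the
anticholinergic sampling pool: the set of formulary drugs scored by at
least one ABS-kind scale.
"""

from __future__ import annotations

import csv
import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ALLOWED_SCORES",
    "ROUTES",
    "NON_SYSTEMIC_ROUTES",
    "ValidationError",
    "DrugEntry",
    "Provenance",
    "ScaleDefinition",
    "ScaleRegistry",
    "load_scale_definitions",
    "write_scale_definitions",
    "load_formulary",
    "write_formulary",
    "anticholinergic_pool",
    "potency_multiset",
    "default_formulary",
    "default_registry",
]

#: Potency scores an expert-curated anticholinergic scale may assign.
ALLOWED_SCORES = frozenset({0.5, 1.0, 2.0, 3.0, 4.0})

#: Administration routes.  "oral" stands for all systemic administration;
#: the other four routes are assumed not to reach systemic circulation and
#: contribute zero to burden scores.
ROUTES = ("oral", "ophthalmic", "otic", "nasal", "topical")
NON_SYSTEMIC_ROUTES = frozenset(ROUTES[1:])

#: Seed from which the bundled synthetic formulary / ABS registry derive.
_BUNDLED_SEED = 20150101


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class DrugEntry:
    """One formulary drug with its prescribing propensity and route mix.

    ``route_profile`` gives the probability that a prescription of this drug
    uses each route, ordered as :data:`ROUTES`.
    """

    drug_id: str
    name: str
    prescribing_weight: float
    route_profile: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.prescribing_weight <= 0:
            raise ValidationError(
                f"drug {self.drug_id!r}: prescribing_weight must be > 0"
            )
        if len(self.route_profile) != len(ROUTES):
            raise ValidationError(
                f"drug {self.drug_id!r}: route_profile needs {len(ROUTES)} entries"
            )
        if min(self.route_profile) < 0 or abs(sum(self.route_profile) - 1.0) > 1e-9:
            raise ValidationError(
                f"drug {self.drug_id!r}: route probabilities must be >= 0 and sum to 1"
            )


@dataclass(frozen=True)
class Provenance:
    """How a scale came to be: sampling mode, pool, template and seed."""

    mode: str = "none"  # across | within | none
    pool: str = "none"  # general | anticholinergic | none
    template_scale_id: str = ""
    seed: str = ""


@dataclass(frozen=True)
class ScaleDefinition:
    scale_id: str
    kind: str  # abs | pseudoscale
    potency_map: Mapping[str, float]
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        if self.kind not in ("abs", "pseudoscale"):
            raise ValidationError(f"scale {self.scale_id!r}: unknown kind {self.kind!r}")
        if len(self.potency_map) < 1:
            raise ValidationError(f"scale {self.scale_id!r}: empty potency map")
        bad = {s for s in self.potency_map.values() if s not in ALLOWED_SCORES}
        if bad:
            raise ValidationError(
                f"scale {self.scale_id!r}: scores {sorted(bad)} outside "
                f"{sorted(ALLOWED_SCORES)}"
            )

    @property
    def size(self) -> int:
        return len(self.potency_map)

    def score(self, drug_id: str) -> float:
        """Potency of ``drug_id`` under this scale (0 if not listed)."""
        return self.potency_map.get(drug_id, 0.0)


def potency_multiset(scale: ScaleDefinition) -> list[float]:
    """Multiset of potency scores, one entry per drug, sorted."""
    return sorted(scale.potency_map.values())


class ScaleRegistry:
    """Collection of :class:`ScaleDefinition` keyed by unique scale_id."""

    def __init__(self, scales: Iterable[ScaleDefinition] = ()) -> None:
        self._scales: dict[str, ScaleDefinition] = {}
        for s in scales:
            self.add(s)

    def add(self, scale: ScaleDefinition) -> None:
        if scale.scale_id in self._scales:
            raise ValidationError(f"duplicate scale_id {scale.scale_id!r}")
        self._scales[scale.scale_id] = scale

    def __getitem__(self, scale_id: str) -> ScaleDefinition:
        return self._scales[scale_id]

    def __contains__(self, scale_id: str) -> bool:
        return scale_id in self._scales

    def __iter__(self) -> Iterator[ScaleDefinition]:
        return iter(self._scales.values())

    def __len__(self) -> int:
        return len(self._scales)

    @property
    def scale_ids(self) -> list[str]:
        return list(self._scales)

    def abs_scales(self) -> list[ScaleDefinition]:
        return [s for s in self if s.kind == "abs"]


# ---------------------------------------------------------------------------
# File I/O: delimited text, header scale_id,drug_id,score (comma or tab).
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _read_scale_file(path: Path, rows: dict[str, dict[str, float]]) -> None:
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            return
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        expected = {"scale_id", "drug_id", "score"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise ValidationError(
                f"{path}: expected header with columns {sorted(expected)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            sid, did, raw = row["scale_id"], row["drug_id"], row["score"]
            try:
                score = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(f"{path} row {i}: unreadable score {raw!r}")
            if score not in ALLOWED_SCORES:
                raise ValidationError(
                    f"{path} row {i}: score {score} outside {sorted(ALLOWED_SCORES)}"
                )
            scale = rows.setdefault(sid, {})
            if did in scale:
                raise ValidationError(
                    f"{path} row {i}: duplicate (scale_id, drug_id) = ({sid}, {did})"
                )
            scale[did] = score


def load_scale_definitions(path: str | Path, kind: str = "abs") -> ScaleRegistry:
    """Read scale definitions from a delimited file or a directory of files."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    files = sorted(path.glob("*")) if path.is_dir() else [path]
    rows: dict[str, dict[str, float]] = {}
    for f in files:
        if f.is_file():
            _read_scale_file(f, rows)
    return ScaleRegistry(
        ScaleDefinition(scale_id=sid, kind=kind, potency_map=pm)
        for sid, pm in rows.items()
    )


def write_scale_definitions(
    scales: Iterable[ScaleDefinition], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["scale_id", "drug_id", "score"])
        for scale in scales:
            for did, score in scale.potency_map.items():
                w.writerow([scale.scale_id, did, f"{score:g}"])


def load_formulary(path: str | Path) -> list[DrugEntry]:
    """Read a formulary file: drug_id,name,prescribing_weight,route_probs
    with route_probs as 5 colon-separated reals ordered as :data:`ROUTES`."""
    path = Path(path)
    out: list[DrugEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        for i, row in enumerate(reader, start=2):
            try:
                probs = tuple(float(p) for p in row["route_probs"].split(":"))
            except (KeyError, ValueError):
                raise ValidationError(f"{path} row {i}: unreadable route_probs")
            out.append(
                DrugEntry(
                    drug_id=row["drug_id"],
                    name=row["name"],
                    prescribing_weight=float(row["prescribing_weight"]),
                    route_profile=probs,  # type: ignore[arg-type]
                )
            )
    return out


def write_formulary(formulary: Iterable[DrugEntry], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["drug_id", "name", "prescribing_weight", "route_probs"])
        for d in formulary:
            w.writerow(
                [
                    d.drug_id,
                    d.name,
                    repr(d.prescribing_weight),
                    ":".join(repr(p) for p in d.route_profile),
                ]
            )


# ---------------------------------------------------------------------------
# Sampling pools
# ---------------------------------------------------------------------------

def anticholinergic_pool(
    registry: ScaleRegistry, formulary: Iterable[DrugEntry]
) -> set[str]:
    """Formulary drugs scored (>0) by at least one ABS-kind scale."""
    if len(registry) == 0:
        raise ValidationError("empty scale registry")
    scored: set[str] = set()
    for scale in registry.abs_scales():
        scored.update(d for d, s in scale.potency_map.items() if s > 0)
    return {d.drug_id for d in formulary} & scored


# ---------------------------------------------------------------------------
# Bundled synthetic defaults (deterministic; see synthetic_cohort)
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _bundled() -> tuple[tuple[DrugEntry, ...], ScaleRegistry]:
    from . import synthetic_cohort  # deferred to avoid an import cycle

    formulary, registry = synthetic_cohort.generate_formulary(seed=_BUNDLED_SEED)
    return tuple(formulary), registry


def default_formulary() -> list[DrugEntry]:
    """The bundled synthetic 525-drug formulary (fixed internal seed)."""
    return list(_bundled()[0])


def default_registry() -> ScaleRegistry:
    """The bundled registry of 23 synthetic ABS (fixed internal seed)."""
    return _bundled()[1]
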