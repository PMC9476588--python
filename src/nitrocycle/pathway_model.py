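"""Declarative nitrogen-pathway registry.

A pathway is an ordered list of reaction steps. Each step carries *alternative
gene groups* (OR of ANDs): the step is satisfied when every gene of at least
one group is present. Groups express both enzyme complexes (dinitrogenase
needs ``nifD`` AND ``nifK``) and isozyme/subtype alternatives (the Fe/Mo,
Fe/V and Fe/Fe nitrogenase subtypes, or the urease cluster variants ``URE``,
``ureAB`` and ``ureA``+``ureB``+``ureC``).

Gene symbols are matched case-insensitively and with whitespace stripped,
but their first-seen spelling is preserved for display.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

CATEGORIES = ("BNF", "urea_hydrolysis", "ammonium_assimilation", "EAA")

#: The ten amino acids the host cannot synthesise de novo.
EAA_AMINO_ACIDS = frozenset(
    {
        "valine",
        "leucine",
        "isoleucine",
        "histidine",
        "methionine",
        "threonine",
        "lysine",
        "phenylalanine",
        "tryptophan",
        "arginine",
    }
)


class RegistryError(Exception):
    """Base class for registry problems."""


class RegistryFormatError(RegistryError):
    """The document could not be parsed or misses required fields."""


class RegistrySchemaError(RegistryError):
    """The document parsed but violates registry invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


def canonical_symbol(symbol: str) -> str:
    """Canonical (matching) form of a gene symbol.

    Strips surrounding/internal whitespace and subscript markers and folds
    case, so that ``nifH``, ``NifH`` and ``nifH `` all collide.
    """
    if not isinstance(symbol, str):
        raise RegistryFormatError(f"gene symbol must be a string, got {symbol!r}")
    cleaned = "".join(symbol.split()).replace("_", "")
    if not cleaned:
        raise RegistryFormatError("empty gene symbol")
    return cleaned.casefold()


@dataclass(frozen=True)
class ReactionStep:
    """One enzymatic reaction step with OR-of-AND gene logic."""

    step_id: str
    label: str
    alternatives: tuple[frozenset[str], ...]  # canonical symbols
    essential: bool = True

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for group in self.alternatives:
            out |= group
        return frozenset(out)


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    category: str
    steps: tuple[ReactionStep, ...]
    amino_acid: str | None = None  # only for EAA pathways

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for step in self.steps:
            out |= step.genes()
        return frozenset(out)


@dataclass
class PathwayRegistry:
    """Validated collection of pathway definitions plus a gene symbol table."""

    pathways: dict[str, PathwayDefinition]
    symbol_table: dict[str, str] = field(default_factory=dict)  # canonical -> display
    version: str = "unversioned"
    schema_version: int = 1

    def __getitem__(self, pathway_id: str) -> PathwayDefinition:
        return self.pathways[pathway_id]

    def __iter__(self):
        return iter(self.pathways.values())

    def __len__(self) -> int:
        return len(self.pathways)

    def pathways_in(self, category: str) -> list[PathwayDefinition]:
        if category != "all" and category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES} or 'all'")
        return [p for p in self if category == "all" or p.category == category]

    def genes(self, category: str = "all") -> frozenset[str]:
        out: set[str] = set()
        for pathway in self.pathways_in(category):
            out |= pathway.genes()
        return frozenset(out)

    def display(self, canonical: str) -> str:
        return self.symbol_table.get(canonical, canonical)


def _parse_step(raw: Mapping, pathway_id: str) -> ReactionStep:
    for key in ("id", "label", "alternatives"):
        if key not in raw:
            raise RegistryFormatError(f"pathway {pathway_id!r}: step missing field {key!r}")
    alternatives = []
    for group in raw["alternatives"]:
        if not isinstance(group, (list, tuple)):
            raise RegistryFormatError(
                f"pathway {pathway_id!r} step {raw['id']!r}: alternative must be a gene list"
            )
        alternatives.append(tuple(group))
    return ReactionStep(
        step_id=str(raw["id"]),
        label=str(raw["label"]),
        alternatives=tuple(frozenset(canonical_symbol(g) for g in group) for group in alternatives),
        essential=bool(raw.get("essential", True)),
    )


def load_registry(source: str | Path | io.IOBase | Mapping) -> PathwayRegistry:
    """Parse and validate a pathway-definition document (YAML or JSON).

    Raises :class:`RegistryFormatError` on parse/shape problems and
    :class:`RegistrySchemaError` when the parsed registry violates invariants.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if isinstance(source, (str, Path)):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source.read()
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise RegistryFormatError(f"could not parse registry document: {exc}") from exc
    if not isinstance(doc, Mapping) or "pathways" not in doc:
        raise RegistryFormatError("registry document must be a mapping with a 'pathways' list")

    pathways: dict[str, PathwayDefinition] = {}
    symbol_table: dict[str, str] = {}
    duplicates: list[str] = []
    for raw in doc["pathways"]:
        for key in ("id", "name", "category", "steps"):
            if key not in raw:
                raise RegistryFormatError(f"pathway entry missing field {key!r}: {raw!r}")
        steps = tuple(_parse_step(s, raw["id"]) for s in raw["steps"])
        definition = PathwayDefinition(
            pathway_id=str(raw["id"]),
            name=str(raw["name"]),
            category=str(raw["category"]),
            steps=steps,
            amino_acid=raw.get("amino_acid"),
        )
        if definition.pathway_id in pathways:
            duplicates.append(definition.pathway_id)
        pathways[definition.pathway_id] = definition
        # record display spellings, first occurrence wins
        for s in raw["steps"]:
            for group in s["alternatives"]:
                for g in group:
                    symbol_table.setdefault(canonical_symbol(g), str(g).strip())

    registry = PathwayRegistry(
        pathways=pathways,
        symbol_table=symbol_table,
        version=str(doc.get("registry_version", "unversioned")),
        schema_version=int(doc.get("schema_version", 1)),
    )
    violations = [f"duplicate pathway_id {pid!r}" for pid in duplicates]
    violations += validate_registry(registry)
    if violations:
        raise RegistrySchemaError(violations)
    return registry


def validate_registry(registry: PathwayRegistry) -> list[str]:
    """Return invariant violations (empty list means the registry is valid)."""
    violations: list[str] = []
    for pathway in registry:
        pid = pathway.pathway_id
        if pathway.category not in CATEGORIES:
            violations.append(f"pathway {pid!r}: unknown category {pathway.category!r}")
        if pathway.category == "EAA":
            if pathway.amino_acid not in EAA_AMINO_ACIDS:
                violations.append(
                    f"pathway {pid!r}: EAA pathway must name one of the ten essential"
                    f" amino acids, got {pathway.amino_acid!r}"
                )
        if not pathway.steps:
            violations.append(f"pathway {pid!r}: has no steps")
        seen_steps: set[str] = set()
        for step in pathway.steps:
            if step.step_id in seen_steps:
                violations.append(f"pathway {pid!r}: duplicate step_id {step.step_id!r}")
            seen_steps.add(step.step_id)
            if not step.alternatives:
                violations.append(f"pathway {pid!r} step {step.step_id!r}: no alternative gene groups")
            for i, group in enumerate(step.alternatives):
                if not group:
                    violations.append(
                        f"pathway {pid!r} step {step.step_id!r}: alternative group {i} is empty"
                    )
                for gene in group:
                    if gene not in registry.symbol_table:
                        violations.append(
                            f"pathway {pid!r} step {step.step_id!r}: gene {gene!r} missing"
                            " from symbol table"
                        )
    return violations


def registry_gene_count(registry: PathwayRegistry, category: str = "all") -> int:
    """Number of distinct genes referenced by pathways of ``category``."""
    return len(registry.genes(category))


def serialize_registry(registry: PathwayRegistry) -> dict:
    """Plain-document form of a registry; ``load_registry`` round-trips it."""
    return {
        "schema_version": registry.schema_version,
        "registry_version": registry.version,
        "pathways": [
            {
                "id": p.pathway_id,
                "name": p.name,
                "category": p.category,
                **({"amino_acid": p.amino_acid} if p.amino_acid else {}),
                "steps": [
                    {
                        "id": s.step_id,
                        "label": s.label,
                        "essential": s.essential,
                        "alternatives": [
                            sorted(registry.display(g) for g in group) for group in s.alternatives
                        ],
                    }
                    for s in p.steps
                ],
            }
            for p in registry
        ],
    }


def save_registry(registry: PathwayRegistry, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(serialize_registry(registry), sort_keys=False), encoding="utf-8")


_DEFAULT_CACHE: PathwayRegistry | None = None


def default_registry() -> PathwayRegistry:
    """The packaged nitrogen-metabolism registry (13 pathways, 10 of them EAA)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        from importlib.resources import files

        text = files("nitrocycle").joinpath("data/pathways.yaml").read_text(encoding="utf-8")
        _DEFAULT_CACHE = load_registry(io.StringIO(text))
    return _DEFAULT_CACHE


def genes_of(step_or_pathway: ReactionStep | PathwayDefinition) -> frozenset[str]:
    return step_or_pathway.genes()
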