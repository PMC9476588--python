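"""Pathway completeness scoring and blocker detection.

A step is *satisfied* when one of its alternative gene groups is fully covered
by the in-scope taxa. Two pooling modes are supported:

``pooled``
    community complementation — each gene of a group may come from a different
    taxon of the set (the default; a core community is scored collectively).
``single_taxon``
    all genes of a group must co-occur in one and the same taxon.

A *blocker* is an unsatisfied essential step: it renders the pathway
non-functional regardless of how many other steps are covered, the way a
missing dinitrogenase (nifD/nifK) interrupts electron transfer from the
nifH-encoded reductase even when nifH itself is expressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import Layer, PresenceMatrix, Stage
from .pathway_model import PathwayDefinition, PathwayRegistry, ReactionStep

CATEGORY_COMPLETE = "complete"
CATEGORY_ALMOST = "almost_complete"
CATEGORY_INCOMPLETE = "incomplete"

POOLING_MODES = ("pooled", "single_taxon")


class ConfigurationError(Exception):
    """A step references genes unknown to the registry symbol table."""


@dataclass(frozen=True)
class StepStatus:
    step_id: str
    satisfied: bool
    layer: str
    stage: str
    pooling: str
    #: per alternative group: gene -> taxa carrying it (within scope)
    support: tuple[Mapping[str, tuple[str, ...]], ...]
    #: per alternative group: genes missing from the group (sorted)
    gaps: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class Blocker:
    step_id: str
    label: str
    #: minimal missing genes per alternative group, each sorted lexicographically
    gene_gaps: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class CompletenessResult:
    pathway_id: str
    taxa: tuple[str, ...]
    layer: str
    stage: str
    pooling: str
    satisfied_steps: frozenset[str]
    total_steps: int
    blockers: tuple[Blocker, ...]
    category: str

    @property
    def completeness(self) -> Fraction:
        return Fraction(len(self.satisfied_steps), self.total_steps)

    @property
    def completeness_float(self) -> float:
        return float(self.completeness)


def evaluate_step(
    step: ReactionStep,
    presence: PresenceMatrix,
    taxa: Iterable[str],
    layer: str,
    stage: str,
    pooling: str = "pooled",
    known_genes: frozenset[str] | None = None,
) -> StepStatus:
    """Evaluate one reaction step against a presence matrix.

    ``known_genes``, when given (normally the registry symbol table), guards
    against steps referencing genes the registry does not know.
    """
    taxa = tuple(taxa)
    if not taxa:
        raise ValueError("taxa set must be non-empty")
    if pooling not in POOLING_MODES:
        raise ValueError(f"unknown pooling mode {pooling!r}; expected one of {POOLING_MODES}")
    layer, stage = Layer(layer).value, Stage(stage).value
    if known_genes is not None:
        unknown = step.genes() - known_genes
        if unknown:
            raise ConfigurationError(
                f"step {step.step_id!r} references gene(s) absent from the registry"
                f" symbol table: {', '.join(sorted(unknown))}"
            )

    support: list[dict[str, tuple[str, ...]]] = []
    gaps: list[tuple[str, ...]] = []
    satisfied = False
    for group in step.alternatives:
        carriers = {g: tuple(sorted(presence.taxa_with(g, layer, stage, within=taxa))) for g in sorted(group)}
        support.append(carriers)
        if pooling == "pooled":
            missing = tuple(sorted(g for g, ts in carriers.items() if not ts))
        else:  # single_taxon: one taxon must carry the whole group
            if any(set(carriers[g]) & set(taxa) for g in group):
                covering = [t for t in taxa if all(t in carriers[g] for g in group)]
            else:
                covering = []
            missing = () if covering else tuple(sorted(g for g in group))
            if not covering and all(carriers[g] for g in group):
                # every gene is somewhere, but never together in one taxon:
                # report the whole group as the gap for this mode
                missing = tuple(sorted(group))
        gaps.append(missing)
        if not missing:
            satisfied = True
    return StepStatus(
        step_id=step.step_id,
        satisfied=satisfied,
        layer=layer,
        stage=stage,
        pooling=pooling,
        support=tuple(support),
        gaps=tuple(gaps),
    )


def classify_pathway(
    satisfied_steps: int,
    total_steps: int,
    n_essential_blockers: int,
    tolerance: int = 1,
) -> str:
    """Three-way pathway category.

    complete        — every step satisfied;
    almost_complete — no essential blocker and at most ``tolerance`` missing
                      (non-essential) steps;
    incomplete      — anything with an essential blocker, or more gaps.
    """
    if not 0 <= satisfied_steps <= total_steps:
        raise ValueError("satisfied_steps out of range")
    if satisfied_steps == total_steps:
        return CATEGORY_COMPLETE
    if n_essential_blockers == 0 and (total_steps - satisfied_steps) <= tolerance:
        return CATEGORY_ALMOST
    return CATEGORY_INCOMPLETE


def pathway_completeness(
    pathway: PathwayDefinition,
    presence: PresenceMatrix,
    taxa: Iterable[str],
    layer: str,
    stage: str,
    pooling: str = "pooled",
    tolerance: int = 1,
    known_genes: frozenset[str] | None = None,
) -> CompletenessResult:
    """Score one pathway for one taxon scope, omic layer and life stage."""
    taxa = tuple(taxa)
    if not pathway.steps:
        raise ValueError(f"pathway {pathway.pathway_id!r} has no steps")
    statuses = [
        evaluate_step(step, presence, taxa, layer, stage, pooling, known_genes=known_genes)
        for step in pathway.steps
    ]
    satisfied = frozenset(s.step_id for s in statuses if s.satisfied)
    blockers = tuple(
        Blocker(step_id=step.step_id, label=step.label, gene_gaps=status.gaps)
        for step, status in zip(pathway.steps, statuses)
        if step.essential and not status.satisfied
    )
    category = classify_pathway(len(satisfied), len(pathway.steps), len(blockers), tolerance)
    return CompletenessResult(
        pathway_id=pathway.pathway_id,
        taxa=taxa,
        layer=Layer(layer).value,
        stage=Stage(stage).value,
        pooling=pooling,
        satisfied_steps=satisfied,
        total_steps=len(pathway.steps),
        blockers=blockers,
        category=category,
    )


def evaluate_registry(
    registry: PathwayRegistry,
    presence: PresenceMatrix,
    taxa: Iterable[str],
    layers: Sequence[str] = (Layer.DNA, Layer.RNA),
    stages: Sequence[str] = (Stage.LARVA, Stage.ADULT),
    pooling: str = "pooled",
    tolerance: int = 1,
) -> list[CompletenessResult]:
    """Score every pathway in the registry over a layer x stage grid."""
    taxa = tuple(taxa)
    known = frozenset(registry.symbol_table)
    out = []
    for pathway in registry:
        for layer in layers:
            for stage in stages:
                out.append(
                    pathway_completeness(
                        pathway, presence, taxa, layer, stage, pooling, tolerance, known_genes=known
                    )
                )
    return out


@dataclass(frozen=True)
class TranscriptionalGap:
    """A step with genomic (DNA) support but no transcriptional (RNA) support."""

    pathway_id: str
    step_id: str
    stage: str
    dna_support: tuple[Mapping[str, tuple[str, ...]], ...]
    rna_gaps: tuple[tuple[str, ...], ...]


def detect_transcriptional_blockers(
    registry: PathwayRegistry,
    presence: PresenceMatrix,
    taxa: Iterable[str],
    stage: str,
    pooling: str = "pooled",
) -> dict[str, list[TranscriptionalGap]]:
    """Steps satisfied at the DNA layer but unsatisfied at the RNA layer.

    These are candidate transcriptionally silent capabilities: the genomic
    potential exists but no expression is observed, the pattern that marks a
    disabled pathway even when its genes are encoded.
    """
    for layer in (Layer.DNA.value, Layer.RNA.value):
        if layer not in presence.layers:
            raise ValueError(f"presence matrix lacks the {layer} layer")
    taxa = tuple(taxa)
    known = frozenset(registry.symbol_table)
    report: dict[str, list[TranscriptionalGap]] = {}
    for pathway in registry:
        gaps: list[TranscriptionalGap] = []
        for step in pathway.steps:
            dna = evaluate_step(step, presence, taxa, Layer.DNA, stage, pooling, known_genes=known)
            rna = evaluate_step(step, presence, taxa, Layer.RNA, stage, pooling, known_genes=known)
            if dna.satisfied and not rna.satisfied:
                gaps.append(
                    TranscriptionalGap(
                        pathway_id=pathway.pathway_id,
                        step_id=step.step_id,
                        stage=Stage(stage).value,
                        dna_support=dna.support,
                        rna_gaps=rna.gaps,
                    )
                )
        if gaps:
            report[pathway.pathway_id] = gaps
    return report


def completeness_frame(results: Iterable[CompletenessResult]) -> pd.DataFrame:
    """Long-form table of completeness results, one row per result."""
    rows = []
    for r in results:
        rows.append(
            {
                "pathway": r.pathway_id,
                "scope": "+".join(r.taxa),
                "layer": r.layer,
                "stage": r.stage,
                "pooling": r.pooling,
                "satisfied": len(r.satisfied_steps),
                "total": r.total_steps,
                "completeness": r.completeness_float,
                "category": r.category,
                "blockers": ";".join(b.step_id for b in r.blockers),
            }
        )
    return pd.DataFrame(rows)


def completeness_report(results: Iterable[CompletenessResult]) -> dict:
    """Nested JSON-ready report keyed by pathway/layer/stage."""
    report: dict = {}
    for r in results:
        report.setdefault(r.pathway_id, {}).setdefault(r.layer, {})[r.stage] = {
            "satisfied_steps": sorted(r.satisfied_steps),
            "total_steps": r.total_steps,
            "completeness": f"{len(r.satisfied_steps)}/{r.total_steps}",
            "completeness_value": r.completeness_float,
            "category": r.category,
            "pooling": r.pooling,
            "blockers": [
                {"step": b.step_id, "label": b.label, "gene_gaps": [list(g) for g in b.gene_gaps]}
                for b in r.blockers
            ],
        }
    return report


def write_report(results: Iterable[CompletenessResult], tsv_path, json_path, header: str | None = None) -> None:
    results = list(results)
    frame = completeness_frame(results)
    with open(tsv_path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        frame.to_csv(fh, sep="\t", index=False)
    payload = completeness_report(results)
    if header:
        payload = {"_meta": header, **payload}
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
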