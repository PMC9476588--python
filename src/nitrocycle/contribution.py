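"""Per-taxon functional contribution: the proportion of a pathway's reaction
steps a taxon is involved in.

Two counting modes, both reported as exact fractions:

``any_gene``
    a step involves the taxon if the taxon carries at least one gene appearing
    in any of the step's alternative groups (credits partial complex subunits);
``full_step``
    the taxon alone satisfies the step (carries some complete alternative
    group by itself).

``full_step`` involvement is a subset of ``any_gene`` involvement, so its
proportion can never exceed the ``any_gene`` proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .annotation_io import Layer, PresenceMatrix, Stage
from .pathway_model import PathwayDefinition, PathwayRegistry

MODES = ("any_gene", "full_step")


@dataclass(frozen=True)
class ContributionResult:
    taxon: str
    pathway_id: str
    layer: str
    stage: str
    mode: str
    involved_steps: int
    total_steps: int

    @property
    def proportion(self) -> Fraction:
        return Fraction(self.involved_steps, self.total_steps)

    @property
    def proportion_float(self) -> float:
        return float(self.proportion)


def taxon_contribution(
    pathway: PathwayDefinition,
    taxon: str,
    presence: PresenceMatrix,
    layer: str,
    stage: str,
    mode: str = "any_gene",
) -> ContributionResult:
    """Count the steps of ``pathway`` that involve ``taxon``."""
    if mode not in MODES:
        raise ValueError(f"unknown contribution mode {mode!r}; expected one of {MODES}")
    if not pathway.steps:
        raise ValueError(f"pathway {pathway.pathway_id!r} has no steps (invalid registry)")
    layer, stage = Layer(layer).value, Stage(stage).value
    carried = presence.genes_of(taxon, layer, stage)
    involved = 0
    for step in pathway.steps:
        if mode == "any_gene":
            hit = bool(step.genes() & carried)
        else:
            hit = any(group <= carried for group in step.alternatives)
        involved += hit
    return ContributionResult(
        taxon=taxon,
        pathway_id=pathway.pathway_id,
        layer=layer,
        stage=stage,
        mode=mode,
        involved_steps=involved,
        total_steps=len(pathway.steps),
    )


def contribution_matrix(
    registry: PathwayRegistry,
    presence: PresenceMatrix,
    core_taxa: Sequence[str],
    layers: Sequence[str] = (Layer.DNA, Layer.RNA),
    stages: Sequence[str] = (Stage.LARVA, Stage.ADULT),
    mode: str = "any_gene",
) -> list[ContributionResult]:
    """One ContributionResult per (taxon, pathway, layer, stage), ordered
    deterministically by (taxon, pathway, layer, stage)."""
    if not core_taxa:
        raise ValueError("core_taxa must be non-empty")
    out = [
        taxon_contribution(pathway, taxon, presence, layer, stage, mode)
        for taxon in core_taxa
        for pathway in registry
        for layer in layers
        for stage in stages
    ]
    out.sort(key=lambda r: (r.taxon, r.pathway_id, r.layer, r.stage))
    return out


def contribution_frame(results: Iterable[ContributionResult]) -> pd.DataFrame:
    """Long-form table with exact-fraction and decimal proportions."""
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "pathway": r.pathway_id,
                "layer": r.layer,
                "stage": r.stage,
                "mode": r.mode,
                "involved": r.involved_steps,
                "total": r.total_steps,
                "proportion": f"{r.involved_steps}/{r.total_steps}",
                "proportion_value": r.proportion_float,
            }
            for r in results
        ]
    )


def contribution_wide(results: Iterable[ContributionResult], layer: str, stage: str) -> pd.DataFrame:
    """Wide matrix (rows = taxa, columns = pathways) for one layer x stage,
    ready for bar-chart plotting downstream."""
    layer, stage = Layer(layer).value, Stage(stage).value
    df = contribution_frame(r for r in results if r.layer == layer and r.stage == stage)
    if df.empty:
        return pd.DataFrame()
    return df.pivot_table(index="taxon", columns="pathway", values="proportion_value").sort_index()
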