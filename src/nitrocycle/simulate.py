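"""Synthetic data with planted ground truth.

Three generators feed the downstream stages without any sequencing input:

* planted communities — boolean taxon x gene assignment (genomic capability)
  and expression (transcribed subset) matrices, rendered into annotation
  tables with Bernoulli dropout/spurious noise and log-normal abundances;
* isotope feeding trials — three treatment arms (light urea, heavy urea,
  heavy urea + antibiotics) whose tissue enrichment follows a single
  assimilated-fraction parameter, suppressed by the antibiotic arm;
* qPCR runs — Ct differences drawn around planted per-condition shifts.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AnnotationTable, Layer, Stage
from .pathway_model import PathwayDefinition, PathwayRegistry, default_registry
from .isotope import (
    NATURAL_ATOM_PERCENT,
    GROUPS,
    QpcrRecord,
    TracerMeasurement,
)


@dataclass(frozen=True)
class NoiseModel:
    """Independent Bernoulli corruption of presence cells.

    ``dropout``: probability a true (taxon, gene, layer) cell goes unobserved;
    ``spurious``: probability a false cell is observed anyway;
    ``dispersion``: sigma of the log-normal abundance draw per observed cell.
    """

    dropout: float = 0.0
    spurious: float = 0.0
    dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("dropout", "spurious"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class PlantedCommunity:
    """Ground-truth community: who carries and who expresses which gene."""

    taxa: tuple[str, ...]
    genes: tuple[str, ...]  # canonical symbols
    assignment: pd.DataFrame  # bool, taxa x genes
    expression: pd.DataFrame  # bool, subset of assignment
    abundances: pd.DataFrame  # float > 0, taxa x stages
    seed: int
    stages: tuple[str, ...] = (Stage.LARVA.value, Stage.ADULT.value)

    def planted_presence(self, layer: str) -> set[tuple[str, str]]:
        matrix = self.assignment if Layer(layer) is Layer.DNA else self.expression
        return {(t, g) for t in self.taxa for g in self.genes if bool(matrix.at[t, g])}

    def planted_step_satisfied(self, step, layer: str) -> bool:
        matrix = self.assignment if Layer(layer) is Layer.DNA else self.expression
        return any(
            all(g in matrix.columns and bool(matrix[g].any()) for g in group)
            for group in step.alternatives
        )

    def planted_completeness(self, pathway: PathwayDefinition, layer: str) -> tuple[int, int]:
        """(satisfied, total) steps for the pooled community, noise-free."""
        satisfied = sum(self.planted_step_satisfied(s, layer) for s in pathway.steps)
        return satisfied, len(pathway.steps)

    def planted_contribution(
        self, pathway: PathwayDefinition, taxon: str, layer: str, mode: str = "any_gene"
    ) -> tuple[int, int]:
        matrix = self.assignment if Layer(layer) is Layer.DNA else self.expression
        carried = {g for g in self.genes if bool(matrix.at[taxon, g])}
        involved = 0
        for step in pathway.steps:
            if mode == "any_gene":
                involved += bool(step.genes() & carried)
            else:
                involved += any(group <= carried for group in step.alternatives)
        return involved, len(pathway.steps)


def simulate_community(
    registry: PathwayRegistry,
    n_taxa: int = 12,
    assignment_density: float = 0.6,
    expression_rate: float = 0.8,
    seed: int = 0,
    stages: Sequence[str] = (Stage.LARVA, Stage.ADULT),
) -> PlantedCommunity:
    """Plant a community over the registry's gene universe.

    Each taxon carries each gene independently with ``assignment_density``;
    each carried gene is expressed with ``expression_rate``. Per-stage
    abundances are log-normal, emulating the heavy-tailed order-level
    profiles of real gut communities.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    for name, rate in (("assignment_density", assignment_density), ("expression_rate", expression_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    taxa = tuple(f"Order{i + 1:02d}" for i in range(n_taxa))
    genes = tuple(sorted(registry.genes("all")))
    assign = rng.random((n_taxa, len(genes))) < assignment_density
    express = assign & (rng.random((n_taxa, len(genes))) < expression_rate)
    stages = tuple(Stage(s).value for s in stages)
    abund = rng.lognormal(mean=0.0, sigma=1.5, size=(n_taxa, len(stages)))
    return PlantedCommunity(
        taxa=taxa,
        genes=genes,
        assignment=pd.DataFrame(assign, index=taxa, columns=genes),
        expression=pd.DataFrame(express, index=taxa, columns=genes),
        abundances=pd.DataFrame(abund, index=taxa, columns=stages),
        seed=seed,
        stages=stages,
    )


def simulate_annotation_table(community: PlantedCommunity, noise: NoiseModel | None = None) -> AnnotationTable:
    """Render a planted community into a long-form annotation table.

    DNA rows derive from the assignment matrix, RNA rows from the expression
    matrix; each cell is independently flipped per the noise model. With zero
    noise, presence derived from the table equals the planted matrices
    exactly.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    rows: list[dict] = []
    for layer, matrix in ((Layer.DNA.value, community.assignment), (Layer.RNA.value, community.expression)):
        truth = matrix.to_numpy()
        for stage in community.stages:
            flip = rng.random(truth.shape)
            observed = np.where(truth, flip >= noise.dropout, flip < noise.spurious)
            scale = rng.lognormal(mean=0.0, sigma=noise.dispersion, size=truth.shape)
            for i, taxon in enumerate(community.taxa):
                base = float(community.abundances.at[taxon, stage])
                for j, gene in enumerate(community.genes):
                    if observed[i, j]:
                        rows.append(
                            {
                                "order": taxon,
                                "gene": gene,
                                "layer": layer,
                                "stage": stage,
                                "abundance": base * float(scale[i, j]),
                            }
                        )
    frame = pd.DataFrame(rows, columns=["order", "gene", "layer", "stage", "abundance"])
    return AnnotationTable.from_frame(
        frame,
        provenance={"generator": "simulate_annotation_table", "seed": noise.seed,
                    "dropout": noise.dropout, "spurious": noise.spurious},
    )


# ---------------------------------------------------------------------------
# fixed qualitative fixture


#: order-level relative-abundance weights per (layer, stage); chosen so the
#: dominant orders mirror a fly-gut community (Enterobacterales dominant
#: everywhere, Orbales leading the adult metatranscriptome).
_ORDER_WEIGHTS: dict[tuple[str, str], dict[str, float]] = {
    ("DNA", "larva"): {
        "Enterobacterales": 70.0, "Lactobacillales": 9.0, "Clostridiales": 6.0,
        "Pseudomonadales": 4.0, "Flavobacteriales": 3.0, "Bacteroidales": 2.0,
    },
    ("DNA", "adult"): {
        "Enterobacterales": 62.0, "Orbales": 12.0, "Lactobacillales": 9.0,
        "Pseudomonadales": 5.0, "Flavobacteriales": 3.0, "Bacteroidales": 2.0,
    },
    ("RNA", "larva"): {
        "Enterobacterales": 30.0, "Lactobacillales": 12.0, "Flavobacteriales": 6.0,
        "Clostridiales": 5.0, "Bacteroidales": 3.0, "Pseudomonadales": 2.0,
    },
    ("RNA", "adult"): {
        "Orbales": 23.39, "Enterobacterales": 18.0, "Lactobacillales": 10.0,
        "Bacteroidales": 4.0, "Desulfovibrionales": 2.0, "Pseudomonadales": 1.5,
    },
}


def simulate_observed_pattern(registry: PathwayRegistry | None = None) -> AnnotationTable:
    """Fixed annotation table encoding the qualitative fly-gut presence
    pattern: the full nitrogenase gene complement (anfG, nifD, nifK, nifH) in
    the Enterobacterales metagenome but only nifH on the transcript layer;
    the urease cluster on both layers across core orders; argF absent from
    every taxon; every other registry gene present on both layers.

    Running the completeness engine on this table yields biological nitrogen
    fixation blocked at the dinitrogenase step on the RNA layer, complete urea
    hydrolysis, and arginine as the only incomplete EAA pathway.
    """
    registry = registry or default_registry()
    rows: list[tuple[str, str, str, str]] = []  # (order, gene, layer, stage)

    def add(order: str, genes, layer: str, stage: str) -> None:
        for gene in genes:
            rows.append((order, gene, layer, stage))

    # nitrogen fixation: full complement in the Enterobacterales metagenome,
    # nifH scattered more widely; transcripts restricted to nifH.
    add("Enterobacterales", ["anfG", "nifD", "nifK", "nifH"], "DNA", "larva")
    add("Clostridiales", ["nifH"], "DNA", "larva")
    add("Lactobacillales", ["nifH"], "DNA", "larva")
    add("Enterobacterales", ["anfG", "nifD", "nifK", "nifH"], "DNA", "adult")
    add("Orbales", ["nifH"], "DNA", "adult")
    add("Lactobacillales", ["nifH"], "DNA", "adult")
    for order in ("Enterobacterales", "Lactobacillales", "Flavobacteriales"):
        add(order, ["nifH"], "RNA", "larva")
    for order in ("Orbales", "Enterobacterales", "Lactobacillales", "Bacteroidales", "Desulfovibrionales"):
        add(order, ["nifH"], "RNA", "adult")

    urease = ["URE", "ureA", "ureB", "ureC", "ureAB"]
    assimilation = ["gdhA", "glnA", "gltB", "gltD", "aspC", "aspB"]
    eaa_genes = sorted(registry.genes("EAA") - {"argf"})
    for layer in ("DNA", "RNA"):
        for stage, orders in (("larva", ("Enterobacterales", "Lactobacillales")),
                              ("adult", ("Enterobacterales", "Orbales", "Lactobacillales"))):
            for order in orders:
                add(order, urease, layer, stage)
                add(order, assimilation, layer, stage)
            add("Enterobacterales", [registry.display(g) for g in eaa_genes], layer, stage)

    # spread each order's relative abundance over its genes so that the
    # order-level totals reproduce the intended community profile
    counts: dict[tuple[str, str, str], int] = {}
    for order, _, layer, stage in rows:
        counts[(order, layer, stage)] = counts.get((order, layer, stage), 0) + 1
    frame = pd.DataFrame(
        [
            {
                "order": order,
                "gene": gene,
                "layer": layer,
                "stage": stage,
                "abundance": _ORDER_WEIGHTS[(layer, stage)].get(order, 1.0)
                / counts[(order, layer, stage)],
            }
            for order, gene, layer, stage in rows
        ]
    )
    return AnnotationTable.from_frame(frame, provenance={"generator": "simulate_observed_pattern"})


# ---------------------------------------------------------------------------
# feeding trial and qPCR generators


def simulate_tracer_trial(
    n_per_group: int = 5,
    f_assimilation: float = 0.3,
    suppression: float = 0.6,
    diet_atom_percent: float = 5.17,
    natural_atom_percent: float = NATURAL_ATOM_PERCENT,
    sd: float = 0.1,
    seed: int = 0,
    stage: str = "adult",
    tissues: Sequence[str] = ("gut",),
) -> list[TracerMeasurement]:
    """Three-arm feeding trial on a 5.17 atom% heavy-urea diet.

    Tissue enrichment is ``natural + f_eff * (diet - natural)`` plus Gaussian
    noise, where the effective assimilated fraction ``f_eff`` is
    ``f_assimilation`` for the untreated heavy-urea arm, scaled down by
    ``1 - suppression`` under antibiotics, and zero on the light-urea diet.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    for name, value in (("f_assimilation", f_assimilation), ("suppression", suppression)):
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    if not 0 <= natural_atom_percent < 100 or not 0 <= diet_atom_percent < 100:
        raise ValueError("atom percentages must lie in [0, 100)")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    f_eff = {
        "n14_bact_plus": 0.0,
        "n15_bact_plus": f_assimilation,
        "n15_bact_minus": f_assimilation * (1.0 - suppression),
    }
    out: list[TracerMeasurement] = []
    for tissue in tissues:
        for group in GROUPS:
            centre = natural_atom_percent + f_eff[group] * (diet_atom_percent - natural_atom_percent)
            values = np.clip(centre + rng.normal(0.0, sd, size=n_per_group), 0.0, 99.9)
            for i, v in enumerate(values):
                out.append(
                    TracerMeasurement(
                        sample_id=f"{stage[:1]}-{tissue[:2]}-{group}-{i + 1}",
                        stage=stage,
                        tissue=tissue,
                        group=group,
                        atom_percent_15N=float(v),
                    )
                )
    return out


def simulate_qpcr(
    strains: Sequence[str] = ("Kp", "Kox", "Cf", "Mm"),
    conditions: Sequence[float] = (5.5, 7.0),
    planted_ct_shifts: Mapping[tuple[str, float], float] | None = None,
    sd: float = 0.2,
    n_replicates: int = 3,
    ct_reference: float = 15.0,
    seed: int = 0,
) -> list[QpcrRecord]:
    """qPCR runs with planted Ct shifts.

    ``planted_ct_shifts`` maps (strain, condition) to the mean delta-Ct
    (Ct_ureC - Ct_16S); the recovered relative expression is
    ``2 ** (-shift)`` in expectation (a shift of -1 doubles expression).
    Missing entries default to 0 (expression ratio 1).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    planted_ct_shifts = dict(planted_ct_shifts or {})
    rng = np.random.default_rng(seed)
    out: list[QpcrRecord] = []
    for strain in strains:
        for condition in conditions:
            shift = planted_ct_shifts.get((strain, float(condition)), 0.0)
            noise = rng.normal(0.0, sd, size=n_replicates)
            for rep in range(n_replicates):
                out.append(
                    QpcrRecord(
                        strain=strain,
                        condition=float(condition),
                        ct_target=ct_reference + shift + float(noise[rep]),
                        ct_reference=ct_reference,
                        replicate=rep + 1,
                    )
                )
    return out


def tracer_frame(measurements: Sequence[TracerMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "stage": m.stage,
                "tissue": m.tissue,
                "group": m.group,
                "atom_percent": m.atom_percent_15N,
                "delta15N": m.delta15N,
            }
            for m in measurements
        ]
    )


def qpcr_frame(records: Sequence[QpcrRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": r.strain,
                "pH": r.condition,
                "ct_ureC": r.ct_target,
                "ct_16S": r.ct_reference,
                "replicate": r.replicate,
                "relative_expression": r.relative_expression_value,
            }
            for r in records
        ]
    )
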