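"""Taxon x gene annotation tables, presence reduction, and core-taxon selection.

The input is a long-form TSV of derived annotation results: one row per
(taxon, gene, omic layer, life stage) with a non-negative abundance. The
metagenome layer (``DNA``, a.k.a. ``G``) records gene presence in assembled
genomes; the metatranscriptome layer (``RNA``, a.k.a. ``T``) records detected
expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .pathway_model import canonical_symbol

log = logging.getLogger(__name__)


class Layer(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


class Stage(str, Enum):
    LARVA = "larva"
    PUPA = "pupa"
    ADULT = "adult"


_LAYER_SYNONYMS = {
    "dna": Layer.DNA,
    "g": Layer.DNA,
    "dna-seq": Layer.DNA,
    "dnaseq": Layer.DNA,
    "metagenome": Layer.DNA,
    "rna": Layer.RNA,
    "t": Layer.RNA,
    "rna-seq": Layer.RNA,
    "rnaseq": Layer.RNA,
    "metatranscriptome": Layer.RNA,
}

_STAGE_SYNONYMS = {
    "larva": Stage.LARVA,
    "larvae": Stage.LARVA,
    "larval": Stage.LARVA,
    "l": Stage.LARVA,
    "bdl": Stage.LARVA,
    "pupa": Stage.PUPA,
    "pupae": Stage.PUPA,
    "p": Stage.PUPA,
    "bdp": Stage.PUPA,
    "adult": Stage.ADULT,
    "adults": Stage.ADULT,
    "a": Stage.ADULT,
    "bda": Stage.ADULT,
}


def parse_layer(value: str) -> Layer:
    try:
        return _LAYER_SYNONYMS[str(value).strip().casefold()]
    except KeyError:
        raise ValueError(f"unknown omic layer {value!r}; expected DNA/G or RNA/T") from None


def parse_stage(value: str) -> Stage:
    try:
        return _STAGE_SYNONYMS[str(value).strip().casefold()]
    except KeyError:
        raise ValueError(f"unknown life stage {value!r}; expected larva, pupa or adult") from None


@dataclass(frozen=True)
class TaxonLineage:
    """Taxonomic lineage down to (optionally) species; order is mandatory."""

    order: str
    genus: str | None = None
    species: str | None = None

    def __post_init__(self):
        if not self.order or not str(self.order).strip():
            raise ValueError("order name must be non-empty")
        if self.species and not self.genus:
            raise ValueError(f"species {self.species!r} given without genus")

    def at_rank(self, rank: str) -> str:
        if rank == "order":
            return self.order
        if rank == "genus":
            if not self.genus:
                raise ValueError(f"lineage {self} has no genus")
            return self.genus
        raise ValueError(f"unsupported rank {rank!r} (use 'order' or 'genus')")


REQUIRED_COLUMNS = ("order", "gene", "layer", "stage", "abundance")
OPTIONAL_COLUMNS = ("genus", "species")


@dataclass
class AnnotationTable:
    """Canonicalized long-form annotation records.

    ``frame`` columns: order, genus, species, gene (canonical), gene_display,
    layer (Layer value), stage (Stage value), abundance. At most one row per
    (order, genus, species, gene, layer, stage); duplicates are aggregated by
    summing abundance at construction time.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def layers(self) -> frozenset[str]:
        return frozenset(self.frame["layer"].unique())

    @property
    def stages(self) -> frozenset[str]:
        return frozenset(self.frame["stage"].unique())

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "AnnotationTable":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing required column(s): {', '.join(missing)}")
        df = df.copy()
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = None
        df["order"] = df["order"].astype(str).str.strip()
        bad_order = df.index[df["order"].isin(["", "nan", "None"])]
        if len(bad_order):
            raise ValueError(f"empty order name at row {bad_order[0]}")
        df["genus"] = df["genus"].where(df["genus"].notna(), None)
        df["species"] = df["species"].where(df["species"].notna(), None)
        df["gene_display"] = df["gene"].astype(str).str.strip()
        df["gene"] = df["gene_display"].map(canonical_symbol)
        df["layer"] = df["layer"].map(lambda v: parse_layer(v).value)
        df["stage"] = df["stage"].map(lambda v: parse_stage(v).value)
        abundance = pd.to_numeric(df["abundance"], errors="coerce")
        if abundance.isna().any():
            row = int(df.index[abundance.isna()][0])
            raise ValueError(f"non-numeric abundance at row {row}")
        if (abundance < 0).any():
            row = int(df.index[abundance < 0][0])
            raise ValueError(f"negative abundance at row {row}")
        df["abundance"] = abundance.astype(float)

        key = ["order", "genus", "species", "gene", "layer", "stage"]
        dupes = df.duplicated(subset=key, keep=False)
        if dupes.any():
            log.info("aggregating %d duplicate annotation rows by summing abundance", int(dupes.sum()))
            df = (
                df.groupby(key, dropna=False, sort=False)
                .agg(abundance=("abundance", "sum"), gene_display=("gene_display", "first"))
                .reset_index()
            )
        columns = ["order", "genus", "species", "gene", "gene_display", "layer", "stage", "abundance"]
        return cls(frame=df[columns].reset_index(drop=True), provenance=dict(provenance or {}))


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a tab-separated annotation table (UTF-8, header row mandatory)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return AnnotationTable.from_frame(df, provenance={"source": str(path)})


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    out = table.frame.drop(columns="gene").rename(columns={"gene_display": "gene"})
    out = out[["order", "genus", "species", "gene", "layer", "stage", "abundance"]]
    out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean indicator over (taxon, gene, layer, stage).

    ``cells`` holds the present cells; ``layers`` records which omic layers
    the source table observed at all (an observed layer with no present cells
    is distinct from a layer that was never measured).
    """

    cells: frozenset[tuple[str, str, str, str]]
    threshold: float
    rank: str
    taxa: frozenset[str]
    genes: frozenset[str]
    layers: frozenset[str]
    stages: frozenset[str]

    def is_present(self, taxon: str, gene: str, layer: str, stage: str) -> bool:
        return (taxon, canonical_symbol(gene), str(Layer(layer).value), str(Stage(stage).value)) in self.cells

    def taxa_with(self, gene: str, layer: str, stage: str, within: Iterable[str] | None = None) -> frozenset[str]:
        gene = canonical_symbol(gene)
        layer, stage = Layer(layer).value, Stage(stage).value
        scope = set(within) if within is not None else None
        return frozenset(
            t for (t, g, l, s) in self.cells
            if g == gene and l == layer and s == stage and (scope is None or t in scope)
        )

    def genes_of(self, taxon: str, layer: str, stage: str) -> frozenset[str]:
        layer, stage = Layer(layer).value, Stage(stage).value
        return frozenset(g for (t, g, l, s) in self.cells if t == taxon and l == layer and s == stage)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.cells)
        return pd.DataFrame(rows, columns=["taxon", "gene", "layer", "stage"]).assign(present=1)


def derive_presence(table: AnnotationTable, threshold: float = 0.0, rank: str = "order") -> PresenceMatrix:
    """Reduce abundances to presence: present iff abundance > ``threshold``.

    Deterministic and idempotent; raising the threshold can only remove cells.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    df = table.frame
    if rank == "order":
        taxon = df["order"]
    elif rank == "genus":
        if df["genus"].isna().any():
            raise ValueError("cannot derive genus-rank presence: some records lack a genus")
        taxon = df["genus"]
    else:
        raise ValueError(f"unsupported rank {rank!r}")
    mask = df["abundance"] > threshold
    cells = frozenset(zip(taxon[mask], df.loc[mask, "gene"], df.loc[mask, "layer"], df.loc[mask, "stage"]))
    return PresenceMatrix(
        cells=cells,
        threshold=float(threshold),
        rank=rank,
        taxa=frozenset(taxon.unique()),
        genes=frozenset(df["gene"].unique()),
        layers=frozenset(df["layer"].unique()),
        stages=frozenset(df["stage"].unique()),
    )


def select_core_taxa(
    table: AnnotationTable,
    rank: str = "order",
    k: int = 5,
    layers: Sequence[str] = (Layer.DNA, Layer.RNA),
    stages: Sequence[str] = (Stage.LARVA, Stage.ADULT),
) -> list[str]:
    """Core taxa: union over each (layer, stage) of the top-``k`` taxa by
    summed abundance at ``rank``. Ties at rank ``k`` include all tied taxa.

    The default scope mirrors the usual core-community rule: the five most
    abundant orders of the DNA and RNA layers in larvae and adults. The result
    is ordered by total abundance over the full scope (descending), then name.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    df = table.frame
    if df.empty:
        log.warning("select_core_taxa called on an empty annotation table")
        return []
    layers = [Layer(l).value for l in layers]
    stages = [Stage(s).value for s in stages]
    if rank == "order":
        df = df.assign(taxon=df["order"])
    elif rank == "genus":
        df = df[df["genus"].notna()].assign(taxon=lambda d: d["genus"])
    else:
        raise ValueError(f"unsupported rank {rank!r}")

    core: set[str] = set()
    for layer in layers:
        for stage in stages:
            sub = df[(df["layer"] == layer) & (df["stage"] == stage)]
            if sub.empty or k == 0:
                continue
            totals = sub.groupby("taxon")["abundance"].sum().sort_values(ascending=False)
            if len(totals) <= k:
                chosen = set(totals.index)
            else:
                cutoff = totals.iloc[k - 1]
                chosen = set(totals.index[totals >= cutoff])
                if len(chosen) > k:
                    log.info(
                        "tie at rank %d for layer=%s stage=%s: including %d taxa",
                        k, layer, stage, len(chosen),
                    )
            core |= chosen

    scope = df[df["layer"].isin(layers) & df["stage"].isin(stages)]
    totals = scope.groupby("taxon")["abundance"].sum()
    return sorted(core, key=lambda t: (-float(totals.get(t, 0.0)), t))
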