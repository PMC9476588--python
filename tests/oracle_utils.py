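"""Independent brute-force oracles and small construction helpers.

The oracles deliberately use naive exhaustive enumeration (itertools over all
gene->taxon assignments, per-step scans) so that they share no code path with
the set-based engine they are checked against.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import pandas as pd

from nitrocycle.annotation_io import AnnotationTable, PresenceMatrix
from nitrocycle.pathway_model import ReactionStep, canonical_symbol


def make_presence(
    cells: Iterable[tuple[str, str, str, str]],
    taxa: Iterable[str] = (),
    genes: Iterable[str] = (),
    layers: Iterable[str] = ("DNA", "RNA"),
    stages: Iterable[str] = ("larva", "adult"),
    threshold: float = 0.0,
) -> PresenceMatrix:
    cells = frozenset((t, canonical_symbol(g), l, s) for (t, g, l, s) in cells)
    return PresenceMatrix(
        cells=cells,
        threshold=threshold,
        rank="order",
        taxa=frozenset(taxa) | frozenset(t for (t, _, _, _) in cells),
        genes=frozenset(canonical_symbol(g) for g in genes) | frozenset(g for (_, g, _, _) in cells),
        layers=frozenset(layers),
        stages=frozenset(stages),
    )


def make_table(rows: Sequence[dict]) -> AnnotationTable:
    return AnnotationTable.from_frame(pd.DataFrame(rows))


def brute_force_step_satisfied(
    step: ReactionStep,
    present: Mapping[tuple[str, str], bool],
    taxa: Sequence[str],
    pooling: str,
) -> bool:
    """Exhaustively enumerate gene->taxon assignments for each alternative."""
    for group in step.alternatives:
        genes = sorted(group)
        for assignment in itertools.product(taxa, repeat=len(genes)):
            if pooling == "single_taxon" and len(set(assignment)) > 1:
                continue
            if all(present.get((t, g), False) for t, g in zip(assignment, genes)):
                return True
    return False


def brute_force_contribution(
    steps: Sequence[ReactionStep],
    carried: set[str],
    mode: str,
) -> int:
    involved = 0
    for step in steps:
        if mode == "any_gene":
            hit = any(g in carried for group in step.alternatives for g in group)
        else:
            hit = any(all(g in carried for g in group) for group in step.alternatives)
        involved += hit
    return involved


def random_step_instance(rng, max_genes: int = 6, max_taxa: int = 6):
    """A random (step, presence-dict, taxa) triple over a tiny gene universe."""
    n_genes = rng.integers(1, max_genes + 1)
    universe = [f"g{i}" for i in range(n_genes)]
    n_alt = rng.integers(1, 4)
    alternatives = []
    for _ in range(n_alt):
        size = rng.integers(1, min(3, n_genes) + 1)
        alternatives.append(frozenset(rng.choice(universe, size=size, replace=False).tolist()))
    step = ReactionStep(step_id="s", label="random", alternatives=tuple(alternatives))
    n_taxa = rng.integers(1, max_taxa + 1)
    taxa = [f"t{i}" for i in range(n_taxa)]
    present = {
        (t, g): bool(rng.random() < 0.4)
        for t in taxa
        for g in universe
    }
    return step, present, taxa
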