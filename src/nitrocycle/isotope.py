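"""Stable-isotope tracer arithmetic and the feeding-trial / qPCR statistics.

The tracer quantities follow the standard mass-spectrometry conventions:

    atom% 15N   = 100 * 15N / (15N + 14N)
    ratio       = 15N / 14N = atom% / (100 - atom%)
    delta15N    = 1000 * (ratio_sample / ratio_standard - 1)   [per mil]

with the atmospheric-N2 standard ratio fixed at 0.003676 (equivalently a
natural abundance of 0.3663 atom% 15N). Group comparison is one-way ANOVA
followed by Tukey's HSD with a compact letter display; urease expression is
the ratio statistic 2^-(Ct_target - Ct_reference) with two-sided t-tests
between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: 15N/14N of the atmospheric-N2 reference standard.
STANDARD_RATIO = 0.003676
#: Natural 15N abundance in atom percent; consistent with the standard ratio
#: because 0.3663 / (100 - 0.3663) = 0.003676.
NATURAL_ATOM_PERCENT = 0.3663

TISSUES = ("body wall", "gut", "fat body", "Malpighian tubules", "ovary", "other")
GROUPS = ("n14_bact_plus", "n15_bact_plus", "n15_bact_minus")
STRAINS = ("Kp", "Kox", "Cf", "Mm")


# ---------------------------------------------------------------------------
# tracer arithmetic


def atom_percent_to_ratio(atom_percent: float) -> float:
    """15N/14N isotope ratio from atom% 15N."""
    if not 0 <= atom_percent < 100:
        raise ValueError(f"atom percent must lie in [0, 100), got {atom_percent}")
    return atom_percent / (100.0 - atom_percent)


def ratio_to_atom_percent(ratio: float) -> float:
    """Inverse of :func:`atom_percent_to_ratio`."""
    if ratio < 0:
        raise ValueError(f"isotope ratio must be >= 0, got {ratio}")
    return 100.0 * ratio / (1.0 + ratio)


def delta15N(ratio_sample: float, ratio_standard: float = STANDARD_RATIO) -> float:
    """delta-15N in per mil relative to the reference standard."""
    if ratio_standard <= 0:
        raise ValueError(f"standard ratio must be positive, got {ratio_standard}")
    if ratio_sample < 0:
        raise ValueError(f"sample ratio must be >= 0, got {ratio_sample}")
    return 1000.0 * (ratio_sample / ratio_standard - 1.0)


def atom_percent_to_delta15N(atom_percent: float, ratio_standard: float = STANDARD_RATIO) -> float:
    return delta15N(atom_percent_to_ratio(atom_percent), ratio_standard)


# ---------------------------------------------------------------------------
# observations


@dataclass(frozen=True)
class TracerMeasurement:
    """One isotope-ratio MS measurement of a dissected tissue."""

    sample_id: str
    stage: str
    tissue: str
    group: str
    atom_percent_15N: float

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown treatment group {self.group!r}; expected one of {GROUPS}")
        if not 0 <= self.atom_percent_15N < 100:
            raise ValueError(f"atom percent out of range: {self.atom_percent_15N}")

    @property
    def delta15N(self) -> float:
        return atom_percent_to_delta15N(self.atom_percent_15N)


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR observation: target (ureC) and reference (16S) thresholds."""

    strain: str
    condition: float  # pH
    ct_target: float
    ct_reference: float
    replicate: int = 1

    def __post_init__(self):
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be positive and finite, got {ct}")

    @property
    def relative_expression_value(self) -> float:
        return relative_expression(self.ct_target, self.ct_reference)


def read_tracer_table(path: str | Path) -> list[TracerMeasurement]:
    """TSV columns: sample_id, stage, tissue, group, atom_percent."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["sample_id", "stage", "tissue", "group", "atom_percent"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    return [
        TracerMeasurement(
            sample_id=str(r.sample_id),
            stage=str(r.stage),
            tissue=str(r.tissue),
            group=str(r.group),
            atom_percent_15N=float(r.atom_percent),
        )
        for r in df.itertuples()
    ]


def read_qpcr_table(path: str | Path) -> list[QpcrRecord]:
    """TSV columns: strain, pH, ct_ureC, ct_16S, replicate."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["strain", "pH", "ct_ureC", "ct_16S"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return [
        QpcrRecord(
            strain=str(r.strain),
            condition=float(r.pH),
            ct_target=float(r.ct_ureC),
            ct_reference=float(r.ct_16S),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# group comparison: ANOVA + Tukey HSD + compact letter display


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]  # ordered by descending mean
    n: Mapping[str, int]
    means: Mapping[str, float]
    sds: Mapping[str, float]
    f_statistic: float
    p_value: float
    tukey_p: Mapping[tuple[str, str], float]
    letters: Mapping[str, str]
    alpha: float

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _maximal_cliques(nodes: Sequence[str], edges: set[frozenset[str]]) -> list[set[str]]:
    """Bron-Kerbosch maximal cliques of a small undirected graph."""
    adj = {v: {u for u in nodes if frozenset((u, v)) in edges} for v in nodes}
    cliques: list[set[str]] = []

    def expand(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in sorted(p):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(nodes), set())
    return cliques


def compact_letter_display(
    groups: Sequence[str],
    means: Mapping[str, float],
    pairwise_p: Mapping[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Letters over the non-significance graph.

    Each maximal clique of the graph whose edges join pairs with p >= alpha
    receives one letter, so (i) two groups with p < alpha never share a letter
    and (ii) two groups with p >= alpha always share at least one (their edge
    lies in some maximal clique). Letters are ordered by the best (highest)
    group mean they contain, descending.
    """
    edges = {
        frozenset((a, b))
        for (a, b), p in pairwise_p.items()
        if a != b and p >= alpha
    }
    cliques = _maximal_cliques(list(groups), edges)
    cliques.sort(key=lambda c: (-max(means[g] for g in c), tuple(sorted(c))))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for i, clique in enumerate(cliques):
        letter = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in clique:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def anova_tukey(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way fixed-effects ANOVA then all-pairs Tukey HSD with letters."""
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = {g: np.asarray(samples[g], dtype=float) for g in names}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than two observations")
    f_stat, p_val = stats.f_oneway(*arrays.values())
    hsd = stats.tukey_hsd(*arrays.values())
    tukey_p: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                p = float(hsd.pvalue[i, j])
                tukey_p[(a, b)] = p
                tukey_p[(b, a)] = p
    means = {g: float(arr.mean()) for g, arr in arrays.items()}
    order = tuple(sorted(names, key=lambda g: (-means[g], g)))
    letters = compact_letter_display(order, means, tukey_p, alpha)
    return GroupComparison(
        groups=order,
        n={g: int(arr.size) for g, arr in arrays.items()},
        means=means,
        sds={g: float(arr.std(ddof=1)) for g, arr in arrays.items()},
        f_statistic=float(f_stat),
        p_value=float(p_val),
        tukey_p=tukey_p,
        letters=letters,
        alpha=alpha,
    )


def compare_groups(
    measurements: Iterable[TracerMeasurement],
    response: str = "delta15N",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare treatment groups of one tissue/stage slice of a feeding trial."""
    if response not in ("delta15N", "atom_percent"):
        raise ValueError("response must be 'delta15N' or 'atom_percent'")
    by_group: dict[str, list[float]] = {}
    for m in measurements:
        value = m.delta15N if response == "delta15N" else m.atom_percent_15N
        by_group.setdefault(m.group, []).append(value)
    return anova_tukey(by_group, alpha=alpha)


def compare_groups_by_tissue(
    measurements: Iterable[TracerMeasurement],
    response: str = "delta15N",
    alpha: float = 0.05,
) -> dict[tuple[str, str], GroupComparison]:
    """Per (stage, tissue) group comparisons, mirroring per-tissue reporting."""
    slices: dict[tuple[str, str], list[TracerMeasurement]] = {}
    for m in measurements:
        slices.setdefault((m.stage, m.tissue), []).append(m)
    return {key: compare_groups(ms, response, alpha) for key, ms in sorted(slices.items())}


# ---------------------------------------------------------------------------
# qPCR relative expression and two-condition tests


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^-(Ct_target - Ct_reference): target abundance relative to reference."""
    for name, ct in (("ct_target", ct_target), ("ct_reference", ct_reference)):
        if not math.isfinite(ct):
            raise ValueError(f"{name} must be finite, got {ct}")
    return 2.0 ** (-(ct_target - ct_reference))


@dataclass(frozen=True)
class TwoConditionResult:
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    welch: bool


def two_condition_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
    welch: bool = True,
) -> TwoConditionResult:
    """Two-sided two-sample t-test (Welch by default; pooled optional)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each condition needs at least two observations")
    stat, p = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(p)
    if math.isnan(p):  # zero variance in both samples with equal means
        p = 1.0
        stat = 0.0
    return TwoConditionResult(
        statistic=float(stat), p_value=p, significant=p < alpha, alpha=alpha, welch=welch
    )


def qpcr_condition_tests(
    records: Iterable[QpcrRecord],
    alpha: float = 0.05,
    welch: bool = True,
) -> dict[str, TwoConditionResult]:
    """Per-strain test of relative expression between the two pH conditions."""
    by: dict[str, dict[float, list[float]]] = {}
    for r in records:
        by.setdefault(r.strain, {}).setdefault(r.condition, []).append(r.relative_expression_value)
    out: dict[str, TwoConditionResult] = {}
    for strain, conditions in sorted(by.items()):
        if len(conditions) != 2:
            raise ValueError(f"strain {strain!r} needs exactly two conditions, got {sorted(conditions)}")
        lo, hi = (conditions[c] for c in sorted(conditions))
        out[strain] = two_condition_test(lo, hi, alpha=alpha, welch=welch)
    return out
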