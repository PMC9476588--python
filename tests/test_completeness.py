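"""Step evaluation, pathway completeness, classification and blockers."""

import numpy as np
import pytest

from nitrocycle.completeness import (
    CATEGORY_ALMOST,
    CATEGORY_COMPLETE,
    CATEGORY_INCOMPLETE,
    ConfigurationError,
    classify_pathway,
    detect_transcriptional_blockers,
    evaluate_step,
    pathway_completeness,
)
from nitrocycle.pathway_model import PathwayDefinition, ReactionStep, canonical_symbol
from oracle_utils import brute_force_step_satisfied, make_presence, random_step_instance

NIFH = canonical_symbol("nifH")


def step(step_id, *alternatives, essential=True):
    return ReactionStep(
        step_id=step_id,
        label=step_id,
        alternatives=tuple(frozenset(map(canonical_symbol, group)) for group in alternatives),
        essential=essential,
    )


class TestEvaluateStep:
    def test_reductase_without_catalytic_genes_leaves_dinitrogenase_unsatisfied(self, registry):
        presence = make_presence([("Enterobacterales", "nifH", "RNA", "larva")])
        bnf = registry["bnf"]
        reductase = evaluate_step(bnf.steps[0], presence, ["Enterobacterales"], "RNA", "larva")
        dinitrogenase = evaluate_step(bnf.steps[1], presence, ["Enterobacterales"], "RNA", "larva")
        assert reductase.satisfied and not dinitrogenase.satisfied
        assert ("nifd", "nifk") in dinitrogenase.gaps

    def test_one_taxon_with_all_genes_satisfies_both_modes(self):
        s = step("s", ["a", "b"])
        presence = make_presence([("T1", "a", "DNA", "larva"), ("T1", "b", "DNA", "larva")])
        for pooling in ("pooled", "single_taxon"):
            assert evaluate_step(s, presence, ["T1", "T2"], "DNA", "larva", pooling).satisfied

    def test_split_complex_counts_only_under_pooling(self):
        s = step("s", ["a", "b"])
        presence = make_presence([("T1", "a", "DNA", "larva"), ("T2", "b", "DNA", "larva")])
        assert evaluate_step(s, presence, ["T1", "T2"], "DNA", "larva", "pooled").satisfied
        assert not evaluate_step(s, presence, ["T1", "T2"], "DNA", "larva", "single_taxon").satisfied

    def test_unknown_gene_is_a_configuration_error(self):
        s = step("s", ["mystery"])
        presence = make_presence([("T1", "a", "DNA", "larva")])
        with pytest.raises(ConfigurationError, match="mystery"):
            evaluate_step(s, presence, ["T1"], "DNA", "larva", known_genes=frozenset({"a"}))

    def test_empty_taxa_rejected(self):
        with pytest.raises(ValueError):
            evaluate_step(step("s", ["a"]), make_presence([]), [], "DNA", "larva")

    @pytest.mark.parametrize("pooling", ["pooled", "single_taxon"])
    def test_matches_exhaustive_enumeration(self, pooling):
        rng = np.random.default_rng(42)
        for _ in range(300):
            s, present, taxa = random_step_instance(rng)
            cells = [(t, g, "DNA", "larva") for (t, g), p in present.items() if p]
            presence = make_presence(cells, taxa=taxa)
            got = evaluate_step(s, presence, taxa, "DNA", "larva", pooling).satisfied
            assert got == brute_force_step_satisfied(s, present, taxa, pooling)


class TestClassification:
    @pytest.mark.parametrize(
        "satisfied,total,blockers,expected",
        [
            (10, 10, 0, CATEGORY_COMPLETE),
            (9, 10, 0, CATEGORY_ALMOST),
            (8, 10, 0, CATEGORY_INCOMPLETE),
            (9, 10, 1, CATEGORY_INCOMPLETE),
            (0, 5, 5, CATEGORY_INCOMPLETE),
        ],
    )
    def test_three_way_rule(self, satisfied, total, blockers, expected):
        assert classify_pathway(satisfied, total, blockers, tolerance=1) == expected

    def test_tolerance_widens_almost_complete(self):
        assert classify_pathway(8, 10, 0, tolerance=2) == CATEGORY_ALMOST


class TestPathwayCompleteness:
    def _pathway(self, *steps):
        return PathwayDefinition("p", "p", "BNF", tuple(steps))

    def test_all_satisfied_is_complete_with_no_blockers(self):
        p = self._pathway(step("s1", ["a"]), step("s2", ["b"]))
        presence = make_presence([("T", "a", "DNA", "larva"), ("T", "b", "DNA", "larva")])
        r = pathway_completeness(p, presence, ["T"], "DNA", "larva")
        assert float(r.completeness) == 1.0 and r.category == CATEGORY_COMPLETE and not r.blockers

    def test_blocker_reports_minimal_gene_gaps(self):
        p = self._pathway(step("s1", ["a"]), step("s2", ["b", "c"], ["d"]))
        presence = make_presence([("T", "a", "DNA", "larva"), ("T", "c", "DNA", "larva")])
        r = pathway_completeness(p, presence, ["T"], "DNA", "larva")
        (blocker,) = r.blockers
        assert blocker.step_id == "s2"
        assert blocker.gene_gaps == (("b",), ("d",))
        assert r.category == CATEGORY_INCOMPLETE

    def test_monotone_in_presence(self):
        rng = np.random.default_rng(3)
        p = self._pathway(
            step("s1", ["a", "b"], ["c"]), step("s2", ["d"]), step("s3", ["b", "e"], essential=False)
        )
        taxa = ["T1", "T2", "T3"]
        genes = list("abcde")
        for _ in range(50):
            cells = {
                (t, g, "DNA", "larva") for t in taxa for g in genes if rng.random() < 0.3
            }
            extra = (str(rng.choice(taxa)), str(rng.choice(genes)), "DNA", "larva")
            before = pathway_completeness(p, make_presence(cells, taxa=taxa), taxa, "DNA", "larva")
            after = pathway_completeness(p, make_presence(cells | {extra}, taxa=taxa), taxa, "DNA", "larva")
            assert after.completeness >= before.completeness
            assert {b.step_id for b in after.blockers} <= {b.step_id for b in before.blockers}

    def test_pooled_completeness_bounds_single_taxon(self):
        rng = np.random.default_rng(11)
        p = self._pathway(step("s1", ["a", "b"]), step("s2", ["c"], ["d", "e"]))
        taxa = ["T1", "T2", "T3"]
        for _ in range(50):
            cells = [
                (t, g, "DNA", "larva") for t in taxa for g in "abcde" if rng.random() < 0.4
            ]
            presence = make_presence(cells, taxa=taxa)
            pooled = pathway_completeness(p, presence, taxa, "DNA", "larva", "pooled")
            best_single = max(
                pathway_completeness(p, presence, [t], "DNA", "larva", "single_taxon").completeness
                for t in taxa
            )
            assert pooled.completeness >= best_single


class TestTranscriptionalBlockers:
    def test_genomic_but_silent_dinitrogenase_is_reported(self, registry, observed_presence):
        report = detect_transcriptional_blockers(
            registry, observed_presence, ["Enterobacterales", "Lactobacillales"], "adult"
        )
        assert [g.step_id for g in report["bnf"]] == ["dinitrogenase"]
        gap = report["bnf"][0]
        assert any("nifd" in g or "nifk" in g for gaps in gap.rna_gaps for g in gaps)

    def test_identical_layers_give_empty_report(self, registry):
        cells = [("T", g, layer, "larva") for g in ("nifH", "nifD", "nifK") for layer in ("DNA", "RNA")]
        report = detect_transcriptional_blockers(registry, make_presence(cells), ["T"], "larva")
        assert report == {}

    def test_missing_layer_is_named_in_the_error(self, registry):
        presence = make_presence([("T", "nifH", "DNA", "larva")], layers=["DNA"])
        with pytest.raises(ValueError, match="RNA"):
            detect_transcriptional_blockers(registry, presence, ["T"], "larva")

    def test_equals_per_layer_set_difference(self, registry):
        rng = np.random.default_rng(5)
        genes = sorted(registry.genes("all"))
        taxa = ["T1", "T2"]
        for _ in range(10):
            cells = {
                (t, g, layer, "larva")
                for t in taxa for g in rng.choice(genes, size=60).tolist()
                for layer in (["DNA"] if rng.random() < 0.7 else ["DNA", "RNA"])
            }
            presence = make_presence(cells, taxa=taxa)
            report = detect_transcriptional_blockers(registry, presence, taxa, "larva")
            flat = {(pid, g.step_id) for pid, gaps in report.items() for g in gaps}
            expected = set()
            for pathway in registry:
                dna = pathway_completeness(pathway, presence, taxa, "DNA", "larva")
                rna = pathway_completeness(pathway, presence, taxa, "RNA", "larva")
                for sid in dna.satisfied_steps - rna.satisfied_steps:
                    expected.add((pathway.pathway_id, sid))
            assert flat == expected
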