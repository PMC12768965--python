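"""Decision rules and full cascade behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bapstools.cascade import (
    AnnotationHit,
    MarkerProfile,
    assign_lifestyle,
    classify_by_hits,
    length_gate,
    phager_gate,
    profiles_from_hit_table,
    propagate_temperate,
    run_cascade,
    screen_markers,
)
from bapstools.core import Contig
from bapstools import synthetic as syn


def _hit(desc="", subj_len=50_000, aln=1_000, db="nucleotide_ref"):
    return AnnotationHit("q", "s", subj_len, aln, 95.0, desc, db)


class TestGates:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (1_200_000, "bacterial"),     # exceeding 1 Mb: true bacteria
            (4_000, "non_candidate"),     # below the 5 kb window
            (5_000, "candidate"),         # inclusive lower bound
            (1_000_000, "candidate"),     # inclusive upper bound
            (1_000_001, "bacterial"),
            (4_999, "non_candidate"),
        ],
    )
    def test_length_gate_boundaries(self, length, expected):
        assert length_gate(length) == expected

    def test_length_gate_accepts_contig(self):
        assert length_gate(Contig("c", "A" * 6_000)) == "candidate"

    @pytest.mark.parametrize(
        "score,expected",
        [(0.79, "fail"), (0.80, "pass"), (1.0, "pass"), (0.0, "fail")],
    )
    def test_phager_gate_strictly_below_excluded(self, score, expected):
        assert phager_gate(score) == expected


class TestHitClassification:
    def test_long_bacterial_top_hit(self):
        hits = [_hit("some chromosome", subj_len=1_500_000, aln=3_000)]
        assert classify_by_hits(hits) == "bacterial"

    def test_bacterial_needs_both_thresholds(self):
        assert classify_by_hits(
            [_hit("x", subj_len=1_500_000, aln=2_000)]) == "no_call"
        assert classify_by_hits(
            [_hit("x", subj_len=1_100_000, aln=3_000)]) == "no_call"

    def test_bacterial_rule_only_applies_to_top_hit(self):
        hits = [_hit("first"), _hit("second", subj_len=1_500_000, aln=3_000)]
        assert classify_by_hits(hits) == "no_call"

    def test_plasmid_keyword(self):
        hits = [_hit("Salmonella enterica plasmid pSLT")]
        assert classify_by_hits(hits) == "plasmid"

    def test_plasmid_keyword_case_insensitive(self):
        assert classify_by_hits([_hit("a PLASMID sequence")]) == "plasmid"

    def test_phage_keyword(self):
        assert classify_by_hits([_hit("Salmonella phage S16")]) == "phage_db_match"

    def test_prophage_suppresses_phage(self):
        assert classify_by_hits(
            [_hit("Escherichia prophage region")]) == "no_call"

    def test_phage_db_source_matches_without_keyword(self):
        assert classify_by_hits(
            [_hit("unnamed entry", db="phage_db")]) == "phage_db_match"

    def test_plasmid_takes_precedence_over_phage(self):
        hits = [_hit("phage-plasmid hybrid plasmid")]
        assert classify_by_hits(hits) == "plasmid"

    def test_empty_hits_is_no_call(self):
        assert classify_by_hits([]) == "no_call"


class TestMarkerScreen:
    def test_exact_toy_terl_only_sets_terl(self):
        markers = {m.marker_class: m for m in syn.toy_markers()}
        profile = screen_markers(
            [markers["terL"].aa_seq], syn.toy_marker_ref(), contig_id="c"
        )
        assert profile.has_terL
        assert not (profile.has_integrase or profile.has_transposase
                    or profile.has_anti_repressor)
        assert profile.evidence

    def test_empty_gene_list_all_false(self):
        profile = screen_markers([], syn.toy_marker_ref())
        assert not any([profile.has_terL, profile.has_integrase,
                        profile.has_transposase, profile.has_anti_repressor])

    def test_flags_are_independent(self):
        markers = {m.marker_class: m for m in syn.toy_markers()}
        profile = screen_markers(
            [markers["terL"].aa_seq, markers["integrase"].aa_seq],
            syn.toy_marker_ref(),
        )
        assert profile.has_terL and profile.has_integrase
        assert not profile.has_transposase

    def test_unrelated_proteins_do_not_match(self):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        profile = screen_markers([junk], syn.toy_marker_ref())
        assert not profile.has_terL

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            screen_markers(["MAAA"], [])

    def test_extra_marker_class_is_exclusionary(self):
        # unknown lysogeny-marker classes behave like integrase
        ref = syn.toy_marker_ref() + [("excisionase", "toy_xis", "M" + "W" * 50)]
        profile = screen_markers(["M" + "W" * 50], ref)
        assert profile.has_integrase

    def test_profiles_from_hit_table(self):
        table = pd.DataFrame(
            [
                {"contig_id": "a", "marker": "terL", "gene_id": "g1",
                 "method": "hmm"},
                {"contig_id": "a", "marker": "integrase", "gene_id": "g2",
                 "method": "hmm"},
                {"contig_id": "b", "marker": "terL", "gene_id": "g9",
                 "method": "hmm"},
            ]
        )
        profiles = profiles_from_hit_table(table)
        assert profiles["a"].has_terL and profiles["a"].has_integrase
        assert profiles["b"].has_terL and not profiles["b"].has_integrase


class TestLifestyleRules:
    def test_single_integrase_taints_whole_cluster(self):
        clusters = {"A": "c1", "B": "c1", "C": "c1"}
        profiles = {
            "A": MarkerProfile("A"),
            "B": MarkerProfile("B"),
            "C": MarkerProfile("C", has_integrase=True),
        }
        assert propagate_temperate(clusters, profiles) == {"A", "B", "C"}

    def test_clean_cluster_untouched(self):
        clusters = {"A": "c1", "B": "c1"}
        profiles = {"A": MarkerProfile("A", has_terL=True),
                    "B": MarkerProfile("B")}
        assert propagate_temperate(clusters, profiles) == set()

    def test_only_tainted_cluster_returned(self):
        clusters = {"A": "c1", "B": "c1", "X": "c2", "Y": "c2"}
        profiles = {
            "A": MarkerProfile("A", has_integrase=True),
            "B": MarkerProfile("B"),
            "X": MarkerProfile("X", has_terL=True),
            "Y": MarkerProfile("Y"),
        }
        # brute-force check over every contig
        tainted = propagate_temperate(clusters, profiles)
        for cid in profiles:
            cluster = clusters[cid]
            expected = any(
                profiles[o].has_integrase
                for o in profiles if clusters[o] == cluster
            )
            assert (cid in tainted) == expected

    def test_unclustered_contig_is_singleton(self):
        profiles = {"solo": MarkerProfile("solo", has_integrase=True),
                    "other": MarkerProfile("other", has_terL=True)}
        assert propagate_temperate({}, profiles) == {"solo"}

    @pytest.mark.parametrize(
        "terl,integrase,transposase,anti,cluster",
        list(itertools.product([False, True], repeat=5)),
    )
    def test_lifestyle_rule_table_enumeration(self, terl, integrase,
                                              transposase, anti, cluster):
        profile = MarkerProfile(
            "c", has_terL=terl, has_integrase=integrase,
            has_transposase=transposase, has_anti_repressor=anti,
        )
        got = assign_lifestyle(profile, cluster)
        # independent restatement of the rule
        if cluster or integrase:
            expected = "temperate"
        elif terl and not (integrase or transposase or anti):
            expected = "lytic"
        else:
            expected = "phage_like_undetermined"
        assert got == expected

    def test_terl_only_is_lytic(self):
        assert assign_lifestyle(
            MarkerProfile("c", has_terL=True), False) == "lytic"

    def test_terl_with_transposase_is_undetermined(self):
        profile = MarkerProfile("c", has_terL=True, has_transposase=True)
        assert assign_lifestyle(profile, False) == "phage_like_undetermined"


class TestRunCascade:
    def test_fixture_labels_and_stages(self, fixture_suite):
        labels, summary = run_cascade(
            fixture_suite.contigs, fixture_suite.scores, fixture_suite.hits,
            fixture_suite.clusters, fixture_suite.profiles,
        )
        for lab in labels:
            assert lab.label == fixture_suite.expected_labels[lab.contig_id]
            assert lab.stage == fixture_suite.expected_stages[lab.contig_id]
        assert sum(summary["counts"].values()) == len(fixture_suite.contigs)

    def test_order_independence(self, fixture_suite):
        fwd, _ = run_cascade(
            fixture_suite.contigs, fixture_suite.scores, fixture_suite.hits,
            fixture_suite.clusters, fixture_suite.profiles,
        )
        rev, _ = run_cascade(
            list(reversed(fixture_suite.contigs)), fixture_suite.scores,
            fixture_suite.hits, fixture_suite.clusters, fixture_suite.profiles,
        )
        assert {(l.contig_id, l.label) for l in fwd} == {
            (l.contig_id, l.label) for l in rev
        }

    def test_all_short_contigs_yield_no_phage_calls(self):
        contigs = [Contig(f"s{i}", "ACGT" * 500) for i in range(4)]  # 2 kb
        labels, summary = run_cascade(contigs, {}, {}, {}, {})
        assert all(l.label == "non_candidate" for l in labels)
        assert summary["counts"]["lytic"] == 0

    def test_duplicate_ids_raise(self):
        contigs = [Contig("dup", "A" * 6_000), Contig("dup", "C" * 6_000)]
        with pytest.raises(ValueError, match="dup"):
            run_cascade(contigs, {}, {}, {}, {})

    def test_partition_invariant(self, fixture_suite):
        labels, summary = run_cascade(
            fixture_suite.contigs, fixture_suite.scores, fixture_suite.hits,
            fixture_suite.clusters, fixture_suite.profiles,
        )
        assert len(labels) == len(fixture_suite.contigs)
        assert len({l.contig_id for l in labels}) == len(labels)
        assert sum(summary["counts"].values()) == len(labels)

    def test_raising_threshold_never_adds_lytic_calls(self, fixture_suite):
        previous = None
        for threshold in (0.5, 0.8, 0.95, 1.01):
            _, summary = run_cascade(
                fixture_suite.contigs, fixture_suite.scores,
                fixture_suite.hits, fixture_suite.clusters,
                fixture_suite.profiles, threshold=threshold,
            )
            lytic = summary["counts"]["lytic"]
            if previous is not None:
                assert lytic <= previous
            previous = lytic

    def test_fuzzed_lytic_calls_never_carry_lysogeny_markers(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(2, 10))
            ids = [f"c{i}" for i in range(n)]
            profiles = {
                cid: MarkerProfile(
                    cid,
                    has_terL=bool(rng.integers(0, 2)),
                    has_integrase=bool(rng.integers(0, 2)),
                    has_transposase=bool(rng.integers(0, 2)),
                    has_anti_repressor=bool(rng.integers(0, 2)),
                )
                for cid in ids
            }
            clusters = {cid: f"cl{rng.integers(0, 3)}" for cid in ids}
            tainted = propagate_temperate(clusters, profiles)
            for cid in ids:
                label = assign_lifestyle(profiles[cid], cid in tainted)
                if label == "lytic":
                    p = profiles[cid]
                    assert not (p.has_integrase or p.has_transposase
                                or p.has_anti_repressor)
                    assert cid not in tainted
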