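"""Tag design, demultiplexing, clustering and taxonomic assignment rules."""

from collections import Counter

import pytest

from sealdiet._align import identity, levenshtein
from sealdiet.amplicon import (
    AssignmentParams,
    Cluster,
    TagDesignError,
    TagSet,
    assign_taxon,
    build_count_table,
    cluster_reads,
    demultiplex,
    design_tags,
    min_pairwise_distance,
)
from sealdiet.refdb import ReferenceDB, ReferenceEntry

PRIMER = "GATCGAGAAGACCCTATGGAGCT"


class TestDesignTags:
    def test_single_base_tags_are_the_four_bases(self):
        ts = design_tags(length=1, min_distance=1, target_count=4, seed=0)
        assert set(ts.tags) == {"A", "C", "G", "T"}

    def test_infeasible_distance_reports_achieved_size(self):
        # two equal-length 2-mers differ by at most 2 edits
        with pytest.raises(TagDesignError) as exc:
            design_tags(length=2, min_distance=3, target_count=2, seed=0)
        assert exc.value.achieved == 1

    def test_distance_invariant_verified_exhaustively(self):
        ts = design_tags(length=6, min_distance=3, target_count=12, seed=5)
        assert min_pairwise_distance(ts.tags) >= 3
        assert ts.verify()

    def test_duplicate_tags_rejected_by_tagset(self):
        with pytest.raises(ValueError):
            TagSet(("ACGT", "ACGT"), 1)


class TestDemultiplex:
    @pytest.fixture
    def tagmap(self):
        ts = design_tags(10, 5, 3, seed=1)
        return dict(zip(ts.tags, ["s1", "s2", "s3"]))

    def test_exact_tag_and_primer_assigned(self, tagmap):
        tag = next(iter(tagmap))
        res = demultiplex([tag + PRIMER + "AAAA"], tagmap, PRIMER)
        assert res.by_sample[tagmap[tag]] == ["AAAA"]
        assert res.n_assigned == 1

    def test_two_mismatches_tolerated_three_rejected(self, tagmap):
        tag = next(iter(tagmap))
        for n_err, ok in [(2, True), (3, False)]:
            bad = _mutate_positions(tag, n_err)
            res = demultiplex([bad + PRIMER + "AAAA"], tagmap, PRIMER)
            assert (res.n_assigned == 1) is ok

    def test_primer_mismatch_budget_is_separate(self, tagmap):
        tag = next(iter(tagmap))
        # 2 in tag AND 2 in primer: both within their own budgets
        res = demultiplex(
            [_mutate_positions(tag, 2) + _mutate_positions(PRIMER, 2) + "AAAA"],
            tagmap, PRIMER,
        )
        assert res.n_assigned == 1
        res = demultiplex(
            [tag + _mutate_positions(PRIMER, 3) + "AAAA"], tagmap, PRIMER
        )
        assert res.n_bad_primer == 1

    def test_ambiguous_tag_discarded_and_tallied(self):
        # relaxed code: two tags at distance 4; a midpoint read is within
        # 2 of both
        t1 = "AAAAAAAAAA"
        t2 = "CCCCAAAAAA"
        assert levenshtein(t1, t2) == 4
        midpoint = "CCAAAAAAAA"
        res = demultiplex(
            [midpoint + PRIMER + "AAAA"], {t1: "s1", t2: "s2"}, PRIMER
        )
        assert res.n_ambiguous_tag == 1
        assert res.n_assigned == 0


def _mutate_positions(seq, n):
    sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
    chars = list(seq)
    for i in range(n):
        chars[i] = sub[chars[i]]
    return "".join(chars)


class TestClusterReads:
    def test_five_identical_reads_one_cluster(self):
        cl = cluster_reads(["ACGT" * 30] * 5)
        assert len(cl) == 1
        assert cl[0].size == 5

    def test_minimum_cluster_size_discards_pairs(self):
        assert cluster_reads(["ACGT" * 30] * 2) == []

    def test_one_substitution_at_300bp_joins_cluster(self):
        s = "ACGT" * 75
        s1 = "T" + s[1:]
        assert identity(s, s1) >= 0.99  # 299/300
        cl = cluster_reads([s] * 4 + [s1] * 3)
        assert len(cl) == 1
        assert cl[0].size == 7
        assert cl[0].representative == s  # most abundant is centroid

    def test_divergent_sequences_split_clusters(self):
        a = "A" * 200
        b = "C" * 200
        cl = cluster_reads([a] * 3 + [b] * 4)
        assert sorted(c.size for c in cl) == [3, 4]

    def test_empty_input_empty_output(self):
        assert cluster_reads([]) == []

    def test_matches_naive_oracle_on_random_inputs(self):
        # independent re-statement of the greedy rule, no shared code path
        import numpy as np

        rng = np.random.default_rng(42)
        base = "".join(rng.choice(list("ACGT"), size=150))
        reads = []
        for _ in range(40):
            s = list(base)
            for pos in rng.choice(150, size=rng.integers(0, 4), replace=False):
                s[pos] = "ACGT"[rng.integers(4)]
            reads.append("".join(s))
        params = AssignmentParams()
        got = cluster_reads(reads, params)

        counts = Counter(reads)
        oracle = []  # list of [rep, size]
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            for c in oracle:
                d = sum(a != b for a, b in zip(seq, c[0]))
                if 1 - d / 150 >= params.cluster_identity:
                    c[1] += n
                    break
            else:
                oracle.append([seq, n])
        oracle = [(r, n) for r, n in oracle if n >= params.min_cluster_size]
        assert [(c.representative, c.size) for c in got] == oracle


class TestAssignTaxon:
    def test_identical_query_assigned_to_species(self, toy_refdb):
        q = toy_refdb.entries[0].sequence * 5  # >=100 bp
        db = ReferenceDB([ReferenceEntry("Clupea_pallasii", "", q)])
        assert assign_taxon(q, db) == "Clupea_pallasii"

    def test_identity_below_threshold_unassigned(self):
        ref = "ACGT" * 50
        query = ref[:170] + "T" * 30  # ~85% identity
        db = ReferenceDB([ReferenceEntry("X", "", ref)])
        assert identity(query, ref) < 0.9
        assert assign_taxon(query, db) is None

    def test_short_query_fails_length_screen(self):
        db = ReferenceDB([ReferenceEntry("X", "", "ACGT" * 50)])
        assert assign_taxon("ACGT" * 10, db) is None

    def test_tie_within_group_returns_merged_id(self):
        s = "ACGT" * 50
        db = ReferenceDB([ReferenceEntry("A", "", s), ReferenceEntry("B", "", s)])
        groups = {"A": "A_OR_B", "B": "A_OR_B"}
        q = "T" + s[1:]
        assert assign_taxon(q, db, groups=groups) == "A_OR_B"

    def test_tie_across_groups_is_ambiguous(self):
        s = "ACGT" * 50
        db = ReferenceDB([ReferenceEntry("A", "", s), ReferenceEntry("B", "", s)])
        assert assign_taxon(s, db, groups={"A": "A", "B": "B"}) is None

    def test_empty_database_is_an_error(self):
        with pytest.raises(ValueError):
            ReferenceDB([])


class TestBuildCountTable:
    def test_minimum_prey_read_boundary(self):
        assignments = {
            "nine": Counter({"Clupea_pallasii": 9}),
            "ten": Counter({"Clupea_pallasii": 10}),
        }
        table, excluded = build_count_table(assignments)
        assert excluded == ["nine"]
        assert list(table.index) == ["ten"]

    def test_predator_reads_do_not_count_as_prey(self):
        assignments = {
            "s": Counter({"Phoca_vitulina": 100, "Clupea_pallasii": 9}),
        }
        table, excluded = build_count_table(assignments)
        assert excluded == ["s"]
        assert len(table) == 0

    def test_predator_and_contaminants_removed_from_retained(self):
        assignments = {
            "s": Counter({"Phoca_vitulina": 5, "Homo_sapiens": 3,
                          "Clupea_pallasii": 50}),
        }
        table, _ = build_count_table(
            assignments, contaminant_taxa={"Homo_sapiens"}
        )
        assert list(table.columns) == ["Clupea_pallasii"]
        assert table.loc["s", "Clupea_pallasii"] == 50
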