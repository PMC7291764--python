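"""Construction pipeline: trimming, recruitment filtering, taxon assignment,
region extraction, identical-sequence collapse, distances and supraspecies."""

import logging
import math

import numpy as np
import pytest

from habitax import (
    BuildParams,
    CompilationCluster,
    Lineage,
    NucleotideSequence,
    RecruitmentHit,
    TrainingSequence,
    TrainingSet,
    assign_members_to_taxa,
    collapse_identical,
    compile_full_length_ts,
    define_supraspecies,
    extract_region,
    extract_region_by_reference,
    filter_recruitment_hits,
    jukes_cantor,
    pairwise_distances,
    trim_reference,
)
from habitax.build import BuildError
from habitax.io import parse_newick


def lin7(genus="Veillonella", species="parvula", family="Veillonellaceae"):
    return Lineage(("Bacteria", "Firmicutes", "Negativicutes",
                    "Veillonellales", family, genus, species))


def member(seq_id, seq, genus="Veillonella", species="parvula",
           taxon="HMT-161", family="Veillonellaceae"):
    return TrainingSequence(NucleotideSequence(seq_id, seq),
                            lin7(genus, species, family), taxon)


class TestTrimReference:
    P = BuildParams()

    def test_standard_window_length(self):
        ref = NucleotideSequence("r", "A" * 1500)
        assert len(trim_reference(ref, self.P)) == 1373 - 28 + 1 == 1346

    def test_window_content(self):
        seq = "".join("ACGT"[i % 4] for i in range(1500))
        out = trim_reference(NucleotideSequence("r", seq), self.P)
        assert out.seq == seq[27:1373]

    def test_too_short_is_error(self):
        with pytest.raises(BuildError):
            trim_reference(NucleotideSequence("r", "A" * 27), self.P)

    def test_exact_end_boundary(self):
        ref = NucleotideSequence("r", "A" * 1373)
        assert len(trim_reference(ref, self.P)) == 1346

    def test_short_reference_truncated_with_warning(self, caplog):
        ref = NucleotideSequence("r", "A" * 1000)
        with caplog.at_level(logging.WARNING, logger="habitax.build"):
            out = trim_reference(ref, self.P)
        assert len(out) == 1000 - 27
        assert "truncated" in caplog.text


class TestFilterRecruitmentHits:
    P = BuildParams()

    def hit(self, ident, cov, slen, with_seq=True):
        seq = NucleotideSequence("s", "A" * slen) if with_seq else None
        portion = NucleotideSequence("s", "A" * min(slen, 1346))
        return RecruitmentHit("r", "s", ident, cov, slen, seq, portion)

    def test_all_thresholds_met_whole_subject(self):
        kept = filter_recruitment_hits([self.hit(99.2, 98.5, 1450)], self.P)
        assert len(kept) == 1
        assert len(kept[0].aligned_portion.seq) == 1450  # whole subject

    def test_identity_below_99_rejected(self):
        assert filter_recruitment_hits([self.hit(98.9, 100, 1450)],
                                       self.P) == []

    def test_coverage_below_98_rejected(self):
        assert filter_recruitment_hits([self.hit(99.5, 97.9, 1450)],
                                       self.P) == []

    def test_short_subject_rejected(self):
        assert filter_recruitment_hits([self.hit(99.5, 99, 999)],
                                       self.P) == []

    def test_genome_contributes_aligned_portion_only(self):
        kept = filter_recruitment_hits([self.hit(99.8, 99, 1_800_000)],
                                       self.P)
        assert len(kept) == 1
        assert len(kept[0].aligned_portion.seq) == 1346

    def test_missing_subject_sequence_is_error(self):
        h = RecruitmentHit("r", "s", 99.5, 99.0, 1500)
        with pytest.raises(BuildError):
            filter_recruitment_hits([h], self.P)

    def test_missing_subject_length_is_error(self):
        h = RecruitmentHit("r", "s", 99.5, 99.0, None)
        with pytest.raises(BuildError):
            filter_recruitment_hits([h], self.P)


class TestAssignMembersToTaxa:
    def hits(self, subject, pairs):
        out = []
        for ref_id, ident, cov in pairs:
            seq = NucleotideSequence(subject, "A" * 1200)
            out.append(RecruitmentHit(ref_id, subject, ident, cov, 1200,
                                      seq, seq))
        return out

    REF_TAXA = {"refA": "A", "refB": "B"}

    def test_strict_best_taxon_wins(self):
        hits = self.hits("s1", [("refA", 99.5, 99), ("refB", 99.1, 100)])
        clusters = assign_members_to_taxa(hits, self.REF_TAXA, BuildParams())
        assert [c.taxon_id for c in clusters] == ["A"]

    def test_exact_tie_reproducible_under_seed(self):
        hits = self.hits("s1", [("refA", 99.3, 99.0), ("refB", 99.3, 99.0)])
        first = assign_members_to_taxa(hits, self.REF_TAXA,
                                       BuildParams(rng_seed=7))
        again = assign_members_to_taxa(hits, self.REF_TAXA,
                                       BuildParams(rng_seed=7))
        assert [c.taxon_id for c in first] == [c.taxon_id for c in again]

    def test_each_subject_in_exactly_one_cluster(self):
        hits = (self.hits("s1", [("refA", 99.3, 99), ("refB", 99.3, 99)])
                + self.hits("s2", [("refA", 99.9, 100)]))
        clusters = assign_members_to_taxa(hits, self.REF_TAXA, BuildParams())
        ids = [s.id for c in clusters for s in c.member_sequences]
        assert sorted(ids) == ["s1", "s2"]

    def test_determinism_of_whole_clustering(self):
        hits = []
        rng = np.random.default_rng(0)
        for i in range(20):
            refs = [("refA", 99.3, 99.0), ("refB", 99.3, 99.0)]
            hits += self.hits(f"s{i}", refs)
        a = assign_members_to_taxa(hits, self.REF_TAXA, BuildParams(rng_seed=3))
        b = assign_members_to_taxa(hits, self.REF_TAXA, BuildParams(rng_seed=3))
        assert [(c.taxon_id, [s.id for s in c.member_sequences])
                for c in a] == \
               [(c.taxon_id, [s.id for s in c.member_sequences]) for c in b]


class TestCompileFullLength:
    def test_refs_only_degenerate_case(self):
        refs = [member("r1", "ACGTACGT"), member("r2", "TTGGCCAA",
                                                 species="dispar",
                                                 taxon="HMT-160")]
        ts = compile_full_length_ts(refs, [])
        assert ts.ids() == ["r1", "r2"]
        assert ts.region == "full_length" and ts.depth == 7

    def test_member_counting_and_lineages(self):
        refs = [member(f"r{i}", "ACGTACGT", species=f"sp{i}",
                       taxon=f"T{i}") for i in range(3)]
        clusters = [
            CompilationCluster("T0", ["r0"], [
                NucleotideSequence(f"m0{j}", "ACGTACGA") for j in range(4)]),
            CompilationCluster("T1", ["r1"],
                               [NucleotideSequence("m10", "ACGTACGC")]),
        ]
        ts = compile_full_length_ts(refs, clusters)
        assert len(ts) == 3 + 4 + 1
        assert ts.lineage_of("m03").species == "sp0"

    def test_unknown_taxon_is_error(self):
        refs = [member("r1", "ACGTACGT")]
        cl = CompilationCluster("nope", [], [NucleotideSequence("m", "ACGT")])
        with pytest.raises(BuildError):
            compile_full_length_ts(refs, [cl])

    def test_duplicate_member_across_clusters_is_error(self):
        refs = [member("r1", "ACGTACGT"),
                member("r2", "ACGTACGT", species="dispar", taxon="HMT-160")]
        dup = NucleotideSequence("m", "ACGT")
        clusters = [CompilationCluster("HMT-161", ["r1"], [dup]),
                    CompilationCluster("HMT-160", ["r2"], [dup])]
        with pytest.raises(BuildError):
            compile_full_length_ts(refs, clusters)


class TestExtractRegion:
    P = BuildParams(region_start=3, region_end=8)

    def test_gap_free_member_is_substring(self):
        aln = {"m1": "ACGTACGTACGT"}
        out = extract_region(aln, ["m1"], self.P)
        assert out[0].seq == "ACGTACGTACGT"[2:8]

    def test_gap_columns_removed(self):
        aln = {"m1": "AC---GTACGTA"}
        out = extract_region(aln, ["m1"], self.P)
        assert out[0].seq == "GTA"  # columns 3..8 = "---GTA" degapped

    def test_all_gap_member_dropped_with_warning(self, caplog):
        aln = {"m1": "AC------ACGT"}
        with caplog.at_level(logging.WARNING, logger="habitax.build"):
            out = extract_region(aln, ["m1"], self.P)
        assert out == [] and "dropped" in caplog.text

    def test_missing_member_is_error(self):
        with pytest.raises(BuildError):
            extract_region({"m1": "ACGTACGTACGT"}, ["m2"], self.P)

    def test_region_beyond_width_is_error(self):
        with pytest.raises(BuildError):
            extract_region({"m1": "ACGT"}, ["m1"], self.P)


class TestExtractRegionByReference:
    def test_identical_member_gives_exact_substring(self):
        ref = NucleotideSequence("r", "AACCGGTTAACCGGTT")
        out = extract_region_by_reference(ref, [ref], 5, 12)
        assert out[0].seq == ref.seq[4:12]

    def test_substituted_member_gives_its_own_bases(self):
        ref = NucleotideSequence("r", "AACCGGTTAACCGGTT")
        mem = NucleotideSequence("m", "AACCGATTAACCGGTT")  # one substitution
        out = extract_region_by_reference(ref, [mem], 5, 12)
        assert out[0].seq == "GATTAACC"

    def test_member_with_deletion_is_shorter(self):
        ref = NucleotideSequence("r", "AAAACCCCGGGGTTTTAAAACCCC")
        mem = NucleotideSequence("m", "AAAACCCCGGGTTTTAAAACCCC")  # one G lost
        out = extract_region_by_reference(ref, [mem], 5, 20)
        assert len(out[0].seq) == 15

    def test_member_with_insertion_is_longer(self):
        ref = NucleotideSequence("r", "AAAACCCCGGGGTTTTAAAACCCC")
        mem = NucleotideSequence("m", "AAAACCCCGGGGGTTTTAAAACCCC")
        out = extract_region_by_reference(ref, [mem], 5, 20)
        assert len(out[0].seq) == 17

    def test_region_beyond_reference_is_error(self):
        ref = NucleotideSequence("r", "ACGT")
        with pytest.raises(BuildError):
            extract_region_by_reference(ref, [ref], 1, 10)


class TestCollapseIdentical:
    P = BuildParams()

    def ts(self, members):
        return TrainingSet(members, depth=7, region="V1V3")

    def test_intragenus_collapse_concatenates_species(self):
        ts = self.ts([
            member("a", "ACGTACGTAC", species="parvula", taxon="HMT-161"),
            member("b", "ACGTACGTAC", species="dispar", taxon="HMT-160"),
            member("c", "TTTTACGTAC", species="parvula", taxon="HMT-161"),
        ])
        out, events = collapse_identical(ts, self.P)
        assert len(out) == 2
        assert out.members[0].lineage.species == "dispar:parvula"
        assert out.members[0].taxon_id == "HMT-160:HMT-161"
        assert events[0].action == "collapsed"

    def test_same_species_duplicates_keep_name(self):
        ts = self.ts([
            member("a", "ACGTACGTAC"), member("b", "ACGTACGTAC"),
        ])
        out, _ = collapse_identical(ts, self.P)
        assert len(out) == 1
        assert out.members[0].lineage.species == "parvula"

    def test_supported_intergenus_collapse_concatenates_genus_too(self):
        members = (
            [member(f"a{i}", "ACGTACGTAC", genus="Afipia", species="broomeae",
                    taxon="HMT-559", family="Bradyrhizobiaceae")
             for i in range(15)]
            + [member(f"b{i}", "ACGTACGTAC", genus="Bradyrhizobium",
                      species="elkanii", taxon="HMT-597",
                      family="Bradyrhizobiaceae") for i in range(14)])
        out, events = collapse_identical(self.ts(members), self.P)
        assert len(out) == 1
        assert out.members[0].lineage.genus == "Afipia:Bradyrhizobium"
        assert out.members[0].lineage.species == "broomeae:elkanii"
        assert events[0].action == "intergenus-collapsed"
        assert "29" in events[0].detail

    def test_weakly_supported_intergenus_merge_rejected(self, caplog):
        members = [
            member("a1", "ACGTACGTAC", genus="Afipia", species="broomeae",
                   taxon="HMT-559"),
            member("b1", "ACGTACGTAC", genus="Bradyrhizobium",
                   species="elkanii", taxon="HMT-597"),
            member("b2", "TTTTTTTTTT", genus="Bradyrhizobium",
                   species="elkanii", taxon="HMT-597"),
        ]
        with caplog.at_level(logging.INFO, logger="habitax.build"):
            out, events = collapse_identical(self.ts(members), self.P)
        rejected = [e for e in events if e.action == "intergenus-rejected"]
        assert len(rejected) == 1
        assert "rejected" in caplog.text or rejected[0].detail
        # drop-minority: one genus survives with a plain (unconcatenated) name
        dup_survivors = [m for m in out.members if m.sequence.seq ==
                         "ACGTACGTAC"]
        assert len(dup_survivors) == 1
        assert ":" not in dup_survivors[0].lineage.genus

    def test_drop_all_policy_removes_group(self):
        params = BuildParams(intergenus_policy="drop-all")
        members = [
            member("a1", "ACGTACGTAC", genus="Afipia", species="broomeae"),
            member("b1", "ACGTACGTAC", genus="Bradyrhizobium",
                   species="elkanii"),
            member("c1", "TTTTTTTTTT"),
        ]
        out, _ = collapse_identical(self.ts(members), params)
        assert [m.id for m in out.members] == ["c1"]

    def test_full_length_input_refused(self):
        ts = TrainingSet([member("a", "ACGT")], depth=7,
                         region="full_length")
        with pytest.raises(BuildError):
            collapse_identical(ts, self.P)

    def test_idempotent(self, build_result):
        curated = build_result["region_curated"]
        again, events = collapse_identical(curated, BuildParams())
        assert [(m.id, m.sequence.seq, m.lineage) for m in again.members] == \
               [(m.id, m.sequence.seq, m.lineage) for m in curated.members]
        assert not events

    def test_species_component_multiset_preserved(self, build_result):
        raw = build_result["region_raw"]
        curated = build_result["region_curated"]
        def comps(ts):
            out = set()
            for m in ts.members:
                out.update(m.lineage.species.split(":"))
            return out
        assert comps(raw) == comps(curated)


class TestDistances:
    def test_jc_zero_for_identical(self):
        assert jukes_cantor(0.0) == 0.0

    def test_jc_closed_form_small_p(self):
        # one difference over 800 aligned sites
        p = 1 / 800
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert jukes_cantor(p) == pytest.approx(expected, rel=1e-12)
        assert jukes_cantor(p) == pytest.approx(0.001251, abs=1e-6)

    def test_jc_saturates_to_infinity(self):
        assert jukes_cantor(0.75) == math.inf
        assert jukes_cantor(0.9) == math.inf

    def test_matrix_symmetric_zero_diagonal(self):
        seqs = [NucleotideSequence("a", "ACGTACGTAC"),
                NucleotideSequence("b", "ACGTACGTAT"),
                NucleotideSequence("c", "TTTTACGTAC")]
        ids, d = pairwise_distances(seqs)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)
        assert d[0, 1] == pytest.approx(jukes_cantor(0.1))

    def test_gap_columns_excluded_pairwise(self):
        seqs = [NucleotideSequence("a", "ACGTACGTAC"),
                NucleotideSequence("b", "-CGTACGTAT")]
        ids, d = pairwise_distances(seqs)
        # 9 comparable sites, 1 difference
        assert d[0, 1] == pytest.approx(jukes_cantor(1 / 9))

    def test_unaligned_lengths_rejected(self):
        seqs = [NucleotideSequence("a", "ACGT"),
                NucleotideSequence("b", "ACGTA")]
        with pytest.raises(BuildError):
            pairwise_distances(seqs)

    def test_patristic_backend(self):
        seqs = [NucleotideSequence("A", "ACGT"), NucleotideSequence("B",
                                                                    "ACGT")]
        tree = parse_newick("(A:0.002,B:0.002);")
        ids, d = pairwise_distances(seqs, backend="patristic", tree=tree)
        assert d[0, 1] == pytest.approx(0.004)

    def test_patristic_without_tree_is_error(self):
        with pytest.raises(BuildError):
            pairwise_distances([NucleotideSequence("A", "ACGT")],
                               backend="patristic")


class TestDefineSupraspecies:
    def curated(self, specs):
        """specs: list of (seq_id, species, taxon)."""
        members = [member(sid, "ACGT" * 3, species=sp, taxon=tx)
                   for sid, sp, tx in specs]
        return TrainingSet(members, depth=7, region="V1V3")

    def test_all_far_apart_repeats_species(self):
        ts = self.curated([("a", "pigrum", "T1"), ("b", "otitis", "T2")])
        d = np.array([[0.0, 0.02], [0.02, 0.0]])
        ts8, groups = define_supraspecies(ts, ["a", "b"], d, BuildParams())
        assert groups == []
        for m in ts8.members:
            assert m.lineage.supraspecies == m.lineage.species

    def test_chain_merges_to_single_group(self):
        # d(A,B)=0.004, d(B,C)=0.004, d(A,C)=0.010 -> one component A:B:C
        ts = self.curated([("a", "A", "T1"), ("b", "B", "T2"),
                           ("c", "C", "T3")])
        d = np.array([[0.0, 0.004, 0.010],
                      [0.004, 0.0, 0.004],
                      [0.010, 0.004, 0.0]])
        ts8, groups = define_supraspecies(ts, ["a", "b", "c"], d,
                                          BuildParams())
        assert len(groups) == 1
        assert groups[0].concatenated_label == "A:B:C"
        assert all(m.lineage.supraspecies == "A:B:C" for m in ts8.members)
        assert [m.lineage.species for m in ts8.members] == ["A", "B", "C"]

    def test_threshold_is_strict_less_than(self):
        ts = self.curated([("a", "A", "T1"), ("b", "B", "T2")])
        d = np.array([[0.0, 0.005], [0.005, 0.0]])
        _, groups = define_supraspecies(ts, ["a", "b"], d, BuildParams())
        assert groups == []  # exactly 0.005 does not merge

    def test_collapsed_record_carries_label_at_both_levels(self, build_result):
        ts8 = build_result["region_supraspecies"]
        merged = [m for m in ts8.members if ":" in m.lineage.species]
        assert merged, "expected a collapsed record in the fixture"
        for m in merged:
            assert m.lineage.supraspecies == m.lineage.species

    def test_sequences_conserved_exactly(self, build_result):
        curated = build_result["region_curated"]
        ts8 = build_result["region_supraspecies"]
        assert [(m.id, m.sequence.seq) for m in curated.members] == \
               [(m.id, m.sequence.seq) for m in ts8.members]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        n = 12
        ts = self.curated([(f"s{i}", f"sp{i}", f"T{i}") for i in range(n)])
        d = rng.uniform(0, 0.01, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"s{i}" for i in range(n)]
        sizes = {}
        for thr in (0.002, 0.004, 0.006, 0.008):
            _, groups = define_supraspecies(
                ts, ids, d, BuildParams(supraspecies_distance=thr))
            sizes[thr] = sorted(len(g.member_taxon_ids) for g in groups)
        # coarser threshold never shrinks any group: compare total merged taxa
        merged = {t: sum(s) for t, s in sizes.items()}
        assert merged[0.002] <= merged[0.004] <= merged[0.006] <= merged[0.008]

    def test_depth8_input_refused(self, build_result):
        ts8 = build_result["region_supraspecies"]
        with pytest.raises(BuildError):
            define_supraspecies(ts8, [], np.zeros((0, 0)), BuildParams())
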