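"""Repertoire census: translation, germline assignment, selection, trees."""

import numpy as np
import pandas as pd
import pytest

from nbpanel import repertoire, synthetic
from nbpanel.repertoire import (
    GermlineCall,
    NanobodyRecord,
    SelectionCriteria,
    UnassignableError,
    UntranslatableError,
    annotate,
    assign_germline,
    build_cladogram,
    count_lysines,
    deduplicate,
    gene_usage,
    identity_matrix,
    mutation_summary,
    select_candidates,
    translate_and_frame,
)


class TestTranslateAndFrame:
    def test_in_frame_clone_translates_at_offset_zero(self, germline_set):
        recs, _ = synthetic.gen_repertoire(germline_set, n=1, mutation_rate=0.0, seed=0)
        aa, off = translate_and_frame(recs[0].nt_seq)
        assert off == 0
        assert aa == recs[0].aa_seq
        assert "*" not in aa

    def test_prefixed_base_shifts_frame_not_translation(self, germline_set):
        recs, _ = synthetic.gen_repertoire(germline_set, n=1, mutation_rate=0.0, seed=0)
        aa0, _ = translate_and_frame(recs[0].nt_seq)
        aa1, off = translate_and_frame("G" + recs[0].nt_seq)
        assert off == 1
        assert aa1 == aa0

    def test_stop_riddled_sequence_is_untranslatable(self):
        # "TAATAAT" repeats put a stop codon early in every reading frame
        with pytest.raises(UntranslatableError):
            translate_and_frame("TAATAAT" * 15)

    def test_bad_alphabet_rejected(self):
        with pytest.raises(UntranslatableError):
            translate_and_frame("ACGTX" * 20)


class TestDeduplicate:
    def test_two_identical_pairs_among_five(self):
        seqs = ["ATGGCT", "ATGGCT", "ATGAAA", "ATGAAA", "ATGCCC"]
        recs = [NanobodyRecord(f"c{i}", s) for i, s in enumerate(seqs)]
        groups = deduplicate(recs, level="nt")
        assert len(groups) == 3
        assert sorted(len(g) for g in groups) == [1, 2, 2]

    def test_single_record_is_one_group(self):
        assert len(deduplicate([NanobodyRecord("c", "ATG")], level="nt")) == 1

    def test_idempotent_and_aa_merges_silent_variants(self, germline_set):
        recs, _ = synthetic.gen_repertoire(germline_set, n=8, mutation_rate=0.03, seed=4)
        # add a silent nt variant of the first clone: same protein, new DNA
        recs.append(NanobodyRecord(clone_id="dup", nt_seq=recs[0].nt_seq,
                                   aa_seq=recs[0].aa_seq, frame_offset=0))
        nt_groups = deduplicate(recs, level="nt")
        aa_groups = deduplicate(recs, level="aa")
        assert len(aa_groups) <= len(nt_groups)
        regrouped = deduplicate([g[0] for g in nt_groups], level="nt")
        assert len(regrouped) == len(nt_groups)


class TestGermlineAssignment:
    def test_planted_substitutions_counted_exactly(self, germline_set):
        """Alignment-based counts must equal the generator's position-wise truth."""
        recs, truth = synthetic.gen_repertoire(germline_set, n=12, mutation_rate=0.05, seed=11)
        for rec in recs:
            call = assign_germline(rec, germline_set)
            t = truth.data["clones"][rec.clone_id]
            assert call.v_gene == t["v_gene"]
            assert call.j_gene == t["j_gene"]
            assert call.d_gene == t["d_gene"]
            assert call.v_nt_mutations == t["n_nt_mutations"]
            assert call.aa_changes == t["n_aa_changes"]

    def test_noiseless_limit_full_identity(self, germline_set):
        recs, _ = synthetic.gen_repertoire(germline_set, n=3, mutation_rate=0.0, seed=2)
        for rec in recs:
            call = assign_germline(rec, germline_set)
            assert call.v_identity == 100.0
            assert call.v_nt_mutations == 0
            assert call.aa_changes == 0

    def test_pure_vj_concatenation_zero_mutations(self, germline_set):
        nt = germline_set.v_genes["IGHV3S66"] + germline_set.j_genes["IGHJ4"]
        rec = NanobodyRecord.from_nt("vj", nt)
        call = assign_germline(rec, germline_set)
        assert (call.v_gene, call.j_gene) == ("IGHV3S66", "IGHJ4")
        assert call.v_nt_mutations == 0 and call.aa_changes == 0
        assert call.d_gene is None

    def test_unassignable_below_identity_floor(self, germline_set):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 300))
        rec = NanobodyRecord(clone_id="junk", nt_seq=junk, aa_seq="M" * 40, frame_offset=0)
        with pytest.raises(UnassignableError):
            assign_germline(rec, germline_set)


class TestLysineCensusAndSelection:
    def test_census_matches_direct_string_count(self, germline_set):
        recs, _ = synthetic.gen_repertoire(germline_set, n=10, mutation_rate=0.06, seed=5)
        for rec in recs:
            annotate(rec, germline_set)
            lys = count_lysines(rec)
            s, e = rec.regions["CDR3"]
            assert lys.cdr3_lysines == rec.aa_seq[s:e].count("K")
            assert lys.total == rec.aa_seq.count("K")

    def test_missing_cdr3_annotation_errors(self):
        rec = NanobodyRecord("x", "ATG" * 40, aa_seq="M" * 40, frame_offset=0)
        with pytest.raises(ValueError, match="CDR3"):
            count_lysines(rec)

    @pytest.mark.parametrize(
        "cdr3_k,non_cdr3_k,comparator,expected",
        [
            (0, 5, "at_least", True),   # comfortably labelable
            (0, 3, "at_least", True),   # boundary framework count accepted
            (0, 3, "strict_greater", False),
            (1, 9, "at_least", False),  # any CDR3 lysine disqualifies
            (0, 2, "at_least", False),
        ],
    )
    def test_selection_rule(self, cdr3_k, non_cdr3_k, comparator, expected):
        aa = "A" * 10 + "K" * non_cdr3_k + "A" * 10 + "K" * cdr3_k + "A" * 5
        cdr3 = (20 + non_cdr3_k, 20 + non_cdr3_k + cdr3_k)
        rec = NanobodyRecord("x", "ATG" * len(aa), aa_seq=aa, frame_offset=0,
                             regions={"CDR3": cdr3})
        crit = SelectionCriteria(comparator=comparator)
        assert (rec in select_candidates([rec], crit)) is expected


class TestSummaries:
    def test_gene_usage_matches_generator_tally(self, germline_set):
        weights = {"IGHV3S66": 0.7, "IGHV3S53": 0.3}
        recs, truth = synthetic.gen_repertoire(
            germline_set, n=60, mutation_rate=0.02, seed=9, v_weights=weights)
        for rec in recs:
            annotate(rec, germline_set)
        usage = gene_usage(recs)
        tally = pd.Series([t["v_gene"] for t in truth.data["clones"].values()]).value_counts()
        v_rows = usage[usage.segment == "V"].set_index("gene")
        for gene, count in tally.items():
            assert v_rows.loc[gene, "count"] == count
        for seg in ("V", "J"):
            pct = usage[usage.segment == seg]["percent"].sum()
            assert pct == pytest.approx(100.0, abs=0.2)

    def test_mutation_summary_single_clone(self):
        rec = NanobodyRecord("x", "ATG" * 40, aa_seq="M" * 40, frame_offset=0)
        rec.germline = GermlineCall("V", "J", None, 95.0, 10, 4)
        summ = mutation_summary([rec])
        assert summ["nt_mutations"] == {"mean": 10.0, "min": 10, "max": 10}
        assert summ["aa_changes"]["mean"] == 4.0

    def test_mutation_summary_empty_errors(self):
        with pytest.raises(ValueError):
            mutation_summary([])


def _record(cid: str, aa: str) -> NanobodyRecord:
    return NanobodyRecord(cid, "ATG" * len(aa), aa_seq=aa, frame_offset=0)


class TestIdentityAndCladogram:
    def test_matrix_symmetric_diag_100(self, germline_set):
        recs, _ = synthetic.gen_repertoire(germline_set, n=5, mutation_rate=0.08, seed=3)
        m = identity_matrix(recs)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 100.0)
        assert ((m.values >= 0) & (m.values <= 100)).all()

    def test_identical_pair_full_identity_zero_branch(self):
        recs = [_record("a", "MKVLQESGGG"), _record("b", "MKVLQESGGG"), _record("c", "MTTTTESGGG")]
        m = identity_matrix(recs)
        assert m.loc["a", "b"] == 100.0
        tree = build_cladogram(m)
        dists = tree.tip_tip_distances(["a", "b"])
        assert dists[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_nj_reproduces_additive_four_leaf_matrix(self):
        """NJ patristic distances must match any additive 4x4 input exactly.

        Oracle: the planted tree ((a:2,b:3):1,(c:4,d:5)) gives the additive
        distances below by path summation.
        """
        dist = pd.DataFrame(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float)
        tree = build_cladogram(100.0 - dist)
        tips = list("abcd")
        obs = tree.tip_tip_distances(tips)
        for i, a in enumerate(tips):
            for j, b in enumerate(tips):
                assert obs[i, j] == pytest.approx(dist.loc[a, b], abs=1e-9)

    def test_cladogram_needs_three_leaves(self):
        m = pd.DataFrame([[100.0, 90.0], [90.0, 100.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            build_cladogram(m)

    def test_newick_roundtrip(self, germline_set):
        from skbio.tree import TreeNode

        recs, _ = synthetic.gen_repertoire(germline_set, n=4, mutation_rate=0.08, seed=6)
        tree = build_cladogram(identity_matrix(recs))
        reparsed = TreeNode.read([str(tree)])
        assert sorted(t.name for t in reparsed.tips()) == sorted(t.name for t in tree.tips())
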