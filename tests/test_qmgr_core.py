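"""RS/RF scoring: worked examples, brute-force oracle agreement, RF tables."""

import itertools
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgrquant import (
    TYPICAL_NEOBATRACHIAN,
    TYPICAL_VERTEBRATE,
    GeneOrder,
    ReferenceArrangement,
    conserved_segments,
    gene_scores,
    neighbor_context,
    rf_table,
    score_gene,
    score_genome,
)


# --- independent oracle ------------------------------------------------------

def oracle_genome_rs(tokens, ref_tokens, mode="ordered"):
    """Brute-force RS: materialize every (gene, left, right) triple of both
    the observed order and the reference, compare flank by flank."""
    n, m = len(tokens), len(ref_tokens)
    ref_flanks = {g: (ref_tokens[i - 1], ref_tokens[(i + 1) % m])
                  for i, g in enumerate(ref_tokens)}
    total = 0
    for i, g in enumerate(tokens):
        left, right = tokens[(i - 1) % n], tokens[(i + 1) % n]
        ref_left, ref_right = ref_flanks[g]
        if mode == "ordered":
            total += int(left != ref_left) + int(right != ref_right)
        else:
            diff = Counter([left, right]) - Counter([ref_left, ref_right])
            total += sum(diff.values())
    return total


TOY_REF = ReferenceArrangement(
    "toy", GeneOrder.from_tokens("toy", ["a", "b", "c", "d", "e"], alphabet=None)
)


def toy_order(tokens):
    return GeneOrder.from_tokens("t", tokens, alphabet=None)


# --- neighbour context -------------------------------------------------------

class TestNeighborContext:
    def test_trnF_sits_between_cr_and_rrns(self):
        order = TYPICAL_VERTEBRATE.order
        pos = order.labels().index("F")
        assert neighbor_context(order, pos) == ("CR", "rrnS")

    def test_two_element_circle(self):
        order = toy_order(["a", "b"])
        assert neighbor_context(order, 0) == ("b", "b")

    def test_first_copy_of_tandem_duplicate(self, tandem_dup_order):
        order = tandem_dup_order("T")
        pos = order.labels().index("T")
        assert neighbor_context(order, pos) == ("cob", "T")

    def test_position_out_of_range(self):
        with pytest.raises(IndexError):
            neighbor_context(toy_order(["a", "b"]), 5)


# --- worked scoring examples -------------------------------------------------

class TestScoreGene:
    @pytest.mark.parametrize("mode", ["ordered", "unordered"])
    def test_reference_scored_against_itself_is_zero(self, mode):
        for pos in range(len(TYPICAL_VERTEBRATE.order)):
            assert score_gene(TYPICAL_VERTEBRATE.order, pos,
                              TYPICAL_VERTEBRATE, mode).rs == 0

    @pytest.mark.parametrize("mode", ["ordered", "unordered"])
    def test_tandem_duplicate_copies_each_score_one(self, tandem_dup_order, mode):
        order = tandem_dup_order("T")
        first = order.labels().index("T")
        s1 = score_gene(order, first, TYPICAL_VERTEBRATE, mode)
        s2 = score_gene(order, first + 1, TYPICAL_VERTEBRATE, mode)
        assert (s1.rs, s2.rs) == (1, 1)
        if mode == "ordered":
            assert (s1.left_changed, s1.right_changed) == (0, 1)
            assert (s2.left_changed, s2.right_changed) == (1, 0)

    def test_relocated_L2_scores_two(self):
        # L2 moved 3' of the CR: both flanks differ from its reference S2/nad5
        order = TYPICAL_NEOBATRACHIAN.order
        pos = order.labels().index("L2")
        score = score_gene(order, pos, TYPICAL_VERTEBRATE)
        assert score.rs == 2


class TestScoreGenome:
    @pytest.mark.parametrize("mode", ["ordered", "unordered"])
    def test_identity_scores_zero(self, mode):
        gs = score_genome(TYPICAL_VERTEBRATE.order, TYPICAL_VERTEBRATE, mode)
        assert (gs.rs, gs.n_rearranged_genes, gs.n_rearranged_labels) == (0, 0, 0)

    @pytest.mark.parametrize("gene", ["T", "P"])
    @pytest.mark.parametrize("mode", ["ordered", "unordered"])
    def test_tandem_duplication_scores_two_one_label(self, tandem_dup_order, gene, mode):
        gs = score_genome(tandem_dup_order(gene), TYPICAL_VERTEBRATE, mode)
        assert gs.rs == 2
        assert gs.n_rearranged_genes == 2       # two scored occurrences
        assert gs.n_rearranged_labels == 1      # but a single rearranged gene

    @pytest.mark.parametrize("mode", ["ordered", "unordered"])
    def test_neobatrachian_vs_vertebrate_scores_ten(self, mode):
        order = TYPICAL_NEOBATRACHIAN.order
        assert score_genome(order, TYPICAL_VERTEBRATE, mode).rs == 10
        assert oracle_genome_rs(order.labels(), TYPICAL_VERTEBRATE.labels(), mode) == 10
        contributions = {s.label: s.rs
                         for s in gene_scores(order, TYPICAL_VERTEBRATE, mode) if s.rs}
        assert contributions == {"S2": 1, "L2": 2, "nad5": 1, "cob": 1,
                                 "CR": 2, "T": 1, "P": 1, "F": 1}

    def test_lost_gene_scores_through_surviving_neighbours(self):
        tokens = [t for t in TYPICAL_VERTEBRATE.labels() if t != "F"]
        gs = score_genome(GeneOrder.from_tokens("noF", tokens), TYPICAL_VERTEBRATE)
        # CR right flank and rrnS left flank both changed; F contributes nothing
        assert gs.rs == 2
        assert {s.label for s in gene_scores(
            GeneOrder.from_tokens("noF", tokens), TYPICAL_VERTEBRATE) if s.rs} == {"CR", "rrnS"}


class TestOracleEquivalence:
    def test_all_orders_up_to_length_7_over_toy_alphabet(self):
        """Exhaustive agreement with the brute-force flank oracle."""
        letters = ("a", "b", "c", "d", "e")
        ref_tokens = TOY_REF.labels()
        for length in range(2, 8):
            for tokens in itertools.product(letters, repeat=length):
                order = toy_order(list(tokens))
                for mode in ("ordered", "unordered"):
                    assert score_genome(order, TOY_REF, mode).rs == \
                        oracle_genome_rs(tokens, ref_tokens, mode), (tokens, mode)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from("abcde"), min_size=2, max_size=30))
    def test_bounds_and_mode_dominance(self, tokens):
        order = toy_order(tokens)
        ordered = score_genome(order, TOY_REF, "ordered").rs
        unordered = score_genome(order, TOY_REF, "unordered").rs
        assert 0 <= unordered <= ordered <= 2 * len(tokens)


# --- RF tables ---------------------------------------------------------------

class TestRFTable:
    def test_identical_reference_genomes_have_zero_rf(self):
        orders = [GeneOrder.from_tokens(f"sp{i}", TYPICAL_VERTEBRATE.labels(),
                                        taxon=("Anura", "Ranidae")) for i in range(4)]
        (table,) = rf_table(orders, TYPICAL_VERTEBRATE)
        assert all(rf == 0.0 for _, _, rf in table.rows.values())

    def test_tandem_duplication_rf_arithmetic(self, tandem_dup_order):
        ref_genome = GeneOrder.from_tokens("typ", TYPICAL_VERTEBRATE.labels(),
                                           taxon=("TestOrder", "TestFam"))
        (table,) = rf_table([ref_genome, tandem_dup_order("T")], TYPICAL_VERTEBRATE)
        # 3 T occurrences over the group, accumulated RS 2 -> 100*2/6
        acc, cnt, rf = table.rows["T"]
        assert (acc, cnt) == (2, 3)
        assert rf == pytest.approx(100 * 2 / 6)
        assert round(rf, 2) == 33.33
        assert all(table.rows[g][2] == 0.0 for g in table.rows if g != "T")

    def test_rf_of_absent_gene_is_missing_not_zero(self):
        tokens = [t for t in TYPICAL_VERTEBRATE.labels() if t != "F"]
        orders = [GeneOrder.from_tokens("noF", tokens, taxon=("A",))]
        (table,) = rf_table(orders, TYPICAL_VERTEBRATE)
        assert table.rows["F"][2] is None

    def test_45_percent_changed_cr_flanks_give_rf_45(self):
        """A group where ~45% of CR flank slots changed reports RF(CR) ~ 45."""
        vert = list(TYPICAL_VERTEBRATE.labels())
        moved = list(vert)
        moved.remove("CR")
        moved.insert(moved.index("A"), "CR")  # both CR flanks changed: rs 2
        dup = list(vert)
        dup.insert(dup.index("CR") + 1, "CR")  # second CR copy: rs 1 (left ok? no)
        orders = []
        n_moved = 9  # 9 genomes with rs(CR)=2, 11 typical: 18/40 = 45%
        for i in range(n_moved):
            orders.append(GeneOrder.from_tokens(f"m{i}", moved, taxon=("A",)))
        for i in range(11):
            orders.append(GeneOrder.from_tokens(f"t{i}", vert, taxon=("A",)))
        (table,) = rf_table(orders, TYPICAL_VERTEBRATE)
        acc, cnt, rf = table.rows["CR"]
        assert (acc, cnt) == (18, 20)
        assert rf == pytest.approx(45.0)

    def test_grouping_by_taxon_rank(self, tandem_dup_order):
        a = GeneOrder.from_tokens("a", TYPICAL_VERTEBRATE.labels(), taxon=("Anura", "F1"))
        b = tandem_dup_order("T", species_id="b")  # taxon TestOrder
        tables = rf_table([a, b], TYPICAL_VERTEBRATE, group_by="order")
        groups = {t.group for t in tables}
        assert groups == {"Anura", "TestOrder"}


class TestConservedSegments:
    def _table_with_zeros(self, zero_genes):
        orders = [GeneOrder.from_tokens("sp", TYPICAL_VERTEBRATE.labels())]
        (table,) = rf_table(orders, TYPICAL_VERTEBRATE)
        for gene in table.rows:
            acc, cnt, _ = table.rows[gene]
            table.rows[gene] = (acc, cnt, 0.0 if gene in zero_genes else 5.0)
        return table

    def test_all_zero_rf_yields_whole_circle(self):
        orders = [GeneOrder.from_tokens("sp", TYPICAL_VERTEBRATE.labels())]
        (table,) = rf_table(orders, TYPICAL_VERTEBRATE)
        (segment,) = conserved_segments(table, TYPICAL_VERTEBRATE)
        assert segment == TYPICAL_VERTEBRATE.labels()

    def test_recovers_the_two_known_conserved_segments(self):
        zeros = {"atp6", "cox3", "G", "nad3", "R", "nad4L", "S1", "D"}
        segments = conserved_segments(self._table_with_zeros(zeros), TYPICAL_VERTEBRATE)
        assert segments == [("atp6", "cox3", "G", "nad3", "R", "nad4L"), ("S1", "D")]

    def test_isolated_zero_gene_is_not_a_segment(self):
        segments = conserved_segments(self._table_with_zeros({"G"}), TYPICAL_VERTEBRATE)
        assert segments == []

    def test_runs_may_wrap_around_the_origin(self):
        # CR (last) and F (first) zero together form one circular run
        segments = conserved_segments(self._table_with_zeros({"CR", "F"}), TYPICAL_VERTEBRATE)
        assert segments == [("CR", "F")]
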