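"""Grouped-MSA screening, p-distances and neighbor-joining trees."""

import random

import numpy as np
import pytest

from coldlocus.errors import GroupingError, MatrixError, UndefinedDistanceError
from coldlocus.msacomp import (
    GroupedAlignment,
    convergent_sequons,
    distance_matrix,
    nj_tree,
    p_distance,
    screen_specific_columns,
    to_newick,
    tree_splits,
)
from coldlocus.synthgen import MsaSpec, make_msa

from oracles import AdditiveTree, p_distance_oracle


def _aln(seqs, labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return GroupedAlignment(ids, seqs, labels)


def test_alignment_validation():
    with pytest.raises(GroupingError):
        _aln(["AA", "A"], ["focal", "outgroup"])
    with pytest.raises(GroupingError):
        _aln(["AA", "AA"], ["outgroup", "outgroup"])
    with pytest.raises(GroupingError):
        _aln(["AA", "AA"], ["focal", "focal"])


def test_focal_specific_column_with_sequon_candidate():
    aln = _aln(
        ["NAS", "NAS", "NAS", "SAS", "TAS"],
        ["focal", "focal", "focal", "outgroup", "outgroup"],
    )
    (col,) = screen_specific_columns(aln)
    assert col.column == 0
    assert col.classification == "focal_specific"
    assert col.focal_residue == "N"
    assert col.other_residues == frozenset("ST")
    assert col.creates_sequon
    assert not col.charge_change


def test_within_focal_disagreement_is_not_specific():
    aln = _aln(
        ["NAA", "NAA", "DAA", "SAA"],
        ["focal", "focal", "focal", "outgroup"],
    )
    assert screen_specific_columns(aln) == []


def test_charge_change_flagged_against_majority_nonfocal_residue():
    aln = _aln(
        ["KAA", "KAA", "SAA", "SAA", "DAA"],
        ["focal", "focal", "outgroup", "outgroup", "outgroup"],
    )
    (col,) = screen_specific_columns(aln)
    assert col.charge_change  # K (positive) vs majority S (neutral)


def test_focal_sister_shared_classification():
    aln = _aln(
        ["EAA", "EAA", "EAA", "QAA", "QAA"],
        ["focal", "focal", "sister", "outgroup", "outgroup"],
    )
    (col,) = screen_specific_columns(aln)
    assert col.classification == "focal_sister_shared"
    assert col.focal_residue == "E"


def test_all_nonfocal_gap_column_excluded():
    aln = _aln(["KA", "KA", "-A"], ["focal", "focal", "outgroup"])
    assert screen_specific_columns(aln) == []


def test_focal_coverage_rule_controls_gapped_focal_columns():
    aln = _aln(
        ["KA", "-A", "SA", "TA"],
        ["focal", "focal", "outgroup", "outgroup"],
    )
    assert screen_specific_columns(aln, min_focal_coverage=1.0) == []
    (col,) = screen_specific_columns(aln, min_focal_coverage=0.5)
    assert col.column == 0 and col.focal_residue == "K"


def test_screen_invariant_to_sequence_order():
    msa = make_msa(MsaSpec(seed=5))
    aln = msa.alignment
    perm = list(range(len(aln.ids)))
    random.Random(1).shuffle(perm)
    shuffled = GroupedAlignment(
        [aln.ids[i] for i in perm],
        [aln.sequences[i] for i in perm],
        [aln.labels[i] for i in perm],
    )
    key = lambda cols: sorted((c.column, c.classification, c.focal_residue) for c in cols)
    assert key(screen_specific_columns(shuffled)) == key(screen_specific_columns(aln))


def test_convergent_sequons_single_shared_site():
    aln = _aln(
        ["ANISA", "ANISA", "AQGQA"],
        ["focal", "focal", "outgroup"],
    )
    (site,) = convergent_sequons(aln)
    assert site.columns == (1,)
    assert (site.focal_carriers, site.focal_total) == (2, 2)
    assert site.other_carriers == 0


def test_convergent_sequons_maps_through_gaps():
    # sequon NIS is split by an alignment gap; Asn maps to column 1
    aln = _aln(
        ["AN-ISA", "AN-ISA", "AQ-GQA"],
        ["focal", "focal", "outgroup"],
    )
    (site,) = convergent_sequons(aln)
    assert site.columns == (1,)
    assert site.focal_carriers == 2


def test_alternative_asn_placements_merge_into_one_site():
    msa = make_msa(MsaSpec(seed=2))
    truth = msa.plant_log["sequon_site"]
    sites = [
        s for s in convergent_sequons(msa.alignment) if s.columns[0] in truth["columns"]
    ]
    assert len(sites) == 1
    assert sites[0].columns == tuple(truth["columns"])
    assert sites[0].focal_carriers == len(truth["carriers"])
    assert sites[0].other_carriers == 0


@pytest.mark.parametrize(
    "a,b,expected", [("AAA", "AAT", 1 / 3), ("A-A", "ABA", 0.0), ("AB", "AB", 0.0)]
)
def test_p_distance_examples(a, b, expected):
    assert p_distance(a, b) == pytest.approx(expected)


def test_p_distance_undefined_without_comparable_sites():
    with pytest.raises(UndefinedDistanceError):
        p_distance("A-", "-A")


def test_p_distance_matches_columnwise_oracle():
    rng = random.Random(9)
    for _ in range(20):
        n = rng.randrange(5, 60)
        a = "".join(rng.choice("ACDE-") for _ in range(n))
        b = "".join(rng.choice("ACDE-") for _ in range(n))
        try:
            expected = p_distance_oracle(a, b)
        except ZeroDivisionError:
            continue
        assert p_distance(a, b) == pytest.approx(expected)


def test_nj_three_taxa_closed_form_branch_lengths():
    d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
    tree = nj_tree(d, ["A", "B", "C"])
    # three-point formulas: a = (dAB+dAC-dBC)/2 = 1, b = 2, c = 4
    dist = {t.name: tree.find(t.name).accumulate_to_ancestor(tree) for t in tree.tips()}
    total = {(x, y): tree.find(x).distance(tree.find(y)) for x, y in [("A", "B"), ("A", "C"), ("B", "C")]}
    assert total[("A", "B")] == pytest.approx(3)
    assert total[("A", "C")] == pytest.approx(5)
    assert total[("B", "C")] == pytest.approx(6)


def test_nj_recovers_four_taxon_split():
    ids = ["A", "B", "C", "D"]
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = nj_tree(d, ids)
    assert tree_splits(tree) == {frozenset({"A", "B"})}
    for x, y, expected in [("A", "B", 3), ("A", "C", 5), ("B", "D", 7), ("C", "D", 7)]:
        assert tree.find(x).distance(tree.find(y)) == pytest.approx(expected)


def test_nj_exact_on_random_additive_trees():
    rng = random.Random(13)
    for _ in range(10):
        n = rng.randrange(4, 13)
        names = [f"t{i:02d}" for i in range(n)]
        truth = AdditiveTree(names, rng)
        d, ids = truth.distances()
        tree = nj_tree(np.array(d), ids)
        assert tree_splits(tree) == truth.splits()


def test_nj_invariant_to_taxon_input_order():
    rng = random.Random(21)
    truth = AdditiveTree([f"t{i}" for i in range(8)], rng)
    d, ids = truth.distances()
    d = np.array(d)
    perm = list(range(8))
    rng.shuffle(perm)
    t1 = nj_tree(d, ids)
    t2 = nj_tree(d[np.ix_(perm, perm)], [ids[i] for i in perm])
    assert tree_splits(t1) == tree_splits(t2)
    assert to_newick(t1) == to_newick(t2)


def test_nj_rejects_asymmetric_matrix_and_tiny_inputs():
    with pytest.raises(MatrixError):
        nj_tree(np.array([[0, 1, 2], [1.1, 0, 1], [2, 1, 0]]), ["a", "b", "c"])
    with pytest.raises(MatrixError):
        nj_tree(np.zeros((2, 2)), ["a", "b"])


def test_focal_clade_monophyletic_on_synthetic_alignment():
    msa = make_msa(MsaSpec(seed=4))
    d, ids = distance_matrix(msa.alignment)
    tree = nj_tree(d, ids)
    focal = frozenset(i for i, lab in zip(ids, msa.alignment.labels) if lab == "focal")
    all_ids = frozenset(ids)
    split = min(focal, all_ids - focal, key=sorted)
    assert split in tree_splits(tree)
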