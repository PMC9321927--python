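"""Grouped multiple-sequence-alignment analytics.

Sequences carry one of three group labels: ``focal`` (the clade under study,
here the cold-adapted Antarctic lineage), ``sister`` (its closest temperate
relative) and ``outgroup`` (everything else).  The screen reports alignment
columns where the focal clade fixed a residue found in no other sequence,
columns shared by focal+sister but absent from the outgroup, charge-change
annotation, convergent sequon gains, p-distances and a neighbor-joining tree.
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .errors import GroupingError, MatrixError, UndefinedDistanceError
from .protfeat import charge_class, scan_sequons

log = logging.getLogger(__name__)

GAP = "-"
GROUPS = ("focal", "sister", "outgroup")


@dataclass
class GroupedAlignment:
    ids: list[str]
    sequences: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.sequences) == len(self.labels)):
            raise GroupingError("ids, sequences and labels must align")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise GroupingError(f"aligned sequences of unequal length: {sorted(lengths)}")
        bad = set(self.labels) - set(GROUPS)
        if bad:
            raise GroupingError(f"unknown group labels: {sorted(bad)}")
        if "focal" not in self.labels:
            raise GroupingError("alignment has no focal sequences")
        if all(lab == "focal" for lab in self.labels):
            raise GroupingError("alignment has no non-focal sequences")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def indices(self, *groups: str) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab in groups]

    @classmethod
    def from_files(cls, alignment_fasta, groups_tsv) -> "GroupedAlignment":
        """Aligned FASTA plus a TSV with columns id, group."""
        if hasattr(alignment_fasta, "read"):
            handle = alignment_fasta
        else:
            handle = io.StringIO(
                alignment_fasta
                if "\n" in str(alignment_fasta)
                else open(alignment_fasta).read()
            )
        records = list(SeqIO.parse(handle, "fasta"))
        table = pd.read_csv(groups_tsv, sep="\t")
        mapping = dict(zip(table["id"].astype(str), table["group"]))
        ids = [r.id for r in records]
        missing = [i for i in ids if i not in mapping]
        if missing:
            raise GroupingError(f"no group label for: {missing}")
        return cls(ids, [str(r.seq) for r in records], [mapping[i] for i in ids])


@dataclass(frozen=True)
class SpecificColumn:
    column: int  # 0-based alignment column
    focal_residue: str
    other_residues: frozenset[str]
    classification: str  # focal_specific | focal_sister_shared
    charge_change: bool
    creates_sequon: bool


def _column(aln: GroupedAlignment, col: int, idx: Sequence[int]) -> list[str]:
    return [aln.sequences[i][col] for i in idx]


def _consensus_if_unanimous(residues: Sequence[str]) -> str | None:
    present = [r for r in residues if r != GAP]
    if not present:
        return None
    return present[0] if len(set(present)) == 1 else None


def _sequon_at(aln: GroupedAlignment, seq_idx: int, col: int) -> bool:
    """Valid sequon whose Asn sits at this alignment column (ungapped context)."""
    seq = aln.sequences[seq_idx]
    if seq[col] != "N":
        return False
    rest = [c for c in seq[col + 1 :] if c != GAP][:2]
    if len(rest) < 2:
        return False
    return rest[0] != "P" and rest[1] in "ST"


def screen_specific_columns(
    aln: GroupedAlignment,
    min_focal_coverage: float = 1.0,
    include_histidine_charge: bool = False,
) -> list[SpecificColumn]:
    """Columns where the focal clade (or focal+sister) fixed a private residue.

    A column is ``focal_specific`` when every focal sequence covering it
    (non-gap) shows one identical residue, focal coverage is at least
    ``min_focal_coverage`` (fraction of focal sequences that are non-gap),
    and that residue appears in no covering non-focal sequence.
    ``focal_sister_shared`` is defined analogously for focal+sister versus the
    outgroup.  Columns where all non-focal sequences are gapped are excluded
    (logged).  ``charge_change`` compares the focal residue with the majority
    residue of the covering non-focal sequences; ``creates_sequon`` flags
    columns whose private residue is an Asn forming a valid sequon in at
    least one focal sequence and in no covering non-focal sequence.
    """
    focal_idx = aln.indices("focal")
    sister_idx = aln.indices("sister")
    outgroup_idx = aln.indices("outgroup")
    nonfocal_idx = sister_idx + outgroup_idx
    out: list[SpecificColumn] = []
    for col in range(aln.length):
        nonfocal = _column(aln, col, nonfocal_idx)
        nonfocal_present = [r for r in nonfocal if r != GAP]
        if not nonfocal_present:
            log.info("column %d: all non-focal sequences gapped; excluded", col)
            continue
        classification = None
        focal = _column(aln, col, focal_idx)
        focal_res = _consensus_if_unanimous(focal)
        coverage = sum(r != GAP for r in focal) / len(focal)
        if (
            focal_res is not None
            and coverage >= min_focal_coverage
            and focal_res not in nonfocal_present
        ):
            classification = "focal_specific"
            other = frozenset(nonfocal_present)
            contrast_idx = nonfocal_idx
        else:
            # focal+sister vs outgroup
            fs_idx = focal_idx + sister_idx
            fs = _column(aln, col, fs_idx)
            fs_res = _consensus_if_unanimous(fs)
            fs_cov = sum(r != GAP for r in fs) / len(fs)
            outg = [r for r in _column(aln, col, outgroup_idx) if r != GAP]
            if (
                fs_res is not None
                and fs_cov >= min_focal_coverage
                and outg
                and fs_res not in outg
            ):
                classification = "focal_sister_shared"
                focal_res = fs_res
                other = frozenset(outg)
                contrast_idx = outgroup_idx
        if classification is None:
            continue
        contrast = [r for r in _column(aln, col, contrast_idx) if r != GAP]
        majority = Counter(sorted(contrast)).most_common(1)[0][0]
        charge_change = charge_class(
            focal_res, include_histidine_charge
        ) != charge_class(majority, include_histidine_charge)
        creates_sequon = (
            focal_res == "N"
            and any(_sequon_at(aln, i, col) for i in focal_idx)
            and not any(_sequon_at(aln, i, col) for i in contrast_idx)
        )
        out.append(
            SpecificColumn(
                column=col,
                focal_residue=focal_res,
                other_residues=other,
                classification=classification,
                charge_change=charge_change,
                creates_sequon=creates_sequon,
            )
        )
    return out


@dataclass(frozen=True)
class SequonSite:
    columns: tuple[int, ...]  # alignment columns of the alternative Asn starts
    focal_carriers: int
    focal_total: int
    other_carriers: int
    other_total: int


def convergent_sequons(aln: GroupedAlignment, cluster_span: int = 2) -> list[SequonSite]:
    """Per-site sequon prevalence in focal vs non-focal sequences.

    Sequons are detected on each ungapped sequence and mapped back to
    alignment columns; start columns within ``cluster_span`` of each other
    are merged into one site (capturing alternative Asn placements spaced by
    a single residue).
    """
    focal_set = set(aln.indices("focal"))
    per_seq_cols: list[tuple[int, int]] = []  # (column, seq index)
    for i, seq in enumerate(aln.sequences):
        ungapped = seq.replace(GAP, "")
        col_of = [c for c, ch in enumerate(seq) if ch != GAP]
        for hit in scan_sequons(ungapped):
            per_seq_cols.append((col_of[hit.asn_position - 1], i))
    per_seq_cols.sort()
    sites: list[SequonSite] = []
    i = 0
    n_focal = len(focal_set)
    n_other = len(aln.ids) - n_focal
    while i < len(per_seq_cols):
        j = i
        while (
            j + 1 < len(per_seq_cols)
            and per_seq_cols[j + 1][0] - per_seq_cols[j][0] <= cluster_span
        ):
            j += 1
        members = per_seq_cols[i : j + 1]
        cols = tuple(sorted({c for c, _ in members}))
        carriers = {s for _, s in members}
        sites.append(
            SequonSite(
                columns=cols,
                focal_carriers=len(carriers & focal_set),
                focal_total=n_focal,
                other_carriers=len(carriers - focal_set),
                other_total=n_other,
            )
        )
        i = j + 1
    return sites


# ---------------------------------------------------------------------------
# distances and trees


def p_distance(a: str, b: str) -> float:
    """Mismatch fraction over sites without a gap in either sequence."""
    if len(a) != len(b):
        raise MatrixError("aligned sequences of unequal length")
    compared = mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == GAP or y == GAP:
            continue
        compared += 1
        mismatches += x != y
    if compared == 0:
        raise UndefinedDistanceError("no comparable (gap-free) sites")
    return mismatches / compared


def distance_matrix(aln: GroupedAlignment) -> tuple[np.ndarray, list[str]]:
    """Symmetric p-distance matrix over all sequences."""
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(aln.sequences[i], aln.sequences[j])
    return d, list(aln.ids)


def nj_tree(d: np.ndarray, ids: Sequence[str]):
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix.

    Taxa are canonicalised to lexicographic id order before joining, making
    the result deterministic and invariant to input order; negative branch
    lengths are clamped to zero (logged).  Returns an skbio TreeNode.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (len(ids), len(ids)):
        raise MatrixError("matrix shape does not match ids")
    if len(ids) < 3:
        raise MatrixError("neighbor joining needs at least 3 taxa")
    if np.max(np.abs(d - d.T)) > 1e-9:
        raise MatrixError("distance matrix asymmetric beyond 1e-9")
    order = np.argsort(np.asarray(ids, dtype=object))
    ids_sorted = [ids[i] for i in order]
    d_sorted = (d + d.T)[np.ix_(order, order)] / 2.0
    np.fill_diagonal(d_sorted, 0.0)
    tree = _skbio_nj(DistanceMatrix(d_sorted, ids=ids_sorted), neg_as_zero=True)
    return tree


def to_newick(tree) -> str:
    out = io.StringIO()
    tree.write(out, format="newick")
    return out.getvalue().strip()


def tree_splits(tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as leaf-name sets on one side) of a tree."""
    all_leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(min(side, all_leaves - side, key=sorted))
    return splits
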