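"""Seeded synthetic-data generators with ground-truth plant logs.

Three generators emulate the statistical structure the pipeline assumes:

* :func:`make_locus` — a multi-exon gene on a scaffold with an AT-rich i.i.d.
  background, an optionally planted CpG-rich island upstream of the gene,
  planted motif copies (either strand, with mismatches) and planted PAS
  hexamers.  Every planted feature is logged with exact coordinates.
* :func:`make_msa` — a grouped protein alignment (focal / sister / outgroup)
  with planted clade-specific columns, shared focal+sister columns, a
  convergent sequon site with alternative Asn placements, and i.i.d.
  background substitutions.  Background columns never contain Asn or Cys, so
  sequon and cysteine features are fully controlled by the plants.
* :func:`make_cq` — a qPCR Cq table with per-tissue true dCq means, a
  per-specimen offset applied equally to both genes (cancelling in dCq) and
  Gaussian technical-replicate noise.

Additionally, :func:`synthetic_pigr_cdna` and :func:`synthetic_pigr_locus`
build a fixed, deterministic transcript/locus pair whose design parameters
are the published anatomy of the Antarctic polymeric-Ig-receptor gene: a
1414-nt cDNA (38-nt 5' UTR, 1017-nt CDS, 359-nt 3' UTR) with a canonical
poly(A) signal at 1387 and a non-canonical one at 1395, a 338-aa precursor
(21-aa signal peptide; IgV-type D1/D2 with canonical cysteines spaced 68 and
62 plus nested small pairs spaced 7; a 39-aa proline-rich basic EMPD; a
20-aa leucine-rich TM; a 51-aa cytoplasmic tail) carrying exactly four
N-glycosylation sequons, and an eight-exon genomic locus of 8310 nt total
span.  These are synthetic stand-ins for the real accessions, not the real
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SpecError
from .locus_io import GeneModel, GenomicInterval, write_gene_model_gff3
from .msacomp import GroupedAlignment
from .nucfeat import obs_exp_cpg, gc_content, revcomp

AA_BACKGROUND = "ADEFGHIKLMPQRSTVWY"  # no N (sequons) and no C (bridges)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


# ---------------------------------------------------------------------------
# locus generator


@dataclass(frozen=True)
class MotifPlant:
    position: int  # 0-based start on the scaffold forward strand
    strand: str
    mismatches: int


@dataclass
class LocusSpec:
    """Layout of a synthetic gene locus.

    Defaults reproduce the published profile of the Antarctic *pIgR* gene:
    eight exons whose genomic span is 8310 nt and the published seven intron
    lengths.  ``cgi_length``/``cgi_obs_exp`` control the planted island,
    placed ``cgi_upstream_offset`` nt upstream of the gene start (the
    published islands are 210-348 nt, Obs/Exp 1.35-1.50, ~500 nt upstream).
    """

    gene_id: str = "pigr_synth"
    scaffold_id: str = "scaffold_synth"
    exon_lengths: Sequence[int] = (245, 345, 82, 227, 88, 92, 50, 427)
    intron_lengths: Sequence[int] = (628, 2372, 548, 2825, 124, 146, 111)
    strand: str = "+"
    gc_background: float = 0.32
    flank5: int = 1200
    flank3: int = 400
    cgi_length: int | None = 300
    cgi_obs_exp: float = 1.4
    cgi_gc: float = 0.60
    cgi_upstream_offset: int = 500
    motif: str | None = "GATTACAGGCATCGTAGCTAGCCTTAGGACTGATCGGTACCATGGAATTC"
    motif_plants: Sequence[MotifPlant] | None = None  # None -> default 3 copies
    motif_intron: int = 3  # 1-based intron housing the default plants
    pas_in_intron: int | None = 4  # plant one AATAAA in this intron
    seed: int = 0


@dataclass
class SyntheticLocus:
    scaffold: str
    model: GeneModel
    gff3: str
    plant_log: dict


def _cgi_block(rng, length: int, target_obs_exp: float, gc: float) -> str:
    """CpG-dense block via seeded rejection sampling (Obs/Exp within 0.05)."""
    pi = min(0.45, target_obs_exp * gc * gc / 2.0)
    for _ in range(300):
        out = []
        while len(out) < length:
            if rng.random() < pi and len(out) < length - 1:
                out.extend("CG")
            else:
                out.append(_random_dna(rng, 1, gc))
        block = "".join(out[:length])
        ratio = obs_exp_cpg(block)
        if abs(ratio - target_obs_exp) <= 0.05 and gc_content(block) >= 0.5:
            return block
        pi = float(np.clip(pi * target_obs_exp / max(ratio, 1e-6), 0.01, 0.45))
    raise SpecError("could not realize CGI block at the requested Obs/Exp")


def make_locus(spec: LocusSpec) -> SyntheticLocus:
    """Build scaffold FASTA text, gene model/GFF3 and a plant log.

    Deterministic given ``spec.seed``; raises :class:`SpecError` when planted
    features overlap each other or fall outside the scaffold.
    """
    if len(spec.intron_lengths) != len(spec.exon_lengths) - 1:
        raise SpecError("introns must number exons - 1")
    rng = _rng(spec.seed)
    gene_len = sum(spec.exon_lengths) + sum(spec.intron_lengths)
    total = spec.flank5 + gene_len + spec.flank3
    scaffold = list(_random_dna(rng, total, spec.gc_background))

    # exon coordinates (genomic, plus strand layout)
    exons = []
    pos = spec.flank5
    intron_bounds = []
    for i, ex_len in enumerate(spec.exon_lengths):
        exons.append((pos, pos + ex_len))
        pos += ex_len
        if i < len(spec.intron_lengths):
            intron_bounds.append((pos, pos + spec.intron_lengths[i]))
            pos += spec.intron_lengths[i]
    gene_start, gene_end = exons[0][0], exons[-1][1]

    occupied: list[tuple[int, int, str]] = []

    def claim(start: int, end: int, what: str) -> None:
        if start < 0 or end > total:
            raise SpecError(f"{what} [{start},{end}) outside scaffold")
        for s, e, w in occupied:
            if start < e and s < end:
                raise SpecError(f"{what} overlaps {w}")
        occupied.append((start, end, what))

    log: dict = {"gene": (gene_start, gene_end), "exons": exons}

    if spec.cgi_length:
        cgi_start = gene_start - spec.cgi_upstream_offset - spec.cgi_length
        claim(cgi_start, cgi_start + spec.cgi_length, "CGI")
        block = _cgi_block(rng, spec.cgi_length, spec.cgi_obs_exp, spec.cgi_gc)
        scaffold[cgi_start : cgi_start + spec.cgi_length] = block
        log["cgi"] = {
            "start": cgi_start,
            "end": cgi_start + spec.cgi_length,
            "obs_exp": obs_exp_cpg(block),
            "gc": gc_content(block),
        }

    if spec.motif:
        plants = spec.motif_plants
        if plants is None:
            # default: tandem pair on + strand and one mismatched copy on -,
            # inside the designated intron
            ilo, ihi = intron_bounds[spec.motif_intron - 1]
            m = len(spec.motif)
            plants = (
                MotifPlant(ilo + 20, "+", 0),
                MotifPlant(ilo + 20 + m + 5, "+", 0),
                MotifPlant(ihi - m - 30, "-", 1),
            )
        planted = []
        for p in plants:
            m = spec.motif if p.strand == "+" else revcomp(spec.motif)
            m = list(m)
            mut_sites = rng.choice(len(m), size=p.mismatches, replace=False)
            for site in mut_sites:
                others = [b for b in "ACGT" if b != m[site]]
                m[site] = others[rng.integers(len(others))]
            claim(p.position, p.position + len(m), "motif")
            scaffold[p.position : p.position + len(m)] = m
            planted.append(p)
        log["motifs"] = {"motif": spec.motif, "plants": planted}

    if spec.pas_in_intron:
        ilo, ihi = intron_bounds[spec.pas_in_intron - 1]
        pas_pos = (ilo + ihi) // 2
        claim(pas_pos, pas_pos + 6, "PAS")
        scaffold[pas_pos : pas_pos + 6] = "AATAAA"
        log["pas"] = {"position": pas_pos}

    seq = "".join(scaffold)
    intervals = [
        GenomicInterval(spec.scaffold_id, s, e, spec.strand) for s, e in exons
    ]
    if spec.strand == "-":
        intervals = intervals[::-1]
    model = GeneModel(spec.gene_id, intervals)
    transcript = "".join(seq[s:e] for s, e in exons)
    if spec.strand == "-":
        transcript = revcomp(transcript)
    log["transcript"] = transcript
    return SyntheticLocus(
        scaffold=seq,
        model=model,
        gff3=write_gene_model_gff3(model),
        plant_log=log,
    )


# ---------------------------------------------------------------------------
# grouped-MSA generator


@dataclass
class MsaSpec:
    """Grouped alignment with planted clade-specific structure.

    Defaults mirror the published comparison: 12 Antarctic (focal)
    sequences, one temperate notothenioid sister, 26 perciform outgroup
    sequences over a 317-column mature-protein alignment (D1 108, linker 4,
    D2 95, EMPD 39, TM 20, CYT 51), with 20 planted focal-specific columns
    split 4/6/1/3/6 across D1/D2/EMPD/TM/CYT, two focal+sister shared
    columns, five charge-changing plants and one convergent sequon site in
    D2 carried by 9 of the 12 focal sequences.
    """

    n_focal: int = 12
    n_sister: int = 1
    n_outgroup: int = 26
    length: int = 317
    background_rate: float = 0.02
    n_specific_by_region: Sequence[int] = (4, 6, 1, 3, 6)  # D1, D2, EMPD, TM, CYT
    region_lengths: Sequence[int] = (108, 4, 95, 39, 20, 51)  # D1,link,D2,EMPD,TM,CYT
    n_shared: int = 2
    n_charge_plants: int = 5
    sequon_site: bool = True
    sequon_carriers: int = 9
    fragment_mask: Sequence[tuple[int, int, int]] = ()  # (seq index, start, end) gaps
    seed: int = 0


@dataclass
class SyntheticMsa:
    alignment: GroupedAlignment
    plant_log: dict


def _region_bounds(region_lengths: Sequence[int]) -> list[tuple[int, int]]:
    bounds, pos = [], 0
    for ln in region_lengths:
        bounds.append((pos, pos + ln))
        pos += ln
    return bounds


def make_msa(spec: MsaSpec) -> SyntheticMsa:
    """Build a grouped alignment realizing every planted definition exactly."""
    if sum(spec.region_lengths) != spec.length:
        raise SpecError("region lengths must sum to alignment length")
    rng = _rng(spec.seed)
    n_total = spec.n_focal + spec.n_sister + spec.n_outgroup
    ids = (
        [f"focal_{i:02d}" for i in range(spec.n_focal)]
        + [f"sister_{i:02d}" for i in range(spec.n_sister)]
        + [f"outgroup_{i:02d}" for i in range(spec.n_outgroup)]
    )
    labels = (
        ["focal"] * spec.n_focal
        + ["sister"] * spec.n_sister
        + ["outgroup"] * spec.n_outgroup
    )
    focal_rows = list(range(spec.n_focal))
    nonfocal_rows = list(range(spec.n_focal, n_total))
    outgroup_rows = list(range(spec.n_focal + spec.n_sister, n_total))

    consensus = rng.choice(list(AA_BACKGROUND), size=spec.length)
    msa = np.tile(consensus, (n_total, 1))

    # background substitutions (never to N/C, never at planted columns - the
    # plants overwrite their columns afterwards anyway)
    if spec.background_rate > 0:
        mask = rng.random(msa.shape) < spec.background_rate
        for i, j in zip(*np.nonzero(mask)):
            choices = [a for a in AA_BACKGROUND if a != msa[i, j]]
            msa[i, j] = choices[rng.integers(len(choices))]

    bounds = _region_bounds(spec.region_lengths)
    region_names = ("D1", "linker", "D2", "EMPD", "TM", "CYT")
    plantable_regions = {"D1": 0, "D2": 2, "EMPD": 3, "TM": 4, "CYT": 5}

    reserved: set[int] = set()
    sequon_cols: tuple[int, ...] = ()
    if spec.sequon_site:
        d2_lo, d2_hi = bounds[2]
        c = int(rng.integers(d2_lo + 2, d2_hi - 6))
        sequon_cols = (c, c + 2)
        reserved |= set(range(c - 1, c + 6))

    def draw_columns(region_idx: int, k: int) -> list[int]:
        lo, hi = bounds[region_idx]
        cols = []
        pool = [c for c in range(lo, hi) if c not in reserved]
        take = rng.choice(len(pool), size=k, replace=False)
        for t in take:
            cols.append(pool[int(t)])
            reserved.add(pool[int(t)])
        return cols

    charged, neutral = "KRDE", "AGQSTVLMF"
    planted = []
    charge_budget = spec.n_charge_plants
    for name, k in zip(("D1", "D2", "EMPD", "TM", "CYT"), spec.n_specific_by_region):
        for col in draw_columns(plantable_regions[name], k):
            make_charged = charge_budget > 0 and name in ("D1", "D2", "EMPD")
            if make_charged:
                charge_budget -= 1
                focal_res = charged[rng.integers(len(charged))]
                others = rng.choice(list(neutral), size=2, replace=False)
            else:
                pool = [a for a in neutral]
                pick = rng.choice(len(pool), size=3, replace=False)
                focal_res = pool[pick[0]]
                others = [pool[pick[1]], pool[pick[2]]]
            for row in focal_rows:
                msa[row, col] = focal_res
            for row in nonfocal_rows:
                msa[row, col] = others[rng.integers(len(others))]
            planted.append(
                {
                    "column": col,
                    "region": name,
                    "focal_residue": str(focal_res),
                    "other_residues": sorted(set(map(str, others))),
                    "charge_change": bool(make_charged),
                }
            )

    shared = []
    for _ in range(spec.n_shared):
        region = ("D1", "D2")[int(rng.integers(2))]
        col = draw_columns(plantable_regions[region], 1)[0]
        pool = list(neutral)
        pick = rng.choice(len(pool), size=2, replace=False)
        fs_res, out_res = pool[pick[0]], pool[pick[1]]
        for row in range(spec.n_focal + spec.n_sister):
            msa[row, col] = fs_res
        for row in outgroup_rows:
            msa[row, col] = out_res
        shared.append({"column": col, "region": region, "residue": str(fs_res)})

    carriers: list[int] = []
    if spec.sequon_site:
        c = sequon_cols[0]
        carriers = sorted(
            int(i) for i in rng.choice(spec.n_focal, size=spec.sequon_carriers, replace=False)
        )
        # site layout over columns c-1..c+5; non-carriers keep a sequon-free
        # pattern; carriers alternate the Asn between c and c+2
        for row in range(n_total):
            msa[row, c : c + 6] = list("QGTGAG")
        for k, row in enumerate(carriers):
            if k % 2 == 0:
                msa[row, c : c + 3] = list("NGT")
            else:
                msa[row, c + 2 : c + 5] = list("NGT")

    seqs = ["".join(r) for r in msa]
    for seq_idx, start, end in spec.fragment_mask:
        if not (0 <= start < end <= spec.length):
            raise SpecError("fragment mask outside alignment")
        s = list(seqs[seq_idx])
        s[start:end] = "-" * (end - start)
        seqs[seq_idx] = "".join(s)
    for p in planted:
        if all(seqs[row][p["column"]] == "-" for row in focal_rows):
            raise SpecError(
                f"fragment mask gaps every focal sequence at planted column {p['column']}"
            )

    aln = GroupedAlignment(ids, seqs, labels)
    log = {
        "planted_columns": planted,
        "shared_columns": shared,
        "sequon_site": {
            "columns": sequon_cols,
            "carriers": carriers,
        }
        if spec.sequon_site
        else None,
        "regions": dict(zip(region_names, bounds)),
    }
    return SyntheticMsa(alignment=aln, plant_log=log)


# ---------------------------------------------------------------------------
# Cq-table generator


@dataclass
class CqSpec:
    """qPCR design with per-tissue true dCq means.

    Default tissue folds (relative to the muscle calibrator) follow the
    published expression pattern: gills highest; the middle intestine 2.7x
    and 3.9x below the anterior and posterior segments; liver 3.9x and head
    kidney 10x below gills.  Three specimens in technical duplicate with
    0.2-cycle replicate noise mirror the published design.
    """

    tissue_folds: dict = field(
        default_factory=lambda: {
            "gills": 64.0,
            "anterior_intestine": 10.8,
            "middle_intestine": 4.0,
            "posterior_intestine": 15.6,
            "liver": 64.0 / 3.9,
            "head_kidney": 6.4,
            "muscle": 1.0,
        }
    )
    calibrator: str = "muscle"
    calibrator_dcq: float = 8.0
    reference_cq: float = 16.0
    n_specimens: int = 3
    n_replicates: int = 2
    noise_sd: float = 0.2
    specimen_sd: float = 0.3
    seed: int = 0

    def true_dcq(self, tissue: str) -> float:
        return self.calibrator_dcq - float(np.log2(self.tissue_folds[tissue]))


def make_cq(spec: CqSpec) -> pd.DataFrame:
    """Cq table (tissue, specimen, replicate, gene, cq), seeded and Gaussian."""
    if spec.calibrator not in spec.tissue_folds:
        raise SpecError("calibrator tissue missing from tissue_folds")
    if spec.noise_sd < 0:
        raise SpecError("noise SD must be non-negative")
    rng = _rng(spec.seed)
    rows = []
    offsets = rng.normal(0.0, spec.specimen_sd, size=spec.n_specimens)
    for s in range(spec.n_specimens):
        for tissue in spec.tissue_folds:
            dcq = spec.true_dcq(tissue)
            for rep in range(spec.n_replicates):
                ref = spec.reference_cq + offsets[s] + rng.normal(0, spec.noise_sd)
                tgt = (
                    spec.reference_cq
                    + dcq
                    + offsets[s]
                    + rng.normal(0, spec.noise_sd)
                )
                rows.append((tissue, f"specimen_{s}", rep + 1, "reference", ref))
                rows.append((tissue, f"specimen_{s}", rep + 1, "target", tgt))
    return pd.DataFrame(
        rows, columns=["tissue", "specimen", "replicate", "gene", "cq"]
    )


# ---------------------------------------------------------------------------
# fixed synthetic reference transcript / locus (published-anatomy stand-in)

_SP = "MKTLIALFLVLSAVQGALALP"


def _fill(length: int, special: dict[int, str], filler: str) -> str:
    fi = iter(filler * 20)
    out = []
    for pos in range(1, length + 1):
        if pos in special:
            out.append(special[pos])
        else:
            ch = next(fi)
            while ch in "CN":
                ch = next(fi)
            out.append(ch)
    return "".join(out)


_D1 = _fill(
    108,
    {24: "C", 40: "C", 48: "C", 93: "C", 70: "N", 71: "I", 72: "S"},
    "ADVVTQKPSVLEAKEGSTAVMGQLSKTVDAWFRGE",
)
_D2 = _fill(
    95,
    {15: "C", 78: "C", 30: "C", 38: "C", 50: "N", 51: "V", 52: "T"},
    "GQSLEVKAGDTVTLDAWFRGEPSKMVQHYLKAGE",
)
_LINKER = "VQAP"
_EMPD = "PRLLKQQPDSSKVVPGGPRQQKTTPSSPRGGKAAPETNI"
_TM = "TLFIVLCLIVALFGIVLFAL"
_CYT = _fill(51, {10: "N", 11: "A", 12: "S"}, "KVRQSLGKTAGRVQKSLGETAVRKQGLSTAVKRQGLE")

_CODON = {
    "A": "GCA", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGA",
    "H": "CAT", "I": "ATA", "K": "AAG", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCA", "T": "ACA", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_UTR5 = "AGCTGAGTGCGTGTCTGTGAGAGCTGGAGTCGGACGAC"[:38]
_UTR3_BASE = ("TGTCTGGACTGCAGGTCTGGTCACGTGGTCTGAGACTG" * 12)[:359]


@dataclass(frozen=True)
class ReferenceCdna:
    """Deterministic synthetic transcript with the published pIgR anatomy."""

    cdna: str
    protein: str
    cds_start: int  # 0-based on the cDNA
    cds_end: int
    regions: dict  # name -> (start, end), 1-based inclusive protein coords
    pas_canonical: int  # 1-based cDNA position
    pas_noncanonical: int


def synthetic_pigr_cdna() -> ReferenceCdna:
    """Build the synthetic reference transcript (always identical).

    The protein precursor is SP(21) + D1(108) + linker(4) + D2(95) +
    EMPD(39) + TM(20) + CYT(51) = 338 aa; the cDNA is a 38-nt 5' UTR, the
    1017-nt CDS (AT-leaning codons; isoleucine after asparagine uses ATT so
    no poly(A)-variant hexamer arises inside the CDS) and a 359-nt 3' UTR
    carrying AATAAA at cDNA position 1387 and ATTAAA at 1395.
    """
    protein = _SP + _D1 + _LINKER + _D2 + _EMPD + _TM + _CYT
    codons, prev = [], ""
    for aa in protein:
        c = _CODON[aa]
        if prev == "N" and aa == "I":
            c = "ATT"
        codons.append(c)
        prev = aa
    cds = "".join(codons) + "TAA"
    utr3 = list(_UTR3_BASE)
    utr3[331:337] = "AATAAA"
    utr3[339:345] = "ATTAAA"
    cdna = _UTR5 + cds + "".join(utr3)
    regions = {}
    pos = 1
    for name, seg in (
        ("SP", _SP), ("D1", _D1), ("linker", _LINKER), ("D2", _D2),
        ("EMPD", _EMPD), ("TM", _TM), ("CYT", _CYT),
    ):
        regions[name] = (pos, pos + len(seg) - 1)
        pos += len(seg)
    return ReferenceCdna(
        cdna=cdna,
        protein=protein,
        cds_start=38,
        cds_end=38 + len(cds),
        regions=regions,
        pas_canonical=1387,
        pas_noncanonical=1395,
    )


def synthetic_pigr_locus(seed: int = 0) -> SyntheticLocus:
    """Eight-exon synthetic locus with the published intron lengths.

    The genomic span (last exon end minus first exon start) is 8310 nt; the
    published exon components and the published total do not agree exactly,
    so the final exon is sized to the total (see docs).
    """
    return make_locus(LocusSpec(seed=seed))
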