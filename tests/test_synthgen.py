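"""Synthetic-data generators: determinism, plant logs, reference anatomy."""

import numpy as np
import pytest

from coldlocus import extract_introns, spliced_sequence
from coldlocus.errors import SpecError
from coldlocus.nucfeat import detect_cgi, scan_motif, scan_pas
from coldlocus.protfeat import (
    composition,
    cysteine_pattern,
    hydropathy_tm_scan,
    scan_sequons,
    theoretical_pi,
    translate,
)
from coldlocus.msacomp import screen_specific_columns
from coldlocus.synthgen import (
    CqSpec,
    LocusSpec,
    MotifPlant,
    MsaSpec,
    make_cq,
    make_locus,
    make_msa,
    synthetic_pigr_cdna,
    synthetic_pigr_locus,
)


def test_locus_generator_deterministic():
    a, b = make_locus(LocusSpec(seed=42)), make_locus(LocusSpec(seed=42))
    assert a.scaffold == b.scaffold
    assert a.gff3 == b.gff3
    assert make_locus(LocusSpec(seed=43)).scaffold != a.scaffold


def test_locus_realizes_requested_intron_lengths():
    loc = make_locus(LocusSpec(seed=0))
    assert extract_introns(loc.model).lengths == list(LocusSpec().intron_lengths)


def test_locus_transcript_matches_spliced_sequence():
    for strand in "+-":
        loc = make_locus(LocusSpec(seed=3, strand=strand))
        assert spliced_sequence(loc.model, loc.scaffold) == loc.plant_log["transcript"]


def test_locus_without_planted_island_is_island_free():
    loc = make_locus(LocusSpec(seed=0, cgi_length=None))
    assert detect_cgi(loc.scaffold) == []


def test_planted_island_detected_at_logged_coordinates():
    loc = make_locus(LocusSpec(seed=0))
    truth = loc.plant_log["cgi"]
    islands = detect_cgi(loc.scaffold)
    overlapping = [
        i for i in islands if i.start < truth["end"] and truth["start"] < i.end
    ]
    assert len(islands) == 1 and len(overlapping) == 1
    assert abs(truth["obs_exp"] - LocusSpec().cgi_obs_exp) <= 0.05


def test_planted_motifs_recovered_with_strands_and_mismatches():
    spec = LocusSpec(seed=8)
    loc = make_locus(spec)
    truth = loc.plant_log["motifs"]["plants"]
    hits = scan_motif(loc.scaffold, spec.motif, max_mismatch=1)
    got = {(h.position, h.strand) for h in hits}
    assert {(p.position, p.strand) for p in truth} <= got
    by_pos = {h.position: h for h in hits}
    for plant in truth:
        assert by_pos[plant.position].mismatches == plant.mismatches
    # the two exact tandem copies share a group
    tandem = [by_pos[p.position] for p in truth if p.mismatches == 0]
    assert len({h.tandem_group for h in tandem}) == 1


def test_planted_pas_present_in_logged_intron():
    loc = make_locus(LocusSpec(seed=1))
    pas_pos = loc.plant_log["pas"]["position"]
    hits = scan_pas(loc.scaffold[pas_pos - 10 : pas_pos + 16])
    assert any(h.canonical and h.position == 11 for h in hits)


def test_overlapping_plants_rejected():
    spec = LocusSpec(seed=0, motif_plants=(MotifPlant(400, "+", 0),))  # inside CGI
    with pytest.raises(SpecError):
        make_locus(spec)


def test_msa_generator_deterministic_and_seed_sensitive():
    a, b = make_msa(MsaSpec(seed=9)), make_msa(MsaSpec(seed=9))
    assert a.alignment.sequences == b.alignment.sequences
    assert make_msa(MsaSpec(seed=10)).alignment.sequences != a.alignment.sequences


def test_msa_no_plants_no_background_screens_empty():
    spec = MsaSpec(
        seed=0,
        background_rate=0.0,
        n_specific_by_region=(0, 0, 0, 0, 0),
        n_shared=0,
        n_charge_plants=0,
        sequon_site=False,
    )
    assert screen_specific_columns(make_msa(spec).alignment) == []


@pytest.mark.parametrize("seed", range(5))
def test_screen_recovers_exactly_planted_columns(seed):
    msa = make_msa(MsaSpec(seed=seed))
    cols = screen_specific_columns(msa.alignment)
    got_specific = sorted(c.column for c in cols if c.classification == "focal_specific")
    got_shared = sorted(c.column for c in cols if c.classification == "focal_sister_shared")
    assert got_specific == sorted(p["column"] for p in msa.plant_log["planted_columns"])
    assert got_shared == sorted(s["column"] for s in msa.plant_log["shared_columns"])
    by_col = {c.column: c for c in cols}
    for plant in msa.plant_log["planted_columns"]:
        assert by_col[plant["column"]].charge_change == plant["charge_change"]


def test_fragment_mask_gapping_all_focal_at_plant_rejected():
    spec = MsaSpec(seed=0, fragment_mask=tuple((i, 0, 317) for i in range(12)))
    with pytest.raises(SpecError):
        make_msa(spec)


def test_cq_generator_deterministic_and_ranked():
    a, b = make_cq(CqSpec(seed=6)), make_cq(CqSpec(seed=6))
    assert a.equals(b)
    spec = CqSpec(seed=2, noise_sd=0.1)
    from coldlocus.qexpr import ddcq

    rel = ddcq(make_cq(spec), spec.calibrator)
    summary = rel.summary.set_index("tissue")["mean_fold"]
    true_rank = sorted(spec.tissue_folds, key=spec.tissue_folds.get)
    assert list(summary.loc[true_rank].sort_values().index) == true_rank


# ---------------------------------------------------------------------------
# fixed synthetic reference (published-anatomy stand-in)


@pytest.fixture(scope="module")
def ref():
    return synthetic_pigr_cdna()


def test_reference_cdna_anatomy(ref):
    assert len(ref.cdna) == 1414
    assert ref.cds_start == 38 and len(ref.cdna) - ref.cds_end == 359
    cds = ref.cdna[ref.cds_start : ref.cds_end]
    assert translate(cds) == ref.protein
    assert len(ref.protein) == 338


def test_reference_pas_positions(ref):
    hits = scan_pas(ref.cdna)
    assert [(h.position, h.pas_class) for h in hits] == [
        (1387, "canonical"),
        (1395, "non-canonical"),
    ]


def test_reference_has_exactly_four_sequons(ref):
    hits = scan_sequons(ref.protein)
    assert len(hits) == 4
    regions = ref.regions
    region_of = lambda p: next(
        name for name, (lo, hi) in regions.items() if lo <= p <= hi
    )
    assert [region_of(h.asn_position) for h in hits] == ["D1", "D2", "EMPD", "CYT"]


def test_reference_cysteine_spacings(ref):
    lo, hi = ref.regions["D1"]
    d1 = cysteine_pattern(ref.protein[lo - 1 : hi])
    lo, hi = ref.regions["D2"]
    d2 = cysteine_pattern(ref.protein[lo - 1 : hi])
    assert (d1.canonical_spacing, d1.small_spacing) == (68, 7)
    assert (d2.canonical_spacing, d2.small_spacing) == (62, 7)
    assert d1.igv_like and d2.igv_like


def test_reference_empd_and_tm_composition(ref):
    lo, hi = ref.regions["EMPD"]
    empd = ref.protein[lo - 1 : hi]
    assert len(empd) == 39
    assert composition(empd)["P"] == pytest.approx(0.179, abs=0.0005)
    assert theoretical_pi(empd) == pytest.approx(11.0, abs=0.3)
    lo, hi = ref.regions["TM"]
    tm = ref.protein[lo - 1 : hi]
    assert len(tm) == 20
    assert composition(tm)["L"] == pytest.approx(0.30)
    assert tm.count("C") == 1
    # hydropathy scan flags the annotated TM span
    assert any(c.start <= lo and c.end >= hi for c in hydropathy_tm_scan(ref.protein))


def test_reference_locus_span_and_exons():
    loc = synthetic_pigr_locus()
    assert loc.model.n_exons == 8
    assert loc.model.span_length == 8310
    introns = extract_introns(loc.model)
    assert introns.lengths == [628, 2372, 548, 2825, 124, 146, 111]
    assert sum(loc.model.exon_lengths) + sum(introns.lengths) == 8310
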