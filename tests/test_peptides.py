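"""Editing-specific peptide pairs, PTM mimicry, ion coverage and evidence rules."""

import itertools
import math

import numpy as np
import pytest

from editoform.digest import DigestConfig, default_mass_table, peptide_mass, residue_delta
from editoform.editing_sites import EditingSite
from editoform.peptides import (
    EditingPeptidePair,
    EvidenceThresholds,
    ModificationEntry,
    PSMRecord,
    default_modification_table,
    estimate_editing_fraction,
    filter_psm_evidence,
    find_editing_specific_peptides,
    ptm_mimicry_screen,
    read_psm_tsv,
    site_ion_coverage,
    write_psm_tsv,
)
from editoform.proteoforms import Proteoform, VariantSignature

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Pair enumeration


@pytest.mark.parametrize(
    "site_id, edited, unedited, offset",
    [
        ("nad2eU821SFp100", "ISIFANILR", "ISISANILR", 4),
        ("nad7eU739LFp100", "AAPYDVYDQLDFDVPVGTR", "AAPYDVYDQLDLDVPVGTR", 12),
        ("rps4eU299PLp60", "TSYIPFLLNLETR", "TSYIPFPLNLETR", 7),
    ],
)
def test_printed_pairs_recovered(reference_pairs, site_id, edited, unedited, offset):
    pair = reference_pairs[site_id]
    assert pair.edited_peptide == edited
    assert pair.unedited_peptide == unedited
    assert pair.residue_offset_in_peptide == offset
    assert not pair.cleavage_altering and not pair.il_ambiguous


def test_pair_mass_delta_equals_residue_delta(reference_pairs, mass_table):
    for pair in reference_pairs.values():
        site_delta = residue_delta(pair.unedited_residue, pair.edited_residue, mass_table)
        assert pair.mass_delta == pytest.approx(site_delta, abs=1e-4)


def test_mass_delta_equals_residue_difference_for_all_380_pairs(mass_table):
    """For every ordered amino-acid pair, substituting one residue inside a
    peptide shifts its mass by exactly the residue-mass difference."""
    for a, b in itertools.permutations(AA, 2):
        pep_a, pep_b = f"GGG{a}GGGGGGR", f"GGG{b}GGGGGGR"
        delta = peptide_mass(pep_b, mass_table) - peptide_mass(pep_a, mass_table)
        assert delta == pytest.approx(residue_delta(a, b, mass_table), abs=1e-4)


def _proteoform_pair(site_id, edited_seq, unedited_seq):
    pe = Proteoform("g", "", VariantSignature(((site_id, "E"),)), edited_seq)
    pu = Proteoform("g", "", VariantSignature(((site_id, "U"),)), unedited_seq)
    return [pe, pu]


def _raw_site(site_id, gene, nt_pos, ref, edited):
    return EditingSite(site_id, gene, nt_pos, ref, edited, 1.0)


def test_cleavage_altering_substitution_has_no_one_to_one_pair():
    # R (unedited) -> C (edited) at codon 10 destroys a cleavage point,
    # so edited/unedited covering peptides have different coordinates
    unedited = "MAAAKAAAARAAAAAAAK"  # R at position 10
    edited = "MAAAKAAAACAAAAAAAK"
    site = _raw_site("geU28RCp100", "g", 28, "R", "C")
    assert site.codon_index == 10
    pairs = find_editing_specific_peptides(
        _proteoform_pair("geU28RCp100", edited, unedited),
        site,
        DigestConfig(max_missed=0, min_len=4, min_mass=0.0),
    )
    assert pairs and all(p.cleavage_altering for p in pairs)
    for p in pairs:
        assert len(p.edited_peptide) != len(p.unedited_peptide)


def test_il_ambiguous_pair_flagged():
    unedited = "MAAAKAAAIAAAK"
    edited = "MAAAKAAALAAAK"
    site = _raw_site("geU25ILp100", "g", 25, "I", "L")
    pairs = find_editing_specific_peptides(
        _proteoform_pair("geU25ILp100", edited, unedited),
        site,
        DigestConfig(max_missed=0, min_len=4, min_mass=0.0),
    )
    (pair,) = pairs
    assert pair.il_ambiguous
    assert pair.mass_delta == pytest.approx(0.0, abs=1e-9)


def test_uncovered_site_yields_empty_list():
    # the only covering peptide is too short for the filter
    unedited = "MAKSAKAAAAAAAK"
    edited = "MAKFAKAAAAAAAK"
    site = _raw_site("geU11SFp100", "g", 11, "S", "F")
    assert site.codon_index == 4
    pairs = find_editing_specific_peptides(
        _proteoform_pair("geU11SFp100", edited, unedited),
        site,
        DigestConfig(max_missed=0),
    )
    assert pairs == []


# ---------------------------------------------------------------------------
# PTM mass mimicry


def _pair(edited="TSYIPFLLNLETR", unedited="TSYIPFPLNLETR", offset=7, delta=None):
    if delta is None:
        delta = peptide_mass(edited) - peptide_mass(unedited)
    return EditingPeptidePair("s", edited, unedited, offset, delta)


def test_oxidation_mimics_proline_to_leucine():
    pair = _pair()  # P -> L, +16.0313 Da
    hits = ptm_mimicry_screen(pair, default_modification_table())
    assert "Oxidation" in {m.name for m in hits}
    assert pair.mimicry_mods == hits


def test_serine_to_phenylalanine_has_no_mimic_in_sparse_table():
    pair = _pair("ISIFANILR", "ISISANILR", 4)  # +60.0364 Da
    mods = [
        ModificationEntry("m16", 16.0, frozenset("*")),
        ModificationEntry("m57", 57.0, frozenset("*")),
    ]
    assert ptm_mimicry_screen(pair, mods) == []


def test_mimicry_window_boundary_is_inclusive():
    pair = _pair()
    exact = ModificationEntry("exact", pair.mass_delta, frozenset("*"))
    assert ptm_mimicry_screen(pair, [exact], window=0.001) == [exact]


def test_mimicry_respects_site_specificity():
    pair = _pair()  # unedited residue is P
    lys_only = ModificationEntry("lys_mod", pair.mass_delta, frozenset("K"))
    assert ptm_mimicry_screen(pair, [lys_only]) == []


def test_empty_mod_table_warns():
    with pytest.warns(UserWarning):
        assert ptm_mimicry_screen(_pair(), []) == []


# ---------------------------------------------------------------------------
# Site ion coverage


def _psm(peptide, ions, score=150.0, scale="andromeda", spectra=1, mbr=False,
         intensity=1e6):
    return PSMRecord(peptide, "g", score, scale, spectra, mbr,
                     frozenset(ions), intensity, "S1")


@pytest.mark.parametrize(
    "ions, covered",
    [
        ({"b5"}, True),     # b5 spans 1-5, includes position 4
        ({"b4"}, True),     # boundary: b4 spans 1-4
        ({"b3", "y5"}, False),  # b3 spans 1-3; y5 spans 5-9
        ({"y6"}, True),     # y6 spans 4-9
        (set(), False),
    ],
)
def test_site_ion_coverage_span_arithmetic(ions, covered):
    pair = _pair("ISIFANILR", "ISISANILR", 4)
    assert site_ion_coverage(_psm("ISIFANILR", ions), pair) is covered


def test_ion_coverage_rejects_foreign_peptide_and_bad_tags():
    pair = _pair("ISIFANILR", "ISISANILR", 4)
    with pytest.raises(ValueError, match="neither form"):
        site_ion_coverage(_psm("PEPTIDEK", {"b5"}), pair)
    with pytest.raises(ValueError, match="fragment tag"):
        site_ion_coverage(_psm("ISIFANILR", {"a3"}), pair)
    with pytest.raises(ValueError, match="outside"):
        site_ion_coverage(_psm("ISIFANILR", {"b9"}), pair)


# ---------------------------------------------------------------------------
# Evidence filter


GOOD = dict(ions={"b5"}, score=150.0, spectra=2)


def test_evidence_truth_table():
    """Every rule combination produces exactly the expected failure list."""
    pair = _pair("ISIFANILR", "ISISANILR", 4)
    cases = [
        # (psms, expected failed rules)
        ([_psm("ISIFANILR", **GOOD)], []),
        # high score but single spectrum: a one-hit wonder
        ([_psm("ISIFANILR", {"b5"}, score=150.0, spectra=1)], ["spectra_count"]),
        # all records MBR-only (no spectra, no ions)
        (
            [_psm("ISIFANILR", set(), score=0.0, spectra=0, mbr=True)] * 3,
            ["ion_coverage", "mbr_only", "score", "spectra_count"],
        ),
        # strong identifications that never cover the site
        (
            [_psm("ISIFANILR", {"b3"}, spectra=2)],
            ["ion_coverage"],
        ),
        # below the Andromeda threshold
        (
            [_psm("ISIFANILR", {"b5"}, score=80.0, spectra=2)],
            ["ion_coverage", "score"],
        ),
        # covered PSM below threshold plus uncovered PSM above it
        (
            [
                _psm("ISIFANILR", {"b5"}, score=80.0),
                _psm("ISIFANILR", {"b3"}, score=150.0),
            ],
            ["ion_coverage"],
        ),
        # hyperscore scale has its own threshold
        ([_psm("ISIFANILR", {"b5"}, score=25.0, scale="hyperscore", spectra=2)], []),
        ([_psm("ISIFANILR", {"b5"}, score=15.0, scale="hyperscore", spectra=2)],
         ["ion_coverage", "score"]),
        # MBR-only plus one real identification is acceptable
        (
            [
                _psm("ISIFANILR", set(), score=0.0, spectra=0, mbr=True),
                _psm("ISIFANILR", **GOOD),
            ],
            [],
        ),
        # no PSMs at all
        ([], ["spectra_count"]),
    ]
    for psms, expected in cases:
        decision = filter_psm_evidence(psms, pair)
        assert decision.failed_rules == expected, (psms, decision.failed_rules)
        assert decision.accepted == (not expected)


def test_evidence_filter_order_independent_and_idempotent():
    pair = _pair("ISIFANILR", "ISISANILR", 4)
    psms = [
        _psm("ISIFANILR", {"b5"}, score=80.0),
        _psm("ISIFANILR", {"b3"}, score=150.0),
        _psm("ISISANILR", **GOOD),
    ]
    d1 = filter_psm_evidence(psms, pair)
    d2 = filter_psm_evidence(list(reversed(psms)), pair)
    assert d1.failed_rules == d2.failed_rules == filter_psm_evidence(psms, pair).failed_rules


def test_evidence_filter_rejects_foreign_peptides():
    pair = _pair("ISIFANILR", "ISISANILR", 4)
    with pytest.raises(ValueError, match="neither form"):
        filter_psm_evidence([_psm("PEPTIDEK", {"b5"})], pair)


def test_il_ambiguous_pair_rejected_by_default():
    pair = EditingPeptidePair("s", "AAALAAAK", "AAAIAAAK", 4, 0.0, il_ambiguous=True)
    decision = filter_psm_evidence([_psm("AAALAAAK", **GOOD)], pair)
    assert not decision.accepted and "il_ambiguous" in decision.failed_rules
    lenient = EvidenceThresholds(exclude_il_ambiguous=False)
    assert filter_psm_evidence([_psm("AAALAAAK", **GOOD)], pair, lenient).accepted


def test_strict_mimicry_mode_rejects_unresolved_pairs():
    pair = _pair()
    ptm_mimicry_screen(pair, default_modification_table())
    assert pair.mimicry_mods
    strict = EvidenceThresholds(strict_mimicry=True)
    decision = filter_psm_evidence([_psm(pair.edited_peptide, {"y7"}, spectra=2)],
                                   pair, strict)
    assert "mimicry_unresolved" in decision.failed_rules


# ---------------------------------------------------------------------------
# Editing-fraction estimate


@pytest.mark.parametrize(
    "e, u, expected", [(80, 20, 0.8), (0, 5, 0.0), (7, 0, 1.0), (1, 3, 0.25)]
)
def test_estimate_editing_fraction(e, u, expected):
    assert estimate_editing_fraction(e, u) == pytest.approx(expected)


def test_estimate_editing_fraction_undefined_when_both_zero():
    with pytest.warns(UserWarning):
        assert math.isnan(estimate_editing_fraction(0.0, 0.0))


def test_estimate_editing_fraction_rejects_negative():
    with pytest.raises(ValueError):
        estimate_editing_fraction(-1.0, 2.0)


def test_psm_tsv_round_trip(tmp_path):
    psms = [
        _psm("ISIFANILR", {"b5", "y6"}),
        _psm("ISISANILR", set(), score=0.0, spectra=0, mbr=True),
    ]
    path = tmp_path / "psms.tsv"
    write_psm_tsv(psms, path)
    back = read_psm_tsv(path)
    assert back == psms
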