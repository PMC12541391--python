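"""Complexome maps: construction, normalization, aggregation, calibration, peaks."""

import numpy as np
import pandas as pd
import pytest

from editoform.complexome import (
    ComplexomeMap,
    FractionCalibration,
    ModuleDefinition,
    aggregate_module_profile,
    build_profiles,
    calibrate_fraction_masses,
    compare_maps,
    compute_ibaq,
    locate_profile_peaks,
    normalize_profiles,
    read_complexome_tsv,
    read_markers_tsv,
    read_modules_tsv,
    write_complexome_tsv,
)


def _map(rows, n_fractions=None, label=""):
    df = pd.DataFrame(rows).T
    if n_fractions is not None:
        df = df.reindex(columns=range(1, n_fractions + 1), fill_value=0.0)
    else:
        df.columns = range(1, df.shape[1] + 1)
    return ComplexomeMap(df.astype(float), label=label)


class TestBuildProfiles:
    def test_peptide_level_sums_spectra(self):
        records = pd.DataFrame(
            {
                "protein_label": ["p1"] * 3,
                "peptide": ["PEPA"] * 3,
                "fraction_id": [7, 7, 7],
                "intensity": [1.0, 2.0, 3.0],
            }
        )
        cmap = build_profiles(records, level="peptide", n_fractions=10)
        assert cmap.intensity.loc["PEPA", 7] == 6.0
        assert cmap.intensity.loc["PEPA"].drop(7).eq(0).all()

    def test_protein_sum_is_linear_in_peptides(self):
        records = pd.DataFrame(
            {
                "protein_label": ["p1"] * 4,
                "peptide": ["A", "A", "B", "B"],
                "fraction_id": [1, 2, 1, 3],
                "intensity": [1.0, 2.0, 4.0, 8.0],
            }
        )
        by_pep = build_profiles(records, level="peptide", n_fractions=4)
        by_prot = build_profiles(records, level="peptide_sum", n_fractions=4)
        summed = by_pep.intensity.loc["A"] + by_pep.intensity.loc["B"]
        assert (by_prot.intensity.loc["p1"] == summed).all()

    def test_empty_input_warns_and_returns_empty(self, caplog):
        cmap = build_profiles(pd.DataFrame(), n_fractions=5)
        assert cmap.intensity.empty

    def test_missing_fraction_ids_rejected(self):
        records = pd.DataFrame(
            {"protein_label": ["p"], "fraction_id": [None], "intensity": [1.0]}
        )
        with pytest.raises(ValueError, match="1 records missing"):
            build_profiles(records)

    def test_ibaq_divides_by_theoretical_count(self):
        records = pd.DataFrame(
            {"protein_label": ["p1"], "fraction_id": [2], "intensity": [1000.0]}
        )
        cmap = build_profiles(
            records, level="protein", n_fractions=3, theoretical_peptides={"p1": 10}
        )
        assert cmap.intensity.loc["p1", 2] == 100.0


class TestNormalize:
    def test_row_scaled_to_max_100(self):
        cmap = _map({"p": [2.0, 4.0, 8.0]})
        out = normalize_profiles(cmap)
        assert list(out.intensity.loc["p"]) == [25.0, 50.0, 100.0]

    def test_idempotent(self):
        cmap = _map({"p": [2.0, 4.0, 8.0], "q": [1.0, 0.5, 0.25]})
        once = normalize_profiles(cmap)
        twice = normalize_profiles(once)
        pd.testing.assert_frame_equal(once.intensity, twice.intensity)

    def test_scale_invariant(self):
        base = {"p": [3.0, 1.0, 2.0]}
        a = normalize_profiles(_map(base))
        b = normalize_profiles(_map({"p": [30.0, 10.0, 20.0]}))
        pd.testing.assert_frame_equal(a.intensity, b.intensity)

    def test_zero_rows_dropped(self, caplog):
        cmap = _map({"p": [1.0, 2.0], "zero": [0.0, 0.0]})
        with caplog.at_level("INFO"):
            out = normalize_profiles(cmap)
        assert list(out.intensity.index) == ["p"]


class TestAggregate:
    def test_elementwise_sum(self):
        cmap = _map({"a": [1.0, 2.0], "b": [10.0, 20.0]})
        mod = ModuleDefinition("m", ("a", "b"))
        assert list(aggregate_module_profile(cmap, mod)) == [11.0, 22.0]

    def test_absent_member_warns_and_is_skipped(self, caplog):
        cmap = _map({"a": [1.0, 2.0]})
        with caplog.at_level("WARNING"):
            out = aggregate_module_profile(cmap, ModuleDefinition("m", ("a", "ghost")))
        assert list(out) == [1.0, 2.0]
        assert "ghost" in caplog.text

    def test_no_members_present_is_error(self):
        cmap = _map({"a": [1.0]})
        with pytest.raises(ValueError):
            aggregate_module_profile(cmap, ModuleDefinition("m", ("ghost",)))

    def test_partitioning_modules_conserve_column_totals(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(
            rng.uniform(0, 10, (6, 5)),
            index=[f"p{i}" for i in range(6)],
            columns=range(1, 6),
        )
        cmap = ComplexomeMap(mat)
        mods = [
            ModuleDefinition("m1", ("p0", "p1")),
            ModuleDefinition("m2", ("p2", "p3", "p4")),
            ModuleDefinition("m3", ("p5",)),
        ]
        total = sum(aggregate_module_profile(cmap, m) for m in mods)
        assert np.allclose(total, mat.sum(axis=0).to_numpy())


class TestCompareMaps:
    def test_doubled_map_gets_factor_half(self):
        ref = _map({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        other = ComplexomeMap(ref.intensity * 2.0)
        _, rescaled, factor = compare_maps(ref, other)
        assert factor == pytest.approx(0.5)
        pd.testing.assert_frame_equal(rescaled.intensity, ref.intensity)

    def test_self_comparison_is_identity(self):
        ref = _map({"a": [1.0, 2.0]})
        _, rescaled, factor = compare_maps(ref, ref)
        assert factor == pytest.approx(1.0)
        pd.testing.assert_frame_equal(rescaled.intensity, ref.intensity)

    def test_within_map_ratios_preserved(self):
        ref = _map({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        other = _map({"a": [5.0, 2.0], "b": [1.0, 8.0]})
        _, rescaled, _ = compare_maps(ref, other)
        ratio_before = other.intensity.loc["a", 1] / other.intensity.loc["b", 2]
        ratio_after = rescaled.intensity.loc["a", 1] / rescaled.intensity.loc["b", 2]
        assert ratio_after == pytest.approx(ratio_before)

    def test_factor_invariant_to_protein_ordering(self):
        ref = _map({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        other = _map({"a": [5.0, 2.0], "b": [1.0, 8.0]})
        shuffled = ComplexomeMap(other.intensity.loc[["b", "a"]])
        assert compare_maps(ref, other)[2] == pytest.approx(
            compare_maps(ref, shuffled)[2]
        )

    def test_disjoint_proteins_rejected(self):
        with pytest.raises(ValueError, match="share no proteins"):
            compare_maps(_map({"a": [1.0]}), _map({"z": [1.0]}))


class TestCalibration:
    def test_log_linear_interpolation(self):
        cal = calibrate_fraction_masses([(10, 1000.0), (30, 100.0)])
        assert float(cal.mass_at(20)) == pytest.approx(316.23, rel=1e-3)

    def test_markers_reproduced(self):
        # masses chosen on a log-linear gradient gel (2: 1600 kDa, 42: 60 kDa)
        cal = calibrate_fraction_masses([(2, 1600.0), (20, 365.0), (42, 60.0)])
        for f, m in cal.markers:
            assert float(cal.mass_at(f)) == pytest.approx(m, rel=0.05)

    def test_fraction_at_inverts_mass_at(self):
        cal = calibrate_fraction_masses([(2, 1600.0), (42, 60.0)])
        assert cal.fraction_at(float(cal.mass_at(17))) == pytest.approx(17.0)

    def test_single_marker_rejected(self):
        with pytest.raises(ValueError):
            calibrate_fraction_masses([(10, 1000.0)])

    def test_non_monotone_markers_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            calibrate_fraction_masses([(10, 100.0), (20, 1000.0), (30, 500.0)])


class TestPeaks:
    cal = FractionCalibration(slope=-0.0358, intercept=3.2758)  # ~1600->60 kDa

    def test_single_gaussian_bump(self):
        x = np.arange(1, 44)
        profile = 100 * np.exp(-0.5 * ((x - 20) / 2) ** 2)
        peaks = locate_profile_peaks(profile, self.cal)
        assert len(peaks) == 1
        assert peaks[0][0] == 20

    def test_two_bumps_ordered_by_height(self):
        x = np.arange(1, 44)
        profile = 100 * np.exp(-0.5 * ((x - 10) / 1.5) ** 2) + 40 * np.exp(
            -0.5 * ((x - 30) / 1.5) ** 2
        )
        peaks = locate_profile_peaks(profile, self.cal)
        assert [p[0] for p in peaks] == [10, 30]
        assert peaks[0][2] > peaks[1][2]

    def test_noise_below_prominence_is_empty(self):
        rng = np.random.default_rng(8)
        profile = 100.0 + rng.uniform(0, 5, size=43)  # wiggles << 10% of max
        assert locate_profile_peaks(profile, self.cal) == []

    def test_flat_profile_is_empty(self):
        assert locate_profile_peaks(np.zeros(43), self.cal) == []

    def test_apparent_mass_comes_from_calibration(self):
        x = np.arange(1, 44)
        profile = np.exp(-0.5 * ((x - 15) / 2) ** 2)
        ((frac, mass, _),) = locate_profile_peaks(profile, self.cal)
        assert mass == pytest.approx(float(self.cal.mass_at(15)))


class TestIbaq:
    def test_division(self):
        assert compute_ibaq(1000.0, 10) == 100.0
        assert compute_ibaq(0.0, 5) == 0.0

    def test_linearity(self):
        assert compute_ibaq(2000.0, 7) == 2 * compute_ibaq(1000.0, 7)

    def test_zero_theoretical_peptides_rejected(self):
        with pytest.raises(ValueError):
            compute_ibaq(100.0, 0)


def test_complexome_tsv_round_trip(tmp_path):
    cmap = _map({"a": [1.0, 2.0, 3.0], "b": [0.5, 0.0, 4.0]}, label="wt")
    path = tmp_path / "map.tsv"
    write_complexome_tsv(cmap, path)
    back = read_complexome_tsv(path, label="wt")
    pd.testing.assert_frame_equal(back.intensity, cmap.intensity, check_names=False)


def test_bottom_up_orientation_flips_fraction_axis(tmp_path):
    cmap = _map({"a": [1.0, 2.0, 3.0]})
    path = tmp_path / "map.tsv"
    write_complexome_tsv(cmap, path)
    flipped = read_complexome_tsv(path, orientation="bottom_up")
    assert list(flipped.intensity.loc["a"]) == [3.0, 2.0, 1.0]


def test_negative_intensities_rejected():
    with pytest.raises(ValueError):
        _map({"a": [1.0, -0.5]})


def test_bundled_module_definitions_load():
    from importlib import resources

    with resources.as_file(
        resources.files("editoform").joinpath("data/complex1_modules.tsv")
    ) as p:
        mods = read_modules_tsv(p)
    names = {m.name for m in mods}
    assert {"N", "Q", "P_P", "P_D", "200kDa", "400kDa"} <= names
    m200 = next(m for m in mods if m.name == "200kDa")
    assert "ATMG00285" in m200.member_proteins  # Nad2 joins at the 200 kDa step
    assert m200.expected_mass_kda == 200
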