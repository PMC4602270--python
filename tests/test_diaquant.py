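"""Targeted extraction: window assignment, XICs, integration, alignment,
normalization and summation roll-up."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import swathlite as sw
from swathlite import diaquant, simdata


def _run_from_points(points):
    """DiaRun from (window_low, window_high, rt, mz, intensity) tuples."""
    scans = pd.DataFrame(points, columns=["window_low", "window_high",
                                          "rt_min", "mz", "intensity"])
    return simdata.DiaRun("r1", "control", 1, 1, scans)


class TestAssignWindow:
    def test_boundary_belongs_to_upper_window(self):
        s = sw.AcquisitionScheme(mode="swath", windows=((350.0, 400.0), (400.0, 450.0)))
        assert diaquant.assign_window(400.0, s) == 1
        assert diaquant.assign_window(399.999, s) == 0

    def test_out_of_range_is_unscheduled(self, scheme):
        assert diaquant.assign_window(1300.0, scheme) is None
        assert diaquant.assign_window(349.9, scheme) is None

    def test_overlap_resolved_by_nearest_center(self):
        s = sw.AcquisitionScheme(mode="swath", windows=((398.0, 412.0), (410.0, 424.0)))
        # centers 405 and 417: 411 is nearer the first
        assert diaquant.assign_window(411.0, s) == 0
        assert diaquant.assign_window(412.5, s) == 1

    def test_library_precursors_covered_exactly_once(self, small_proteome, scheme):
        idx = scheme.assign(small_proteome.peptides["precursor_mz"].to_numpy())
        assert (idx >= 0).all()  # each precursor in exactly one window


class TestExtractXic:
    def test_fifty_ppm_band_edges(self):
        # 500 Th at 50 ppm -> [499.975, 500.025]
        run = _run_from_points([
            (350, 400, 1.0, 499.974, 5.0),
            (350, 400, 1.0, 499.976, 7.0),
            (350, 400, 1.0, 500.024, 11.0),
            (350, 400, 1.0, 500.026, 13.0),
        ])
        xic = diaquant.extract_xic(run, 500.0, 350.0, rt_center=1.0, rt_halfwidth=5)
        assert len(xic) == 1
        assert xic.intensity[0] == pytest.approx(18.0)  # 7 + 11, edges excluded

    def test_no_nearby_points_gives_empty_xic(self):
        run = _run_from_points([(350, 400, 1.0, 380.0, 5.0)])
        xic = diaquant.extract_xic(run, 500.0, 350.0, rt_center=1.0)
        assert len(xic) == 0

    def test_points_summed_per_cycle_and_sorted(self):
        run = _run_from_points([
            (350, 400, 2.0, 500.001, 1.0),
            (350, 400, 1.0, 500.001, 2.0),
            (350, 400, 1.0, 499.999, 3.0),
        ])
        xic = diaquant.extract_xic(run, 500.0, 350.0, rt_center=1.5, rt_halfwidth=5)
        assert list(xic.rt_min) == [1.0, 2.0]
        assert list(xic.intensity) == [5.0, 1.0]

    def test_noiseless_apex_equals_simulated_amplitude(self, noiseless_study, scheme):
        study = noiseless_study
        lib = study.library
        row = lib.iloc[7]
        pep = study.truth.proteome.peptides.set_index("peptide").loc[row.peptide]
        amp = (study.truth_record.runs.loc[row.protein_accession, study.runs[0].run_id]
               * pep.pep_share * row.fragment_rel_intensity)
        w = scheme.assign(np.array([row.precursor_mz]))[0]
        xic = diaquant.extract_xic(study.runs[0], row.fragment_mz,
                                   scheme.windows[w][0], rt_center=row.ref_rt_min)
        assert xic.intensity.max() == pytest.approx(amp, rel=1e-6)


class TestIntegratePeak:
    def _xic(self, rt, inten):
        return diaquant.Xic("r", 500.0, 50.0, np.asarray(rt, float),
                            np.asarray(inten, float))

    def test_triangle_area_by_hand(self):
        assert diaquant.integrate_peak(self._xic([0, 1, 2], [0, 10, 0])) == pytest.approx(10.0)

    def test_flat_zero_trace_is_missing(self):
        assert np.isnan(diaquant.integrate_peak(self._xic([0, 1, 2], [0, 0, 0])))

    def test_too_few_points_is_missing(self):
        assert np.isnan(diaquant.integrate_peak(self._xic([0, 1], [5, 5])))

    @given(st.lists(st.floats(0.1, 1e6), min_size=3, max_size=40),
           st.floats(1.5, 100.0))
    def test_doubling_intensities_doubles_area(self, heights, scale):
        rt = np.arange(len(heights), dtype=float)
        a1 = diaquant.integrate_peak(self._xic(rt, heights))
        a2 = diaquant.integrate_peak(self._xic(rt, np.asarray(heights) * scale))
        if np.isnan(a1):
            assert np.isnan(a2)
        else:
            assert a2 == pytest.approx(scale * a1, rel=1e-9)


class TestAlignRt:
    def test_no_jitter_fits_identity(self, noiseless_study, scheme):
        lib = sw.SpectralLibrary(entries=noiseless_study.library)
        m = diaquant.align_rt(noiseless_study.runs[0], lib, scheme)
        assert not m.identity
        # apex RTs are quantized to the cycle grid (one cycle ~ 0.05 min),
        # which bounds the fit error of an otherwise exact identity mapping
        dt = sw.cycle_time(scheme) / 60.0
        assert m.slope == pytest.approx(1.0, abs=1e-3)
        assert abs(m.intercept) <= dt
        assert m.residual_sd <= dt

    def test_constant_shift_recovered(self, design, small_truth, scheme):
        study = sw.simulate_study(design, small_truth, sw.NoiseModel.noiseless(),
                                  scheme, seed=12, run_rt_shifts=[2.0] * 18)
        lib = sw.SpectralLibrary(entries=study.library)
        m = diaquant.align_rt(study.runs[0], lib, scheme)
        assert m.slope == pytest.approx(1.0, abs=1e-3)
        assert m.intercept == pytest.approx(2.0, abs=0.05)

    def test_single_anchor_falls_back_to_identity(self, noiseless_study, scheme, caplog):
        one = sw.SpectralLibrary(entries=noiseless_study.library.iloc[:6])
        with caplog.at_level("WARNING", logger="swathlite"):
            m = diaquant.align_rt(noiseless_study.runs[0], one, scheme, n_anchors=1)
        assert m.identity
        assert "anchor" in caplog.text


def _quant(values, index=None, runs=("r1", "r2", "r3")):
    idx = index if index is not None else pd.MultiIndex.from_tuples(
        [("P1", "AAK", 300.0 + i) for i in range(len(values))],
        names=["protein", "peptide", "fragment_mz"])
    data = pd.DataFrame(values, index=idx, columns=list(runs))
    annot = pd.DataFrame({"run_id": list(runs), "group": "control",
                          "bio_rep": 1, "tech_rep": range(1, len(runs) + 1)})
    return diaquant.QuantTable("transition", data, annot)


class TestNormalize:
    def test_equal_totals_unit_factors(self):
        q = _quant([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        _, f = diaquant.normalize(q)
        assert np.allclose(f, 1.0)

    def test_double_total_halved(self):
        q = _quant([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0]])
        _, f = diaquant.normalize(q)
        assert f["r2"] == pytest.approx(0.5)
        assert f["r1"] == pytest.approx(1.0)

    def test_within_run_ratios_preserved(self):
        q = _quant([[3.0, 6.0, 9.0], [1.0, 4.0, 2.0]])
        out, _ = diaquant.normalize(q)
        before = q.data.iloc[0] / q.data.iloc[1]
        after = out.data.iloc[0] / out.data.iloc[1]
        assert np.allclose(before, after)

    def test_all_missing_run_is_named(self):
        q = _quant([[1.0, np.nan, 1.0], [2.0, np.nan, 2.0]])
        with pytest.raises(ValueError, match="r2"):
            diaquant.normalize(q)


class TestRollup:
    def _library(self, frags_per_pep=6, peptides=("AAK",), protein="P1"):
        rows = []
        for p, pep in enumerate(peptides):
            for i in range(frags_per_pep):
                rows.append((protein, pep, pep, 500.0 + p, 2, 300.0 + i,
                             1.0 - i * 0.1, 10.0, 9.0, 0.0, False))
        return sw.SpectralLibrary(entries=pd.DataFrame(
            rows, columns=["protein_accession", "peptide", "modified_peptide",
                           "precursor_mz", "charge", "fragment_mz",
                           "fragment_rel_intensity", "ref_rt_min", "score",
                           "q_value", "is_decoy"]))

    def test_peptide_is_sum_of_transitions(self):
        lib = self._library(6)
        q = _quant(np.array([[1.0], [2], [3], [4], [5], [6]]), runs=("r1",),
                   index=pd.MultiIndex.from_tuples(
                       [("P1", "AAK", 300.0 + i) for i in range(6)],
                       names=["protein", "peptide", "fragment_mz"]))
        pep, prot = diaquant.rollup(q, lib)
        assert pep.data.loc[("P1", "AAK"), "r1"] == pytest.approx(21.0)
        assert prot.data.loc["P1", "r1"] == pytest.approx(21.0)

    def test_only_library_top_six_summed(self):
        lib = self._library(8)  # library carries 8 ranked fragments
        q = _quant(np.array([[10.0]] * 8), runs=("r1",),
                   index=pd.MultiIndex.from_tuples(
                       [("P1", "AAK", 300.0 + i) for i in range(8)],
                       names=["protein", "peptide", "fragment_mz"]))
        pep, _ = diaquant.rollup(q, lib, max_transitions=6)
        assert pep.data.loc[("P1", "AAK"), "r1"] == pytest.approx(60.0)

    def test_protein_is_sum_of_peptides(self):
        lib = self._library(1, peptides=("AAK", "CCK"))
        idx = pd.MultiIndex.from_tuples(
            [("P1", "AAK", 300.0), ("P1", "CCK", 300.0)],
            names=["protein", "peptide", "fragment_mz"])
        q = _quant(np.array([[21.0], [9.0]]), runs=("r1",), index=idx)
        _, prot = diaquant.rollup(q, lib)
        assert prot.data.loc["P1", "r1"] == pytest.approx(30.0)

    def test_missing_only_when_all_constituents_missing(self):
        lib = self._library(2)
        idx = pd.MultiIndex.from_tuples(
            [("P1", "AAK", 300.0), ("P1", "AAK", 301.0)],
            names=["protein", "peptide", "fragment_mz"])
        q = _quant(np.array([[np.nan, np.nan], [5.0, np.nan]]),
                   runs=("r1", "r2"), index=idx)
        pep, _ = diaquant.rollup(q, lib)
        assert pep.data.loc[("P1", "AAK"), "r1"] == pytest.approx(5.0)
        assert np.isnan(pep.data.loc[("P1", "AAK"), "r2"])

    def test_unknown_transition_ignored_with_warning(self, caplog):
        lib = self._library(1)
        idx = pd.MultiIndex.from_tuples(
            [("P1", "AAK", 300.0), ("P1", "AAK", 999.0)],
            names=["protein", "peptide", "fragment_mz"])
        q = _quant(np.array([[5.0], [7.0]]), runs=("r1",), index=idx)
        with caplog.at_level("WARNING", logger="swathlite"):
            pep, _ = diaquant.rollup(q, lib)
        assert pep.data.loc[("P1", "AAK"), "r1"] == pytest.approx(5.0)
        assert "not retained" in caplog.text


class TestMonotonicity:
    def test_raising_one_transition_never_lowers_protein(self, design, small_truth, scheme):
        """Doubling one transition's simulated ionization share cannot
        decrease its protein's quantified value."""
        study = sw.simulate_study(design, small_truth, sw.NoiseModel.noiseless(),
                                  scheme, seed=13)
        lib = sw.SpectralLibrary(entries=study.library)
        tq = diaquant.quantify_study(lib, study.runs[:1], scheme, align=False)
        _, prot = diaquant.rollup(tq, lib)
        target = study.library.iloc[0]
        boosted = study.runs[0].scans.copy()
        sel = np.isclose(boosted["mz"], target.fragment_mz)
        boosted.loc[sel, "intensity"] *= 2.0
        run2 = simdata.DiaRun("r1", "control", 1, 1, boosted)
        tq2 = diaquant.quantify_study(lib, [run2], scheme, align=False)
        _, prot2 = diaquant.rollup(tq2, lib)
        before = prot.data.loc[target.protein_accession].iloc[0]
        after = prot2.data.loc[target.protein_accession].iloc[0]
        assert after >= before


class TestIo:
    def test_quant_table_roundtrip(self, tmp_path):
        q = _quant([[1.0, np.nan, 3.0], [4.0, 5.0, 6.0]])
        diaquant.write_quant_table(q, tmp_path / "q.tsv")
        back = diaquant.read_quant_table(tmp_path / "q.tsv")
        assert back.level == "transition"
        np.testing.assert_allclose(back.data.to_numpy(), q.data.to_numpy())
        pd.testing.assert_frame_equal(back.annotations.astype(str),
                                      q.annotations.astype(str))

    def test_mzml_roundtrip(self, noiseless_study, tmp_path):
        run = noiseless_study.runs[0]
        diaquant.write_mzml(run, tmp_path / "run.mzML")
        back = diaquant.read_mzml(tmp_path / "run.mzML", run_id=run.run_id)
        a = run.scans.sort_values(["window_low", "rt_min", "mz"]).reset_index(drop=True)
        b = back.scans.sort_values(["window_low", "rt_min", "mz"]).reset_index(drop=True)
        assert len(a) == len(b)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9)
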