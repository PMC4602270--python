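"""Reproducibility cascade: CV computation, stage filters, nesting, R2."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import swathlite as sw
from swathlite import diaquant, qcfilter


def quant_from_matrix(runs_matrix, design):
    """Protein-level QuantTable from a protein x run DataFrame."""
    return diaquant.QuantTable("protein", runs_matrix.copy(), design.run_table())


@pytest.fixture()
def abundance_quant(design):
    p = sw.generate_proteome(200, 1, seed=21)
    truth = sw.generate_ground_truth(p, de_fraction=0.1, seed=21)
    rec = sw.simulate_abundances(design, truth, sw.NoiseModel(), seed=21)
    return quant_from_matrix(rec.runs, design)


class TestComputeCv:
    def test_zero_spread(self):
        assert qcfilter.compute_cv([100, 100, 100]) == 0.0

    def test_hand_value(self):
        # sample sd of (100, 110, 120) is 10; mean 110
        assert qcfilter.compute_cv([100, 110, 120]) == pytest.approx(10 / 110)

    def test_single_value_missing(self):
        assert np.isnan(qcfilter.compute_cv([5.0]))

    def test_nonpositive_mean_missing(self):
        assert np.isnan(qcfilter.compute_cv([-1.0, 1.0]))

    @given(st.lists(st.floats(1.0, 1e6), min_size=2, max_size=10),
           st.floats(0.1, 100.0))
    def test_scale_invariant(self, values, k):
        a = qcfilter.compute_cv(values)
        b = qcfilter.compute_cv(np.asarray(values) * k)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, rel=1e-9)


class TestTechnicalStage:
    def test_identical_injections_pass_everywhere(self, design):
        data = pd.DataFrame(100.0, index=["P1", "P2"],
                            columns=design.run_table()["run_id"])
        res = qcfilter.technical_stage(quant_from_matrix(data, design), design)
        assert res.passed.all().all()
        assert (res.percent_passed == 100.0).all()
        assert (res.bio_values == 100.0).all().all()

    def test_high_cv_injections_fail(self, design):
        data = pd.DataFrame(100.0, index=["P1"], columns=design.run_table()["run_id"])
        # (100, 100, 160): CV = 34.64 / 120 > 0.25
        data.loc["P1", "control_b1_t3"] = 160.0
        res = qcfilter.technical_stage(quant_from_matrix(data, design), design)
        assert not res.passed.loc["P1", "control_b1"]
        assert res.passed.loc["P1", "control_b2"]
        assert res.bio_values.loc["P1", "control_b1"] == pytest.approx(120.0)

    def test_infinite_max_cv_is_vacuous(self, abundance_quant, design):
        res = qcfilter.technical_stage(abundance_quant, design, max_cv=np.inf)
        assert res.passed.to_numpy().sum() == res.cv.notna().to_numpy().sum()

    def test_short_sample_skipped_with_warning(self, design, caplog):
        cols = list(design.run_table()["run_id"])
        data = pd.DataFrame(100.0, index=["P1"], columns=cols)
        data = data.drop(columns=["control_b1_t2", "control_b1_t3"])
        q = diaquant.QuantTable("protein", data,
                                design.run_table()[design.run_table().run_id.isin(data.columns)])
        with caplog.at_level("WARNING", logger="swathlite"):
            res = qcfilter.technical_stage(q, design)
        assert "control_b1" in caplog.text
        assert "control_b1" not in res.cv.columns


class TestCompletenessStage:
    def test_missing_one_replicate_excluded(self, design):
        bio = pd.DataFrame(1.0, index=["P1", "P2"], columns=design.bio_sample_ids())
        bio.loc["P2", "heat_b2"] = np.nan
        kept = qcfilter.completeness_stage(bio, design)
        assert list(kept) == ["P1"]

    def test_toy_matrix_matches_bruteforce(self, design):
        rng = np.random.default_rng(4)
        bio = pd.DataFrame(rng.uniform(1, 2, (5, 6)),
                           index=[f"P{i}" for i in range(5)],
                           columns=design.bio_sample_ids())
        mask = rng.random((5, 6)) < 0.3
        bio[mask] = np.nan
        kept = qcfilter.completeness_stage(bio, design)
        expected = [p for p in bio.index
                    if all(np.isfinite(bio.loc[p, c]) for c in bio.columns)]
        assert list(kept) == expected

    def test_all_runs_mode_is_stricter(self, design, abundance_quant):
        data = abundance_quant.data.copy()
        data.iloc[0, 0] = np.nan  # protein 0 misses one injection only
        q = quant_from_matrix(data, design)
        tech = qcfilter.technical_stage(q, design)
        loose = qcfilter.completeness_stage(tech.bio_values, design, mode="all_bio")
        strict = qcfilter.completeness_stage(tech.bio_values, design,
                                             mode="all_runs", run_data=data)
        assert set(strict) <= set(loose)
        assert data.index[0] in loose and data.index[0] not in strict


class TestBiologicalStage:
    def _bio(self, design, control_vals, heat_vals):
        cols = design.bio_sample_ids()
        return pd.DataFrame([control_vals + heat_vals], index=["P1"], columns=cols)

    def test_low_cv_both_groups_in_final(self, design):
        bio = self._bio(design, [100, 105, 110], [200, 205, 210])
        res = qcfilter.biological_stage(bio, design, bio.index)
        assert "P1" in res.final_proteins

    def test_high_cv_both_groups_excluded(self, design):
        bio = self._bio(design, [100, 160, 230], [100, 170, 250])
        res = qcfilter.biological_stage(bio, design, bio.index)
        assert "P1" not in res.final_proteins

    def test_union_rule_keeps_single_group_passer(self, design):
        # passes control (CV ~ 4.7%) but fails heat (CV ~ 44%)
        bio = self._bio(design, [100, 105, 110], [100, 200, 300])
        res = qcfilter.biological_stage(bio, design, bio.index)
        assert not res.passed.loc["P1", "heat"]
        assert res.passed.loc["P1", "control"]
        assert "P1" in res.final_proteins


class TestReplicateR2:
    def test_self_and_exact_linear_pairs(self, design):
        rng = np.random.default_rng(5)
        x = rng.uniform(10, 1e5, 50)
        bio = pd.DataFrame({c: x for c in design.bio_sample_ids()})
        bio["control_b2"] = 2 * x  # exact proportionality
        mat, mins = qcfilter.replicate_r2(bio, design)
        assert mat.loc["control_b1", "control_b1"] == 1.0
        assert mat.loc["control_b1", "control_b2"] == pytest.approx(1.0)
        assert mins["control"] == pytest.approx(1.0)

    def test_toy_pair_matches_pearson_formula(self, design):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.2, 1.9, 3.4, 3.8, 5.5])
        cols = design.bio_sample_ids()
        bio = pd.DataFrame(1.0, index=range(5), columns=cols)
        bio["control_b1"], bio["control_b2"] = 10.0 ** x, 10.0 ** y
        mat, _ = qcfilter.replicate_r2(bio, design)
        # closed-form Pearson r on the log10 values
        r = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert mat.loc["control_b1", "control_b2"] == pytest.approx(r ** 2)

    def test_too_few_shared_proteins_missing(self, design, caplog):
        bio = pd.DataFrame(np.nan, index=range(5), columns=design.bio_sample_ids())
        bio.iloc[0] = 1.0
        with caplog.at_level("WARNING", logger="swathlite"):
            mat, _ = qcfilter.replicate_r2(bio, design)
        assert np.isnan(mat.loc["control_b1", "control_b2"])


class TestCascadeProperties:
    def test_stage_nesting_over_seeds(self, design):
        for seed in range(6):
            p = sw.generate_proteome(150, 1, seed=seed)
            truth = sw.generate_ground_truth(p, seed=seed)
            rec = sw.simulate_abundances(design, truth,
                                         sw.NoiseModel(tech_cv=0.2), seed=seed)
            data = rec.runs.copy()
            rng = np.random.default_rng(seed)
            data[rng.random(data.shape) < 0.05] = np.nan
            qc = qcfilter.run_qc(quant_from_matrix(data, design), design)
            assert set(qc.final_proteins) <= set(qc.complete_proteins)
            assert set(qc.complete_proteins) <= set(qc.quantified_proteins)

    def test_pass_fraction_monotone_in_tech_cv(self, design):
        p = sw.generate_proteome(300, 1, seed=31)
        truth = sw.generate_ground_truth(p, de_fraction=0.0, seed=31)
        fractions = []
        for cv in (0.05, 0.15, 0.30, 0.60):
            rec = sw.simulate_abundances(
                design, truth, sw.NoiseModel(animal_cv=0.1, tech_cv=cv), seed=31)
            res = qcfilter.technical_stage(quant_from_matrix(rec.runs, design), design)
            fractions.append(res.passed.to_numpy().mean())
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_default_noise_reproduces_reference_scale_pass_rates(self, design):
        """tech_cv 0.10 / animal_cv 0.15: technical pass >= 90% and
        per-group biological pass >= 80%, the scale of the reference
        study's Table-1 percentages (average over 20 seeds)."""
        tech_pct, bio_pct = [], []
        for seed in range(20):
            p = sw.generate_proteome(1000, 1, seed=seed + 100)
            truth = sw.generate_ground_truth(p, de_fraction=0.0, seed=seed)
            rec = sw.simulate_abundances(
                design, truth, sw.NoiseModel(animal_cv=0.15, tech_cv=0.10), seed=seed)
            qc = qcfilter.run_qc(quant_from_matrix(rec.runs, design), design)
            tech_pct.append(qc.technical.percent_passed.mean())
            bio_pct.append(qc.biological.percent_passed.min())
        assert np.mean(tech_pct) >= 90.0
        assert np.mean(bio_pct) >= 80.0
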