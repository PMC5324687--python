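"""Design construction, least-squares inversion, amplitude reconstruction."""

import numpy as np
import pytest
from scipy import stats

import pupilglm as pg
from pupilglm.glm import build_design, invert_glm, reconstruct_amplitudes

SR = 100.0


def basis_for(variant, params=None, sr=SR):
    params = params or pg.canonical_params("exp1")
    return pg.basis_set(params, sr,
                        include_derivative=(variant == "cs_plus_derivative"))


def simple_events():
    return pg.EventTable([2.0, 15.0], ["CSm", "CSpUSm"], [True, True])


class TestBuildDesign:
    def test_single_impulse_column_is_the_rf(self):
        events = pg.EventTable([0.0, 15.0], ["CSm", "CSpUSm"], [True, True])
        basis = basis_for("cs_only")
        design = build_design(events, basis, n_samples=3000)
        csm = design.X[:, design.labels.index("CSm")]
        np.testing.assert_allclose(csm[:1000], basis.components[0], atol=1e-12)
        assert np.all(csm[1000:] == 0)
        cspusm = design.X[:, design.labels.index("CSpUSm")]
        assert np.all(cspusm[:1500] == 0)

    def test_two_close_events_superpose(self):
        events = pg.EventTable([2.0, 3.0], ["CSm", "CSm"], [True, True])
        # degenerate CSpUSm class not allowed in cs_only, so add one far out
        events = pg.EventTable([2.0, 3.0, 20.0], ["CSm", "CSm", "CSpUSm"],
                               [True, True, True])
        basis = basis_for("cs_only")
        design = build_design(events, basis, n_samples=3500)
        rf = basis.components[0]
        oracle = np.zeros(3500)
        for onset in (2.0, 3.0):
            i = int(round(onset * SR))
            oracle[i:i + rf.size] += rf
        np.testing.assert_allclose(
            design.X[:, design.labels.index("CSm")], oracle, atol=1e-12
        )

    @pytest.mark.parametrize("variant, ncols", [
        ("cs_only", 3), ("cs_plus_derivative", 5), ("extended_us", 6),
    ])
    def test_column_counts_and_intercept(self, variant, ncols):
        events = pg.EventTable(
            [2.0, 15.0, 28.0], ["CSm", "CSpUSm", "CSpUSp"], [True] * 3
        )
        us_basis = pg.basis_set(pg.us_params_relative_to_us(), SR)
        design = build_design(
            events, basis_for(variant), 5000, variant,
            us_basis=us_basis if variant == "extended_us" else None,
        )
        assert design.n_columns == ncols
        assert design.labels.count("intercept") == 1
        np.testing.assert_array_equal(design.X[:, -1], 1.0)

    def test_excluded_trials_contribute_no_impulse(self):
        basis = basis_for("cs_only")
        a = pg.EventTable([2.0, 15.0], ["CSm", "CSpUSm"], [True, True])
        b = pg.EventTable([2.0, 10.0, 15.0], ["CSm", "CSm", "CSpUSm"],
                          [True, False, True])
        da = build_design(a, basis, 3000)
        db = build_design(b, basis, 3000)
        np.testing.assert_array_equal(da.X, db.X)

    def test_empty_required_class_raises_with_name(self):
        events = pg.EventTable([2.0], ["CSm"], [True])
        with pytest.raises(ValueError, match="CSpUSm"):
            build_design(events, basis_for("cs_only"), 3000)


class TestInvert:
    def test_noiseless_recovery_exact(self):
        design = build_design(simple_events(), basis_for("cs_only"), 3000)
        betas = np.array([2.0, 1.0, 0.5])
        y = design.X @ betas
        trace = pg.CleanTrace(y, np.ones(3000, bool), SR)
        result = invert_glm(trace, design)
        np.testing.assert_allclose(result.betas, betas, atol=1e-9)

    def test_masked_rows_do_not_change_noiseless_solution(self, rng):
        design = build_design(simple_events(), basis_for("cs_only"), 3000)
        betas = np.array([2.0, 1.0, 0.5])
        y = design.X @ betas
        valid = rng.random(3000) > 0.2
        trace = pg.CleanTrace(y, valid, SR)
        result = invert_glm(trace, design)
        np.testing.assert_allclose(result.betas, betas, atol=1e-9)

    def test_ar1_noise_estimates_unbiased(self, rng):
        # simulation oracle: mean beta error across replicates has CI over 0
        design = build_design(simple_events(), basis_for("cs_only"), 3000)
        betas = np.array([1.0, 0.5, 0.0])
        signal = design.X @ betas
        errs = []
        phi, sd = 0.97, 1.0
        for _ in range(150):
            e = rng.normal(0, sd * np.sqrt(1 - phi**2), 3000)
            noise = np.empty(3000)
            noise[0] = rng.normal(0, sd)
            for i in range(1, 3000):
                noise[i] = phi * noise[i - 1] + e[i]
            trace = pg.CleanTrace(signal + noise, np.ones(3000, bool), SR)
            errs.append(invert_glm(trace, design).betas - betas)
        errs = np.asarray(errs)
        mean = errs.mean(axis=0)
        half = 1.96 * errs.std(axis=0, ddof=1) / np.sqrt(len(errs))
        assert np.all(np.abs(mean) <= half + 1e-12)

    def test_rank_deficiency_and_too_few_rows_raise(self):
        design = build_design(simple_events(), basis_for("cs_only"), 3000)
        X = design.X.copy()
        X[:, 0] = X[:, 1]
        bad = pg.DesignMatrix(X, design.labels, SR, design.valid_rows)
        trace = pg.CleanTrace(np.zeros(3000), np.ones(3000, bool), SR)
        with pytest.raises(np.linalg.LinAlgError):
            invert_glm(trace, bad)
        sparse = pg.CleanTrace(np.zeros(3000), np.zeros(3000, bool), SR)
        with pytest.raises(ValueError):
            invert_glm(sparse, design)

    def test_constant_shift_moves_only_intercept(self):
        design = build_design(simple_events(), basis_for("cs_only"), 3000)
        betas = np.array([2.0, 1.0, 0.5])
        base = invert_glm(
            pg.CleanTrace(design.X @ betas, np.ones(3000, bool), SR), design
        )
        shifted = invert_glm(
            pg.CleanTrace(design.X @ betas + 3.0, np.ones(3000, bool), SR),
            design,
        )
        i = design.labels.index("intercept")
        np.testing.assert_allclose(
            np.delete(shifted.betas, i), np.delete(base.betas, i), atol=1e-9
        )
        assert shifted.betas[i] - base.betas[i] == pytest.approx(3.0, abs=1e-9)


class TestAmplitudes:
    def test_single_component_identity(self):
        result = pg.GLMResult(
            betas=np.array([0.3, 0.8, 0.1]),
            labels=("CSpUSm", "CSm", "intercept"),
            model_variant="cs_only", residual_variance=0.0, n_valid=10,
        )
        amps = reconstruct_amplitudes(result, basis_for("cs_only"))
        assert amps == {"CSpUSm": 0.3, "CSm": 0.8}

    def test_zero_derivative_beta_scales_rf_peak(self):
        basis = basis_for("cs_plus_derivative")
        result = pg.GLMResult(
            betas=np.array([2.0, 0.0, 0.0, 0.0, 0.0]),
            labels=("CSpUSm:canonical", "CSpUSm:derivative",
                    "CSm:canonical", "CSm:derivative", "intercept"),
            model_variant="cs_plus_derivative",
            residual_variance=0.0, n_valid=10,
        )
        with pytest.raises(ValueError):
            # CSm betas present but all zero is fine; drop one to check guard
            reconstruct_amplitudes(
                pg.GLMResult(
                    betas=np.array([2.0, 0.0]),
                    labels=("CSpUSm:canonical", "intercept"),
                    model_variant="cs_plus_derivative",
                    residual_variance=0.0, n_valid=10,
                ),
                basis,
            )
        amps = reconstruct_amplitudes(result, basis)
        assert amps["CSpUSm"] == pytest.approx(2.0 * basis.components[0].max())

    def test_two_component_matches_brute_force_excursion(self, rng):
        basis = basis_for("cs_plus_derivative")
        b = rng.normal(size=2)
        result = pg.GLMResult(
            betas=np.array([b[0], b[1], 0.0]),
            labels=("CSpUSm:canonical", "CSpUSm:derivative", "intercept"),
            model_variant="cs_plus_derivative",
            residual_variance=0.0, n_valid=10,
        )
        amps = reconstruct_amplitudes(result, basis)
        recon = b[0] * basis.components[0] + b[1] * basis.components[1]
        oracle = max(recon, key=abs)
        assert amps["CSpUSm"] == pytest.approx(float(oracle))


class TestRoundTrip:
    @pytest.mark.parametrize("variant", ["cs_only", "cs_plus_derivative"])
    def test_matched_generator_recovery(self, unreinforced_paradigm, variant):
        paradigm = pg.generate_paradigm(unreinforced_paradigm, 3)
        sim = pg.SimulationSpec(
            cs_plus_amplitude=1.3, cs_minus_amplitude=0.4,
            noise_sd=0.0, missing_rate=0.0,
        )
        sessions, truth = pg.simulate_participant(paradigm, sim, SR, 3)
        basis = basis_for(variant)
        result = pg.fit_participant(sessions, basis, variant)
        if variant == "cs_only":
            assert result.amplitudes["CSpUSm"] == pytest.approx(1.3, rel=1e-6)
            assert result.amplitudes["CSm"] == pytest.approx(0.4, rel=1e-6)
        else:
            # generator holds no derivative component: its beta vanishes and
            # the canonical beta carries the planted amplitude
            assert result.beta("CSpUSm:canonical") == pytest.approx(1.3, rel=1e-6)
            assert result.beta("CSpUSm:derivative") == pytest.approx(0.0, abs=1e-9)
            peak = basis.components[0].max()
            assert result.amplitudes["CSpUSm"] == pytest.approx(1.3 * peak, rel=1e-6)

    def test_extended_us_recovery_with_reinforced_trials(self, small_paradigm):
        paradigm = pg.generate_paradigm(small_paradigm, 4)
        sim = pg.SimulationSpec(
            cs_plus_amplitude=1.3, cs_minus_amplitude=0.4, us_amplitude=0.9,
            noise_sd=0.0, missing_rate=0.0,
        )
        sessions, _ = pg.simulate_participant(paradigm, sim, SR, 4)
        basis = basis_for("extended_us")
        us_basis = pg.basis_set(pg.us_params_relative_to_us(), SR)
        result = pg.fit_participant(sessions, basis, "extended_us", us_basis)
        assert result.amplitudes["CSp"] == pytest.approx(1.3, rel=1e-6)
        assert result.amplitudes["CSm"] == pytest.approx(0.4, rel=1e-6)
        assert result.amplitudes["USp"] == pytest.approx(0.9, rel=1e-6)
        assert result.amplitudes["USm_CSpUSm"] == pytest.approx(0.0, abs=1e-6)
        assert result.amplitudes["USm_CSm"] == pytest.approx(0.0, abs=1e-6)

    def test_contrast_invariant_to_common_cs_component(self, unreinforced_paradigm):
        # adding the same response to every CS leaves CS+ minus CS- unchanged
        paradigm = pg.generate_paradigm(unreinforced_paradigm, 5)
        basis = basis_for("cs_only")
        results = []
        for common in (0.0, 0.7):
            sim = pg.SimulationSpec(
                cs_plus_amplitude=1.3 + common,
                cs_minus_amplitude=0.4 + common,
                noise_sd=0.0, missing_rate=0.0,
            )
            sessions, _ = pg.simulate_participant(paradigm, sim, SR, 5)
            res = pg.fit_participant(sessions, basis, "cs_only")
            results.append(res.amplitudes["CSpUSm"] - res.amplitudes["CSm"])
        assert results[0] == pytest.approx(results[1], abs=1e-9)

    def test_null_omission_betas_statistically_indistinguishable(self):
        # generator plants no omission response; across replicates the two
        # US-omission betas should not differ (alpha = 0.01)
        spec = pg.ParadigmSpec(n_cspusp=4, n_cspusm=4, n_csm=8, sessions=1)
        sim = pg.SimulationSpec(noise_sd=0.3, missing_rate=0.0)
        basis = basis_for("extended_us", sr=50.0)
        us_basis = pg.basis_set(pg.us_params_relative_to_us(), 50.0)
        diffs = []
        root = np.random.default_rng(11)
        for _ in range(100):
            rng = np.random.default_rng(root.integers(2**31))
            paradigm = pg.generate_paradigm(spec, rng)
            sessions, _ = pg.simulate_participant(paradigm, sim, 50.0, rng)
            res = pg.fit_participant(sessions, basis, "extended_us", us_basis)
            diffs.append(res.beta("USm_CSpUSm") - res.beta("USm_CSm"))
        t, p = stats.ttest_1samp(diffs, 0.0)
        assert p > 0.01
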