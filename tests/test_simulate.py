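"""Generator contracts: determinism, state semantics, occupancy, presets."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import lognorm

from psgpipe import (
    CohortDesign,
    EffectProfile,
    GroundTruth,
    Hypnogram,
    NREM,
    REM,
    WAKE,
    generate_cohort,
    sample_hypnogram,
    synthesize_signals,
)
from psgpipe.simulate import (
    ChainConfig,
    StateParams,
    default_state_params,
    validate_state_params,
)

from oracles import latency as oracle_latency


def small_design(**kw):
    kw.setdefault("n_per_group", 1)
    kw.setdefault("cells", (("TH", "Veh"),))
    kw.setdefault("duration_hours", 1.0)
    kw.setdefault("seed", 7)
    return CohortDesign(**kw)


class TestSampleHypnogram:
    def test_degenerate_all_wake_chain(self):
        """An un-ending initial wake dwell yields a pure-wake record."""
        design = small_design(
            duration_hours=80.0 / 3600.0,
            effects={("TH", "Veh"): EffectProfile(initial_wake_mean=1e9)},
        )
        truth = sample_hypnogram(design, ("TH", "Veh"), 0)
        assert truth.hypnogram.n_epochs == 10
        assert (truth.hypnogram.states == WAKE).all()

    def test_same_seed_reproduces_exactly(self):
        design = small_design(duration_hours=4.0)
        a = sample_hypnogram(design, ("TH", "Veh"), 3)
        b = sample_hypnogram(design, ("TH", "Veh"), 3)
        np.testing.assert_array_equal(a.hypnogram.states, b.hypnogram.states)

    def test_states_only_from_three_value_set(self):
        design = small_design(duration_hours=8.0, cells=(("CC", "DIPH"),))
        truth = sample_hypnogram(design, ("CC", "DIPH"), 0)
        assert set(np.unique(truth.hypnogram.states)) <= {WAKE, NREM, REM}

    def test_rem_never_entered_from_wake(self):
        design = small_design(duration_hours=8.0, n_per_group=4)
        for i in range(4):
            s = sample_hypnogram(design, ("TH", "Veh"), i).hypnogram.states
            prev = s[:-1][np.diff(s.astype(int)) != 0]
            nxt = s[1:][np.diff(s.astype(int)) != 0]
            assert not ((prev == WAKE) & (nxt == REM)).any()

    def test_invalid_state_set_rejected(self):
        params = default_state_params()
        del params[REM]
        with pytest.raises(ValueError, match="missing"):
            small_design(state_params=params)
        with pytest.raises(ValueError):
            small_design(duration_hours=-1.0)

    def test_cage_change_prolongs_time_to_sleep_onset(self):
        """Monte-Carlo over the preset dwell laws: mean latency CC > TH."""
        design = CohortDesign(
            n_per_group=1,
            cells=(("TH", "Veh"), ("CC", "Veh")),
            duration_hours=8.0,
            seed=11,
        )
        means = {}
        for cell in design.cells:
            lats = []
            for i in range(150):
                states = sample_hypnogram(design, cell, i).hypnogram.states
                lat = oracle_latency(states)
                lats.append(lat if lat is not None else 8 * 3600.0)
            means[cell] = np.mean(lats)
        assert means[("CC", "Veh")] > means[("TH", "Veh")]

    def test_occupancy_matches_embedded_chain_stationary_distribution(self):
        """Long-run state fractions match a brute-force semi-Markov computation.

        Oracle: stationary distribution of the embedded 4-state chain
        (long wake, brief wake, NREM, REM) weighted by the expected
        epoch-rounded log-normal dwells, computed by direct linear
        algebra and numerical summation of the dwell CDF.
        """
        chain = ChainConfig(
            dark_wake_dwell_mult=1.0, dark_nrem_dwell_mult=1.0, dark_rem_dwell_mult=1.0
        )
        design = CohortDesign(
            n_per_group=6,
            cells=(("TH", "Veh"),),
            duration_hours=24.0,
            seed=5,
            chain=chain,
            effects={("TH", "Veh"): EffectProfile(initial_wake_mean=180.0)},
        )
        sp = design.state_params

        def mean_dwell_epochs(mean, shape):
            mu = np.log(mean) - shape**2 / 2
            dist = lognorm(s=shape, scale=np.exp(mu))
            ks = np.arange(1, 4000)
            # E[max(1, ceil(X/8))] = sum_k P(ceil > k), offset by 1
            return 1 + np.sum(1 - dist.cdf(ks * 8.0))

        p_r, p_b = chain.p_nrem_to_rem, chain.p_nrem_to_brief_wake
        p_l = 1 - p_r - p_b
        # embedded transition matrix over (Wlong, Wbrief, N, R)
        P = np.array(
            [
                [0, 0, 1, 0],
                [0, 0, 1, 0],
                [p_l, p_b, 0, p_r],
                [chain.p_rem_to_wake, 0, 1 - chain.p_rem_to_wake, 0],
            ]
        )
        evals, evecs = np.linalg.eig(P.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi /= pi.sum()
        d = np.array(
            [
                mean_dwell_epochs(sp[WAKE].dwell_mean, sp[WAKE].dwell_shape),
                mean_dwell_epochs(chain.brief_wake_mean, chain.brief_wake_shape),
                mean_dwell_epochs(sp[NREM].dwell_mean, sp[NREM].dwell_shape),
                mean_dwell_epochs(sp[REM].dwell_mean, sp[REM].dwell_shape),
            ]
        )
        occ = pi * d / (pi * d).sum()
        expected = {WAKE: occ[0] + occ[1], NREM: occ[2], REM: occ[3]}

        counts = np.zeros(3)
        for i in range(design.n_per_group):
            s = sample_hypnogram(design, ("TH", "Veh"), i).hypnogram.states
            counts += np.bincount(s, minlength=3)
        frac = counts / counts.sum()
        for st in (WAKE, NREM, REM):
            assert frac[st] == pytest.approx(expected[st], abs=0.04)


class TestStateParams:
    def test_defaults_encode_staging_contrasts(self):
        validate_state_params(default_state_params())

    def test_violated_contrast_rejected(self):
        params = default_state_params()
        params[NREM].band_amplitudes["delta"] = 0.1
        with pytest.raises(ValueError, match="delta"):
            validate_state_params(params)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            StateParams(WAKE, {"delta": -1.0}, emg_amplitude=1.0, dwell_mean=10.0)


class TestSynthesizeSignals:
    def test_zero_amplitudes_zero_signals(self):
        params = {
            s: StateParams(s, {b: 0.0 for b in ("delta", "theta", "sigma", "beta")},
                           emg_amplitude=0.0, dwell_mean=60.0)
            for s in (WAKE, NREM, REM)
        }
        # contrast validation is about defaults; bypass it via direct call
        hyp = Hypnogram(np.zeros(10, dtype=np.int8))
        truth = GroundTruth(hyp, ("TH", "Veh"), 0)
        import psgpipe.simulate as sim

        orig = sim.validate_state_params
        sim.validate_state_params = lambda p: None
        try:
            rec = synthesize_signals(
                truth, params, rng_seed=3, background_amplitude=0.0, emg_floor=0.0
            )
        finally:
            sim.validate_state_params = orig
        assert not rec.eeg.any() and not rec.emg.any()

    def test_wake_epochs_have_higher_emg_power(self, short_recording):
        rec, truth = short_recording
        from psgpipe import emg_band_power

        p = emg_band_power(rec.emg, rec.emg_rate)
        s = truth.hypnogram.states[: p.size]
        assert np.median(p[s == WAKE]) > 5 * np.median(p[s != WAKE])

    def test_nrem_delta_exceeds_sigma_with_10x_amplitude(self):
        """Independent periodogram oracle on an NREM-only record."""
        params = default_state_params()
        params[NREM].band_amplitudes.update({"delta": 10.0, "sigma": 1.0})
        hyp = Hypnogram(np.full(75, NREM, dtype=np.int8))
        rec = synthesize_signals(GroundTruth(hyp, ("TH", "Veh"), 0), params, rng_seed=5)
        f, p = sps.periodogram(rec.eeg, rec.eeg_rate)
        delta = p[(f >= 0.16) & (f < 4)].sum()
        sigma = p[(f >= 10) & (f < 14)].sum()
        assert delta > 10 * sigma

    def test_doubling_amplitudes_quadruples_band_powers(self):
        from psgpipe import eeg_band_powers
        from psgpipe.spectral import EEG_BANDS

        base = default_state_params()
        doubled = default_state_params()
        for s in doubled.values():
            s.band_amplitudes = {b: 2 * a for b, a in s.band_amplitudes.items()}
        hyp = Hypnogram(np.full(75, NREM, dtype=np.int8))
        truth = GroundTruth(hyp, ("TH", "Veh"), 0)
        kw = dict(rng_seed=9, background_amplitude=0.0, emg_floor=0.0)
        a = eeg_band_powers(synthesize_signals(truth, base, **kw).eeg, 125.0)
        b = eeg_band_powers(synthesize_signals(truth, doubled, **kw).eeg, 125.0)
        np.testing.assert_allclose(
            4 * a[list(EEG_BANDS)].to_numpy(), b[list(EEG_BANDS)].to_numpy(), rtol=1e-9
        )

    def test_missing_state_params_raise(self):
        hyp = Hypnogram(np.zeros(10, dtype=np.int8))
        params = default_state_params()
        del params[REM]
        with pytest.raises(ValueError, match="missing"):
            synthesize_signals(GroundTruth(hyp, ("TH", "Veh"), 0), params)

    def test_quantization_bounds_error_by_step(self):
        hyp = Hypnogram(np.zeros(75, dtype=np.int8))
        truth = GroundTruth(hyp, ("TH", "Veh"), 0)
        raw = synthesize_signals(truth, rng_seed=1)
        q = synthesize_signals(truth, rng_seed=1, quantize_bits=12, full_scale=30.0)
        step = 2 * 30.0 / 2**12
        assert np.abs(raw.eeg - q.eeg).max() <= step / 2 + 1e-12


class TestGenerateCohort:
    def test_two_animals_distinct_streams(self):
        design = small_design(n_per_group=2, duration_hours=0.5)
        animals, manifest = generate_cohort(design, with_signals=False)
        assert len(animals) == 2 and len(manifest) == 2
        a, b = animals[0][1], animals[1][1]
        assert a.seed != b.seed
        assert not np.array_equal(a.hypnogram.states, b.hypnogram.states)

    def test_full_six_cell_design_bookkeeping(self):
        design = CohortDesign(n_per_group=8, duration_hours=8.0 / 60.0, seed=2)
        animals, manifest = generate_cohort(design, with_signals=False)
        assert len(animals) == 48
        assert len(manifest) == 48
        assert manifest["animal_id"].is_unique

    def test_identical_designs_identical_outputs(self):
        design = small_design(n_per_group=2, duration_hours=0.2)
        (rec_a, tr_a), _ = generate_cohort(design)[0][0], None
        (rec_b, tr_b), _ = generate_cohort(design)[0][0], None
        np.testing.assert_array_equal(tr_a.hypnogram.states, tr_b.hypnogram.states)
        np.testing.assert_array_equal(rec_a.eeg, rec_b.eeg)
        np.testing.assert_array_equal(rec_a.emg, rec_b.emg)
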