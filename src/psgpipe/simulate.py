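"""Synthetic polysomnography: ground-truth hypnograms and matching signals.

The generator inverts the staging rules into a generative model. A
semi-Markov chain on {WAKE, NREM, REM} emits state dwells (log-normal,
rounded up to whole 8-s epochs), and each state stamps its spectral
signature onto the signals: NREM is delta-dominant with low muscle
tone, REM is theta-dominant with atonia, wake has low-voltage broadband
EEG and high EMG. REM is entered only from NREM; wake is reachable from
both (standard rodent sleep physiology).

Two wake flavours share the WAKE output code: *brief* wake (seconds to
tens of seconds, the substrate of NREM interruptions) and *long* wake
(consolidated bouts). Sleep pressure follows a two-regime light/dark
switch at ZT 12, and a cage-change design adds a first-night-effect
(FNE): a long initial wake dwell at ZT 0, lengthened wake / shortened
NREM dwells and suppressed REM entry over the early light phase.
Treatment presets modify this: a probiotic-like arm shortens the FNE
initial wake dwell; an antihistamine-like arm shortens REM dwells,
suppresses REM entry and raises the brief-wake (fragmentation) rate.

Signal amplitudes are in arbitrary units: the acquisition chain's
1000x gain is not modelled and staging only uses relative comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .spectral import EEG_BANDS, EMG_BAND
from .states import EPOCH_SECONDS, NREM, REM, WAKE, Hypnogram, PSGRecording

# internal (extended) chain states
_W_LONG, _W_BRIEF, _N, _R = 0, 1, 2, 3
_OUTPUT_CODE = {_W_LONG: WAKE, _W_BRIEF: WAKE, _N: NREM, _R: REM}

LIGHT_SECONDS = 12 * 3600.0  # ZT 0-12 is the light phase
DAY_SECONDS = 24 * 3600.0


@dataclass
class StateParams:
    """Spectral signature and dwell law of one vigilance state.

    band_amplitudes are per-band EEG component amplitudes (arbitrary
    units); emg_amplitude scales the 32-64 Hz EMG component. Dwells are
    log-normal with arithmetic mean ``dwell_mean`` seconds and log-sd
    ``dwell_shape``, rounded up to whole epochs (minimum one).
    """

    state: int
    band_amplitudes: dict[str, float]
    emg_amplitude: float
    dwell_mean: float
    dwell_shape: float = 0.6

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.band_amplitudes.values()) or self.emg_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be positive")


def default_state_params() -> dict[int, StateParams]:
    """Default spectral signatures.

    Chosen so the staging discriminants separate cleanly: NREM delta
    dominates wake and REM delta; wake EMG dominates NREM >= REM EMG
    (REM atonia); sigma*theta power is higher in both sleep states than
    in wake.
    """
    return {
        WAKE: StateParams(
            WAKE,
            {"delta": 1.0, "theta": 1.2, "sigma": 0.6, "beta": 1.0},
            emg_amplitude=3.0,
            dwell_mean=180.0,
            dwell_shape=0.9,
        ),
        NREM: StateParams(
            NREM,
            {"delta": 4.0, "theta": 1.5, "sigma": 1.5, "beta": 0.5},
            emg_amplitude=0.8,
            dwell_mean=200.0,
            dwell_shape=1.0,
        ),
        REM: StateParams(
            REM,
            {"delta": 0.8, "theta": 3.0, "sigma": 1.2, "beta": 0.6},
            emg_amplitude=0.3,
            dwell_mean=64.0,
            dwell_shape=0.4,
        ),
    }


def validate_state_params(params: dict[int, StateParams]) -> None:
    """Check the generative model encodes the staging contrasts."""
    missing = {WAKE, NREM, REM} - set(params)
    if missing:
        raise ValueError(f"state parameters missing for states {sorted(missing)}")
    w, n, r = params[WAKE], params[NREM], params[REM]
    a = lambda p, b: p.band_amplitudes[b]  # noqa: E731
    if not (a(n, "delta") > a(w, "delta") and a(n, "delta") > a(r, "delta")):
        raise ValueError("NREM delta amplitude must dominate wake and REM")
    if not (w.emg_amplitude > n.emg_amplitude >= r.emg_amplitude):
        raise ValueError("EMG amplitudes must order wake > NREM >= REM")
    st = lambda p: (a(p, "sigma") * a(p, "theta")) ** 2  # noqa: E731  (power product)
    if not (st(n) > st(w) and st(r) > st(w)):
        raise ValueError("sleep sigma*theta power must exceed the wake value")


@dataclass
class EffectProfile:
    """Group-level modifiers of the baseline chain.

    ``initial_wake_mean`` is the mean of the dwell starting the record
    (the cage-change manipulation inflates it). The ``fne_*`` fields
    apply while ZT < ``fne_hours``; the remaining fields apply for the
    whole recording.
    """

    initial_wake_mean: float = 600.0
    initial_wake_shape: float = 0.5
    fne_hours: float = 0.0
    fne_wake_dwell_mult: float = 1.0
    fne_nrem_dwell_mult: float = 1.0
    fne_rem_entry_mult: float = 1.0
    rem_dwell_mult: float = 1.0
    rem_entry_mult: float = 1.0
    brief_wake_mult: float = 1.0


#: (handling, treatment) -> EffectProfile. Handling: TH tail-handled
#: control, CC cage change (FNE). Treatment: Veh vehicle, DIPH
#: antihistamine-like, PS150 probiotic-like.
PRESETS: dict[tuple[str, str], EffectProfile] = {
    ("TH", "Veh"): EffectProfile(),
    ("CC", "Veh"): EffectProfile(
        initial_wake_mean=4000.0,
        fne_hours=4.0,
        fne_wake_dwell_mult=2.5,
        fne_nrem_dwell_mult=0.55,
        fne_rem_entry_mult=0.25,
    ),
    ("TH", "PS150"): EffectProfile(initial_wake_mean=300.0),
    ("CC", "PS150"): EffectProfile(
        initial_wake_mean=1200.0,
        fne_hours=4.0,
        fne_wake_dwell_mult=2.5,
        fne_nrem_dwell_mult=0.55,
        fne_rem_entry_mult=0.25,
    ),
    ("TH", "DIPH"): EffectProfile(
        rem_dwell_mult=0.45,
        rem_entry_mult=0.4,
        brief_wake_mult=2.0,
    ),
    ("CC", "DIPH"): EffectProfile(
        initial_wake_mean=1500.0,
        fne_hours=4.0,
        fne_wake_dwell_mult=1.3,
        fne_nrem_dwell_mult=0.9,
        fne_rem_entry_mult=0.25,
        rem_dwell_mult=0.45,
        rem_entry_mult=0.4,
        brief_wake_mult=2.0,
    ),
}

HANDLINGS = ("TH", "CC")
TREATMENTS = ("Veh", "DIPH", "PS150")


@dataclass
class ChainConfig:
    """Baseline semi-Markov chain (light-phase values).

    From NREM the chain exits to REM, brief wake or long wake with the
    given probabilities (renormalised after effect multipliers); from
    REM to wake or back to NREM; wake always yields to NREM. Dark-phase
    sleep pressure is lower: wake dwells stretch and sleep dwells
    shrink by the ``dark_*`` multipliers (two-regime switch at ZT 12).
    """

    p_nrem_to_rem: float = 0.25
    p_nrem_to_brief_wake: float = 0.35
    p_rem_to_wake: float = 0.6
    brief_wake_mean: float = 16.0
    brief_wake_shape: float = 0.4
    dark_wake_dwell_mult: float = 5.0
    dark_nrem_dwell_mult: float = 0.7
    dark_rem_dwell_mult: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.p_nrem_to_rem + self.p_nrem_to_brief_wake <= 1:
            raise ValueError("NREM exit probabilities must sum to at most 1")
        if not 0 <= self.p_rem_to_wake <= 1:
            raise ValueError("p_rem_to_wake must lie in [0, 1]")


@dataclass
class CohortDesign:
    """One simulated experiment: which cells, how many animals, how long."""

    n_per_group: int = 8
    cells: tuple[tuple[str, str], ...] = tuple(PRESETS)
    duration_hours: float = 8.0
    zt_start: float = 0.0
    seed: int = 0
    state_params: dict[int, StateParams] = field(default_factory=default_state_params)
    chain: ChainConfig = field(default_factory=ChainConfig)
    effects: dict[tuple[str, str], EffectProfile] | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.duration_hours <= 0:
            raise ValueError("duration must be positive")
        for cell in self.cells:
            if cell not in PRESETS and (self.effects is None or cell not in self.effects):
                raise ValueError(f"unknown design cell {cell!r}")
        validate_state_params(self.state_params)

    def effect_for(self, cell: tuple[str, str]) -> EffectProfile:
        if self.effects is not None and cell in self.effects:
            return self.effects[cell]
        return PRESETS[cell]


@dataclass
class GroundTruth:
    """A sampled hypnogram plus everything needed to regenerate it."""

    hypnogram: Hypnogram
    cell: tuple[str, str]
    seed: int


def _lognormal_dwell(rng: np.random.Generator, mean: float, shape: float) -> float:
    """Draw from a log-normal with arithmetic mean `mean` and log-sd `shape`."""
    mu = math.log(mean) - 0.5 * shape**2
    return float(rng.lognormal(mu, shape))


def _dwell_epochs(rng, mean, shape, epoch_seconds) -> int:
    return max(1, math.ceil(_lognormal_dwell(rng, mean, shape) / epoch_seconds))


def _is_light(zt_seconds: float) -> bool:
    return (zt_seconds % DAY_SECONDS) < LIGHT_SECONDS


def sample_hypnogram(
    design: CohortDesign,
    cell: tuple[str, str],
    animal_index: int = 0,
    rng_seed: int | None = None,
    animal_id: str = "",
) -> GroundTruth:
    """Sample one animal's ground-truth hypnogram.

    Deterministic in (design.seed or rng_seed, cell, animal_index). A
    cage-change cell starts with a wake dwell drawn from the inflated
    FNE distribution; tail-handled cells start with a normal-length
    wake dwell (every record begins awake: the animal was just handled).
    """
    n_epochs_total = round(design.duration_hours * 3600.0 / EPOCH_SECONDS)
    if abs(n_epochs_total * EPOCH_SECONDS - design.duration_hours * 3600.0) > 1e-9:
        raise ValueError("duration must be a whole number of 8-s epochs")
    if rng_seed is None:
        cell_idx = list(design.cells).index(cell)
        rng_seed = np.random.SeedSequence(
            entropy=design.seed, spawn_key=(cell_idx, animal_index)
        )
    rng = np.random.default_rng(rng_seed)
    eff = design.effect_for(cell)
    chain = design.chain
    sp = design.state_params

    states = np.empty(n_epochs_total, dtype=np.int8)
    pos = 0
    current = _W_LONG
    first = True
    while pos < n_epochs_total:
        zt = design.zt_start + pos * EPOCH_SECONDS
        light = _is_light(zt)
        in_fne = zt < eff.fne_hours * 3600.0

        # dwell for the current internal state
        if current == _W_BRIEF:
            mean, shape = chain.brief_wake_mean, chain.brief_wake_shape
        else:
            out = _OUTPUT_CODE[current]
            mean, shape = sp[out].dwell_mean, sp[out].dwell_shape
            if first and current == _W_LONG:
                mean, shape = eff.initial_wake_mean, eff.initial_wake_shape
            elif out == WAKE and not light:
                mean *= chain.dark_wake_dwell_mult
            elif out == NREM and not light:
                mean *= chain.dark_nrem_dwell_mult
            elif out == REM and not light:
                mean *= chain.dark_rem_dwell_mult
            if in_fne and not first:
                if out == WAKE:
                    mean *= eff.fne_wake_dwell_mult
                elif out == NREM:
                    mean *= eff.fne_nrem_dwell_mult
            if out == REM:
                mean *= eff.rem_dwell_mult
        first = False
        n = min(_dwell_epochs(rng, mean, shape, EPOCH_SECONDS), n_epochs_total - pos)
        states[pos : pos + n] = _OUTPUT_CODE[current]
        pos += n

        # next internal state
        if current in (_W_LONG, _W_BRIEF):
            current = _N
        elif current == _N:
            w_rem = chain.p_nrem_to_rem * eff.rem_entry_mult
            if in_fne:
                w_rem *= eff.fne_rem_entry_mult
            w_brief = chain.p_nrem_to_brief_wake * eff.brief_wake_mult
            w_long = 1.0 - chain.p_nrem_to_rem - chain.p_nrem_to_brief_wake
            w = np.array([w_long, w_brief, 0.0, w_rem])
            total = w.sum()
            if total <= 0:
                raise ValueError("NREM exit probabilities are unnormalizable")
            current = int(rng.choice(4, p=w / total))
        else:  # REM
            current = _W_LONG if rng.random() < chain.p_rem_to_wake else _N
    hyp = Hypnogram(
        states,
        zt_start=design.zt_start,
        animal_id=animal_id,
        handling=cell[0],
        treatment=cell[1],
    )
    return GroundTruth(hypnogram=hyp, cell=cell, seed=_seed_repr(rng_seed))


def _seed_repr(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0])
    return int(seed)


def _band_limited_noise(rng, n, fs, lo, hi, order=4) -> np.ndarray:
    """Unit-RMS noise confined to [lo, hi] Hz."""
    x = rng.standard_normal(n)
    sos = sps.butter(order, [lo, min(hi, fs / 2 * 0.999)], "bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    s = y.std()
    return y / s if s > 0 else y


def _pink_noise(rng, n) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via FFT shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = np.inf
    y = np.fft.irfft(spec / np.sqrt(f), n)
    s = y.std()
    return y / s if s > 0 else y


def _amplitude_envelope(per_epoch: np.ndarray, fs: float, fade_seconds: float = 0.5):
    """Per-sample envelope with a linear cross-fade at epoch boundaries."""
    env = np.repeat(per_epoch, int(round(EPOCH_SECONDS * fs)))
    k = int(round(fade_seconds * fs))
    if k > 1:
        env = uniform_filter1d(env, size=k, mode="nearest")
    return env


def synthesize_signals(
    truth: GroundTruth,
    state_params: dict[int, StateParams] | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
    background_amplitude: float = 0.25,
    emg_floor: float = 0.05,
    eeg_rate: float = 125.0,
    emg_rate: float = 250.0,
    quantize_bits: int | None = None,
    full_scale: float = 30.0,
) -> PSGRecording:
    """Render EEG/EMG traces for a ground-truth hypnogram.

    Per epoch the EEG is a sum of band-limited unit-RMS noise
    components (one per scoring band) scaled by the state's band
    amplitudes, over a low-level 1/f background; the EMG is 32-64 Hz
    noise scaled by the state's EMG amplitude over a small broadband
    floor. Amplitude envelopes cross-fade linearly over 0.5 s at epoch
    boundaries (real transitions are not instantaneous, and hard steps
    would splatter power across bands). Optional uniform quantization
    emulates the 12-bit acquisition.
    """
    state_params = default_state_params() if state_params is None else state_params
    validate_state_params(state_params)
    hyp = truth.hypnogram
    rng = np.random.default_rng(rng_seed)
    n_eeg = int(round(hyp.n_epochs * EPOCH_SECONDS * eeg_rate))
    n_emg = int(round(hyp.n_epochs * EPOCH_SECONDS * emg_rate))

    eeg = np.zeros(n_eeg)
    for band, (lo, hi) in EEG_BANDS.items():
        amps = np.array(
            [state_params[int(s)].band_amplitudes[band] for s in hyp.states]
        )
        if not amps.any():
            continue
        noise = _band_limited_noise(rng, n_eeg, eeg_rate, lo, hi)
        eeg += _amplitude_envelope(amps, eeg_rate) * noise
    if background_amplitude > 0:
        eeg += background_amplitude * _pink_noise(rng, n_eeg)

    emg_amps = np.array([state_params[int(s)].emg_amplitude for s in hyp.states])
    emg = np.zeros(n_emg)
    if emg_amps.any():
        emg = _amplitude_envelope(emg_amps, emg_rate) * _band_limited_noise(
            rng, n_emg, emg_rate, *EMG_BAND
        )
    if emg_floor > 0:
        emg = emg + emg_floor * rng.standard_normal(n_emg)

    if quantize_bits:
        eeg = _quantize(eeg, quantize_bits, full_scale)
        emg = _quantize(emg, quantize_bits, full_scale)

    return PSGRecording(
        eeg=eeg,
        emg=emg,
        eeg_rate=eeg_rate,
        emg_rate=emg_rate,
        zt_start=hyp.zt_start,
        animal_id=hyp.animal_id,
        handling=hyp.handling,
        treatment=hyp.treatment,
    )


def _quantize(x: np.ndarray, bits: int, full_scale: float) -> np.ndarray:
    levels = 2**bits
    step = 2.0 * full_scale / levels
    return np.clip(np.round(x / step), -levels // 2, levels // 2 - 1) * step


def generate_cohort(
    design: CohortDesign,
    with_signals: bool = True,
    **signal_kwargs,
) -> tuple[list[tuple[PSGRecording | None, GroundTruth]], pd.DataFrame]:
    """Simulate every animal in the design.

    Per-animal random streams are derived from (design.seed, cell
    index, animal index), so adding animals or cells never reshuffles
    existing ones. Returns the animals plus a manifest table
    (animal_id, handling, treatment, seed).
    """
    animals: list[tuple[PSGRecording | None, GroundTruth]] = []
    rows = []
    for ci, cell in enumerate(design.cells):
        for ai in range(design.n_per_group):
            animal_id = f"{cell[0]}-{cell[1]}-{ai:02d}"
            ss = np.random.SeedSequence(entropy=design.seed, spawn_key=(ci, ai))
            hyp_seed, sig_seed = ss.spawn(2)
            truth = sample_hypnogram(
                design, cell, ai, rng_seed=hyp_seed, animal_id=animal_id
            )
            rec = (
                synthesize_signals(truth, design.state_params, rng_seed=sig_seed,
                                   **signal_kwargs)
                if with_signals
                else None
            )
            animals.append((rec, truth))
            rows.append(
                {
                    "animal_id": animal_id,
                    "handling": cell[0],
                    "treatment": cell[1],
                    "seed": truth.seed,
                }
            )
    return animals, pd.DataFrame(rows)
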