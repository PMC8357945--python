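"""Vigilance-state codes and the core hypnogram container.

Three vigilance states are scored on a fixed 8-s epoch grid aligned to
Zeitgeber time (ZT 0 = lights on). Wake shows high muscle tone and
low-voltage mixed EEG, NREM sleep shows high delta (slow-wave) power,
and REM sleep shows theta-dominant EEG with muscle atonia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WAKE: int = 0
NREM: int = 1
REM: int = 2

STATE_CODES = (WAKE, NREM, REM)
STATE_NAMES = {WAKE: "W", NREM: "N", REM: "R"}
STATE_LONG_NAMES = {WAKE: "WAKE", NREM: "NREM", REM: "REM"}
NAME_TO_CODE = {v: k for k, v in STATE_NAMES.items()}
NAME_TO_CODE.update({v: k for k, v in STATE_LONG_NAMES.items()})

#: scoring epoch length, seconds
EPOCH_SECONDS: float = 8.0


@dataclass
class Hypnogram:
    """Sequence of scored vigilance states on the 8-s epoch grid.

    Parameters
    ----------
    states : ndarray of int8
        One state code per epoch, values in ``{WAKE, NREM, REM}``.
    epoch_seconds : float
        Scoring epoch length (default 8 s).
    zt_start : float
        Zeitgeber time of epoch 0, in seconds from lights-on.
    animal_id, handling, treatment : str
        Subject and group labels carried through the pipeline.
    """

    states: np.ndarray
    epoch_seconds: float = EPOCH_SECONDS
    zt_start: float = 0.0
    animal_id: str = ""
    handling: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1:
            raise ValueError("hypnogram states must be one-dimensional")
        bad = ~np.isin(self.states, STATE_CODES)
        if bad.any():
            raise ValueError(
                f"invalid state codes {np.unique(self.states[bad])!r}; "
                f"allowed: {STATE_CODES}"
            )

    def __len__(self) -> int:
        return self.states.size

    @property
    def n_epochs(self) -> int:
        return self.states.size

    @property
    def duration_seconds(self) -> float:
        return self.states.size * self.epoch_seconds

    @property
    def zt_seconds(self) -> np.ndarray:
        """ZT of each epoch start, seconds."""
        return self.zt_start + np.arange(self.states.size) * self.epoch_seconds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(self.states.size),
                "zt_seconds": self.zt_seconds,
                "state": [STATE_NAMES[int(s)] for s in self.states],
            }
        )

    @classmethod
    def from_labels(cls, labels, **kwargs) -> "Hypnogram":
        """Build from 'W'/'N'/'R' (or long-name) labels."""
        codes = np.array([NAME_TO_CODE[str(lab)] for lab in labels], dtype=np.int8)
        return cls(codes, **kwargs)


@dataclass
class PSGRecording:
    """Raw two-channel polysomnogram: EEG at 125 Hz and EMG at 250 Hz.

    Amplitudes are in arbitrary units (the acquisition chain's gain is
    not modelled); all staging decisions use relative comparisons, so
    the absolute scale is immaterial.
    """

    eeg: np.ndarray
    emg: np.ndarray
    eeg_rate: float = 125.0
    emg_rate: float = 250.0
    zt_start: float = 0.0
    animal_id: str = ""
    handling: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg_rate <= 0 or self.emg_rate <= 0:
            raise ValueError("sampling rates must be strictly positive")
        d_eeg = self.eeg.size / self.eeg_rate
        d_emg = self.emg.size / self.emg_rate
        if abs(d_eeg - d_emg) > EPOCH_SECONDS:
            raise ValueError(
                f"EEG ({d_eeg:.1f} s) and EMG ({d_emg:.1f} s) durations "
                "differ by more than one epoch"
            )

    @property
    def duration_seconds(self) -> float:
        return min(self.eeg.size / self.eeg_rate, self.emg.size / self.emg_rate)

    @property
    def group(self) -> tuple[str, str]:
        return (self.handling, self.treatment)
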