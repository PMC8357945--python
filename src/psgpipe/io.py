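"""File formats: delimited text for every intermediate, plus EDF signals.

All pipeline intermediates (recordings, band-power tables, hypnograms,
manifests, threshold models) are plain text so run directories diff
cleanly. Signals can additionally be written as EDF (European Data
Format, 16-bit): the writer emits a minimal two-channel EDF directly
(EEG at 125 Hz, EMG at 250 Hz, 1-s data records); reading EDF goes
through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .staging import ThresholdStager
from .states import NAME_TO_CODE, Hypnogram, PSGRecording

# ---------------------------------------------------------------- recordings


def write_recording_csv(path, rec: PSGRecording) -> None:
    """Delimited fallback format: time, eeg, emg at the EMG clock.

    Rows advance at the (faster) EMG rate; EEG cells are empty except
    at EEG sample times. Metadata rides in ``#``-prefixed header lines.
    """
    path = Path(path)
    step = int(round(rec.emg_rate / rec.eeg_rate))
    n = rec.emg.size
    t = np.arange(n) / rec.emg_rate
    eeg_col = np.full(n, np.nan)
    m = min(eeg_col[::step].size, rec.eeg.size)
    eeg_col[::step][:m] = rec.eeg[:m]
    with open(path, "w") as fh:
        fh.write(f"# eeg_rate={rec.eeg_rate}\n# emg_rate={rec.emg_rate}\n")
        fh.write(f"# zt_start={rec.zt_start}\n# animal_id={rec.animal_id}\n")
        fh.write(f"# handling={rec.handling}\n# treatment={rec.treatment}\n")
        pd.DataFrame({"time": t, "eeg": eeg_col, "emg": rec.emg}).to_csv(
            fh, index=False, float_format="%.6g"
        )


def _read_meta(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    return meta


def read_recording_csv(path) -> PSGRecording:
    meta = _read_meta(path)
    tab = pd.read_csv(path, comment="#")
    return PSGRecording(
        eeg=tab["eeg"].dropna().to_numpy(float),
        emg=tab["emg"].to_numpy(float),
        eeg_rate=float(meta.get("eeg_rate", 125.0)),
        emg_rate=float(meta.get("emg_rate", 250.0)),
        zt_start=float(meta.get("zt_start", 0.0)),
        animal_id=meta.get("animal_id", ""),
        handling=meta.get("handling", ""),
        treatment=meta.get("treatment", ""),
    )


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(path, rec: PSGRecording) -> None:
    """Write a two-channel 16-bit EDF file (1-s data records).

    Physical scaling is symmetric about zero at the channel's absolute
    maximum, so the quantization step is |max|/32767. Trailing partial
    seconds are dropped.
    """
    path = Path(path)
    fs = [rec.eeg_rate, rec.emg_rate]
    if any(abs(f - round(f)) > 1e-9 for f in fs):
        raise ValueError("EDF export requires integer samples per 1-s record")
    n_rec = int(min(rec.eeg.size / rec.eeg_rate, rec.emg.size / rec.emg_rate))
    chans = [rec.eeg[: n_rec * int(fs[0])], rec.emg[: n_rec * int(fs[1])]]
    labels = ["EEG", "EMG"]
    phys_max = [max(np.abs(c).max(), 1e-6) for c in chans]
    header = _io.BytesIO()
    header.write(_edf_field("0", 8))
    header.write(_edf_field(rec.animal_id or "X", 80))
    header.write(_edf_field(f"Startdate 01-JAN-2000 {rec.animal_id or 'X'}", 80))
    header.write(_edf_field("01.01.00", 8))
    header.write(_edf_field("00.00.00", 8))
    header.write(_edf_field(256 * (1 + len(chans)), 8))
    header.write(_edf_field("", 44))
    header.write(_edf_field(n_rec, 8))
    header.write(_edf_field(1, 8))
    header.write(_edf_field(len(chans), 4))
    for lab in labels:
        header.write(_edf_field(lab, 16))
    for _ in chans:
        header.write(_edf_field("", 80))  # transducer
    for _ in chans:
        header.write(_edf_field("uV", 8))
    for pm in phys_max:
        header.write(_edf_field(f"{-pm:.6g}"[:8], 8))
    for pm in phys_max:
        header.write(_edf_field(f"{pm:.6g}"[:8], 8))
    for _ in chans:
        header.write(_edf_field(-32768, 8))
    for _ in chans:
        header.write(_edf_field(32767, 8))
    for _ in chans:
        header.write(_edf_field("", 80))  # prefiltering
    for f in fs:
        header.write(_edf_field(int(f), 8))
    for _ in chans:
        header.write(_edf_field("", 32))
    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        digital = [
            np.clip(np.round(c / pm * 32767), -32768, 32767).astype("<i2")
            for c, pm in zip(chans, phys_max)
        ]
        for r in range(n_rec):
            for d, f in zip(digital, fs):
                f = int(f)
                fh.write(d[r * f : (r + 1) * f].tobytes())


def read_recording_edf(path, zt_start: float = 0.0, animal_id: str = "",
                       handling: str = "", treatment: str = "") -> PSGRecording:
    """Read a two-channel EEG/EMG EDF via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne upsamples lower-rate channels to the fastest rate by sample
    # repetition; recover native rates from the header's
    # samples-per-record fields and decimate accordingly
    with open(path, "rb") as fh:
        head = fh.read(256)
        ns = int(head[252:256])
        rec_dur = float(head[244:252])
        sig_head = fh.read(256 * ns)
    off = 216 * ns  # label..prefiltering fields precede samples-per-record
    n_samps = [int(sig_head[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
    native = {n.upper(): s / rec_dur for n, s in zip(raw.ch_names, n_samps)}
    names = [n.upper() for n in raw.ch_names]
    data = {}
    rates = {}
    for want in ("EEG", "EMG"):
        idx = next(i for i, n in enumerate(names) if want in n)
        full = raw.get_data()[idx] * 1e6  # mne scales to volts; undo
        step = int(round(raw.info["sfreq"] / native[names[idx]]))
        data[want] = full[::step]
        rates[want] = native[names[idx]]
    return PSGRecording(
        eeg=data["EEG"], emg=data["EMG"],
        eeg_rate=rates["EEG"], emg_rate=rates["EMG"],
        zt_start=zt_start, animal_id=animal_id,
        handling=handling, treatment=treatment,
    )


def read_recording(path, **kwargs) -> PSGRecording:
    """Dispatch on extension: .edf via mne, anything else as delimited text."""
    if str(path).lower().endswith(".edf"):
        return read_recording_edf(path, **kwargs)
    return read_recording_csv(path)


# ----------------------------------------------------------------- hypnogram


def write_hypnogram(path, hyp: Hypnogram) -> None:
    with open(path, "w") as fh:
        fh.write(f"# epoch_seconds={hyp.epoch_seconds}\n# zt_start={hyp.zt_start}\n")
        fh.write(f"# animal_id={hyp.animal_id}\n# handling={hyp.handling}\n")
        fh.write(f"# treatment={hyp.treatment}\n")
        hyp.to_frame().to_csv(fh, index=False)


def read_hypnogram(path) -> Hypnogram:
    meta = _read_meta(path)
    tab = pd.read_csv(path, comment="#")
    states = np.array([NAME_TO_CODE[s] for s in tab["state"]], dtype=np.int8)
    return Hypnogram(
        states,
        epoch_seconds=float(meta.get("epoch_seconds", 8.0)),
        zt_start=float(meta.get("zt_start", 0.0)),
        animal_id=meta.get("animal_id", ""),
        handling=meta.get("handling", ""),
        treatment=meta.get("treatment", ""),
    )


# ------------------------------------------------------- band powers, tables


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ------------------------------------------------------------------- staging


def save_thresholds(path, model: ThresholdStager) -> None:
    payload = {
        "emg_cut": model.emg_cut_,
        "st_cut": model.st_cut_,
        "delta_cut": model.delta_cut_,
        "params": model.get_params(),
        "diagnostics": model.diagnostics_,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_thresholds(path) -> ThresholdStager:
    payload = yaml.safe_load(Path(path).read_text())
    model = ThresholdStager(**payload.get("params", {}))
    model.emg_cut_ = float(payload["emg_cut"])
    model.st_cut_ = float(payload["st_cut"])
    model.delta_cut_ = float(payload["delta_cut"])
    model.diagnostics_ = payload.get("diagnostics", {})
    return model


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
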