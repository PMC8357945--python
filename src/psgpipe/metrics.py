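"""Sleep-architecture statistics from a hypnogram.

Implements the full reported metric suite: state totals per analysis
window, episode (bout) counts, bout-duration histograms, transitions
per hour, NREM interruptions, sleep latency, hourly state totals,
hourly relative NREM-delta power and REM accumulation.

Window semantics: ZT intervals are half-open ``[lo, hi)`` and epochs
belong to the window containing their start time. Episodes straddling
a window boundary are truncated at the boundary for *totals* but
counted once — in the window containing their start — for episode and
transition counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import EPOCH_SECONDS, NREM, REM, STATE_NAMES, WAKE, Hypnogram

#: default threshold on NREM bout length defining sleep onset ("longer
#: than 5 min", read strictly: > 300 s, i.e. at least 38 epochs)
LATENCY_MIN_BOUT_SECONDS: float = 300.0
#: default cap on a wake episode counting as a NREM interruption
INTERRUPTION_CAP_SECONDS: float = 64.0
#: default bout-histogram edge (wake bouts "longer than 300 s")
BOUT_EDGES_SECONDS: tuple[float, ...] = (300.0,)

_PAIRS = [(a, b) for a in (WAKE, NREM, REM) for b in (WAKE, NREM, REM) if a != b]


def consolidate_episodes(hypnogram: Hypnogram) -> pd.DataFrame:
    """Maximal-run decomposition of the hypnogram.

    Returns a table (state, start_epoch, n_epochs, duration_s) whose
    episodes tile the hypnogram exactly; adjacent episodes differ in
    state.
    """
    states = hypnogram.states
    if states.size == 0:
        raise ValueError("cannot consolidate an empty hypnogram")
    change = np.nonzero(np.diff(states))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    n = ends - starts
    return pd.DataFrame(
        {
            "state": states[starts].astype(int),
            "start_epoch": starts,
            "n_epochs": n,
            "duration_s": n * hypnogram.epoch_seconds,
        }
    )


def _window_slice(hypnogram: Hypnogram, window: tuple[float, float] | None):
    """Epoch index range [i0, i1) whose epoch starts fall in the ZT window."""
    if window is None:
        return 0, hypnogram.n_epochs
    lo, hi = window
    zt = hypnogram.zt_seconds
    if lo < zt[0] - 1e-9 or hi > zt[-1] + hypnogram.epoch_seconds + 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}) outside recorded span "
            f"[{zt[0]}, {zt[-1] + hypnogram.epoch_seconds})"
        )
    i0 = int(np.searchsorted(zt, lo - 1e-9))
    i1 = int(np.searchsorted(zt, hi - 1e-9))
    return i0, i1


def state_totals(
    hypnogram: Hypnogram, window: tuple[float, float] | None = None
) -> dict[int, float]:
    """Seconds spent in each state within the ZT window (8 s per epoch)."""
    i0, i1 = _window_slice(hypnogram, window)
    sl = hypnogram.states[i0:i1]
    return {
        s: float(np.count_nonzero(sl == s) * hypnogram.epoch_seconds)
        for s in (WAKE, NREM, REM)
    }


def bout_histogram(
    episodes: pd.DataFrame,
    state: int,
    bin_edges: tuple[float, ...] = BOUT_EDGES_SECONDS,
) -> dict[str, int]:
    """Episode counts of one state by duration bin.

    ``bin_edges`` (strictly increasing, seconds) split durations into
    ``<= e1``, ``(e1, e2]``, ..., and an open top bin ``> e_last``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size == 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be non-empty and strictly increasing")
    dur = episodes.loc[episodes["state"] == state, "duration_s"].to_numpy()
    idx = np.searchsorted(edges, dur, side="left")
    labels = (
        [f"<={edges[0]:g}s"]
        + [f"({edges[i]:g},{edges[i+1]:g}]s" for i in range(edges.size - 1)]
        + [f">{edges[-1]:g}s"]
    )
    counts = np.bincount(idx, minlength=edges.size + 1)
    return {lab: int(c) for lab, c in zip(labels, counts)}


def transition_analysis(
    episodes: pd.DataFrame, window_hours: float
) -> tuple[dict[tuple[int, int], int], dict[tuple[int, int], float]]:
    """Counts and per-hour rates of each ordered state transition."""
    if window_hours <= 0:
        raise ValueError("window_hours must be positive")
    seq = episodes["state"].to_numpy()
    counts = {pair: 0 for pair in _PAIRS}
    for a, b in zip(seq[:-1], seq[1:]):
        counts[(int(a), int(b))] += 1
    rates = {pair: c / window_hours for pair, c in counts.items()}
    return counts, rates


def nrem_interruptions(
    episodes: pd.DataFrame, max_interruption: float = INTERRUPTION_CAP_SECONDS
) -> int:
    """Brief wake episodes embedded in NREM sleep.

    Counts wake episodes of duration <= ``max_interruption`` seconds
    whose flanking episodes are both NREM.
    """
    if max_interruption < EPOCH_SECONDS:
        raise ValueError("max_interruption must be at least one epoch")
    st = episodes["state"].to_numpy()
    dur = episodes["duration_s"].to_numpy()
    count = 0
    for i in range(1, len(episodes) - 1):
        if (
            st[i] == WAKE
            and dur[i] <= max_interruption
            and st[i - 1] == NREM
            and st[i + 1] == NREM
        ):
            count += 1
    return count


def sleep_latency(
    hypnogram: Hypnogram, min_bout: float = LATENCY_MIN_BOUT_SECONDS
) -> tuple[float, bool]:
    """Time from epoch 0 to the first NREM bout strictly longer than `min_bout`.

    The record is assumed to start at the intervention (ZT 0 in the
    cage-change design). Returns ``(latency_seconds, defined)``; when
    no qualifying bout exists, latency is NaN and ``defined`` is False
    (undefined is a value, not an error — downstream group statistics
    treat it as censored at the window length).
    """
    eps = consolidate_episodes(hypnogram)
    nrem = eps[(eps["state"] == NREM) & (eps["duration_s"] > min_bout)]
    if nrem.empty:
        return float("nan"), False
    return float(nrem.iloc[0]["start_epoch"] * hypnogram.epoch_seconds), True


def hourly_profiles(
    hypnogram: Hypnogram,
    series: pd.DataFrame | None = None,
    reference_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Hourly state totals, relative NREM-delta power and REM accumulation.

    One row per clock hour from the recording start. Relative NREM-delta
    is the mean delta power over the hour's NREM epochs divided by the
    animal's mean NREM-delta over ``reference_window`` (default: the
    whole recording); within-animal normalization removes amplitude
    nuisance. Hours with no NREM epoch carry NaN there. REM
    accumulation is the running total of REM seconds up to the end of
    each hour (the per-hour REM total is also emitted).
    """
    n = hypnogram.n_epochs
    epochs_per_hour = int(round(3600.0 / hypnogram.epoch_seconds))
    n_hours = int(np.ceil(n / epochs_per_hour))
    if series is not None:
        if len(series) != n:
            raise ValueError(
                f"band-power series ({len(series)} epochs) misaligned with "
                f"hypnogram ({n} epochs)"
            )
        delta = series["delta"].to_numpy()
        nrem_mask = hypnogram.states == NREM
        i0, i1 = _window_slice(hypnogram, reference_window)
        ref_mask = np.zeros(n, dtype=bool)
        ref_mask[i0:i1] = True
        ref = delta[nrem_mask & ref_mask]
        ref_mean = ref.mean() if ref.size else np.nan
    rows = []
    rem_cum = 0.0
    for h in range(n_hours):
        sl = slice(h * epochs_per_hour, min((h + 1) * epochs_per_hour, n))
        st = hypnogram.states[sl]
        totals = {
            f"{STATE_NAMES[s].lower()}_s": float(
                np.count_nonzero(st == s) * hypnogram.epoch_seconds
            )
            for s in (WAKE, NREM, REM)
        }
        rem_cum += totals["r_s"]
        row = {
            "hour": h,
            "zt_hour": hypnogram.zt_start / 3600.0 + h,
            "wake_s": totals["w_s"],
            "nrem_s": totals["n_s"],
            "rem_s": totals["r_s"],
            "rem_cumulative_s": rem_cum,
        }
        if series is not None:
            hour_nrem = (hypnogram.states[sl] == NREM)
            if hour_nrem.any() and np.isfinite(ref_mean) and ref_mean > 0:
                row["rel_nrem_delta"] = float(
                    delta[sl][hour_nrem].mean() / ref_mean
                )
            else:
                row["rel_nrem_delta"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ArchitectureSummary:
    """All per-animal metrics for one analysis window."""

    window: tuple[float, float]
    totals: dict[int, float]
    episode_counts: dict[int, int]
    bout_histograms: dict[int, dict[str, int]]
    transition_counts: dict[tuple[int, int], int]
    transitions_per_hour: dict[tuple[int, int], float]
    nrem_interruptions: int
    sleep_latency_s: float
    latency_defined: bool
    hourly: pd.DataFrame
    config: dict = field(default_factory=dict)

    def to_long(self, animal_id="", handling="", treatment="") -> pd.DataFrame:
        """Flatten to a cohort-ready long table keyed by (animal, window, metric)."""
        win = f"ZT{self.window[0] / 3600:g}-{self.window[1] / 3600:g}"
        rows = []

        def add(metric, value, censored=False):
            rows.append(
                {
                    "animal_id": animal_id,
                    "handling": handling,
                    "treatment": treatment,
                    "window": win,
                    "metric": metric,
                    "value": value,
                    "censored": censored,
                }
            )

        for s, name in STATE_NAMES.items():
            add(f"total_{name.lower()}_s", self.totals[s])
            add(f"episodes_{name.lower()}", self.episode_counts[s])
            for lab, c in self.bout_histograms[s].items():
                add(f"bouts_{name.lower()}_{lab}", c)
        for (a, b), c in self.transition_counts.items():
            add(f"transitions_{STATE_NAMES[a]}{STATE_NAMES[b]}", c)
        for (a, b), r in self.transitions_per_hour.items():
            add(f"transitions_{STATE_NAMES[a]}{STATE_NAMES[b]}_per_h", r)
        add("nrem_interruptions", self.nrem_interruptions)
        if self.latency_defined:
            add("sleep_latency_s", self.sleep_latency_s)
        else:
            # censored at window length so fully-awake animals are retained
            add("sleep_latency_s", self.window[1] - self.window[0], censored=True)
        for _, hr in self.hourly.iterrows():
            h = int(hr["hour"])
            add(f"hourly_wake_s_h{h}", hr["wake_s"])
            add(f"hourly_nrem_s_h{h}", hr["nrem_s"])
            add(f"hourly_rem_s_h{h}", hr["rem_s"])
            add(f"hourly_rem_cum_s_h{h}", hr["rem_cumulative_s"])
            if "rel_nrem_delta" in hr.index:
                add(f"hourly_rel_nrem_delta_h{h}", hr["rel_nrem_delta"])
        return pd.DataFrame(rows)


def summarize(
    hypnogram: Hypnogram,
    series: pd.DataFrame | None = None,
    windows: list[tuple[float, float]] | None = None,
    latency_min_bout: float = LATENCY_MIN_BOUT_SECONDS,
    interruption_cap: float = INTERRUPTION_CAP_SECONDS,
    bout_edges: tuple[float, ...] = BOUT_EDGES_SECONDS,
) -> list[ArchitectureSummary]:
    """Compute every architecture metric for each ZT window.

    Default windows: the whole recording. Sleep latency is always
    measured from the recording start (the intervention), not the
    window start.
    """
    if windows is None:
        windows = [
            (hypnogram.zt_start, hypnogram.zt_start + hypnogram.duration_seconds)
        ]
    latency, defined = sleep_latency(hypnogram, latency_min_bout)
    all_eps = consolidate_episodes(hypnogram)
    out = []
    for lo, hi in windows:
        i0, i1 = _window_slice(hypnogram, (lo, hi))
        sub = Hypnogram(
            hypnogram.states[i0:i1],
            hypnogram.epoch_seconds,
            zt_start=hypnogram.zt_start + i0 * hypnogram.epoch_seconds,
        )
        # episodes belong to the window containing their start; their
        # full (untruncated) duration is used for counts and histograms
        eps = all_eps[
            (all_eps["start_epoch"] >= i0) & (all_eps["start_epoch"] < i1)
        ].reset_index(drop=True)
        counts = {
            s: int((eps["state"] == s).sum()) for s in (WAKE, NREM, REM)
        }
        t_counts, t_rates = transition_analysis(eps, (hi - lo) / 3600.0)
        sub_series = series.iloc[i0:i1] if series is not None else None
        out.append(
            ArchitectureSummary(
                window=(lo, hi),
                totals=state_totals(hypnogram, (lo, hi)),
                episode_counts=counts,
                bout_histograms={
                    s: bout_histogram(eps, s, bout_edges) for s in (WAKE, NREM, REM)
                },
                transition_counts=t_counts,
                transitions_per_hour=t_rates,
                nrem_interruptions=nrem_interruptions(eps, interruption_cap),
                sleep_latency_s=latency,
                latency_defined=defined,
                hourly=hourly_profiles(sub, sub_series),
                config={
                    "latency_min_bout_s": latency_min_bout,
                    "interruption_cap_s": interruption_cap,
                    "bout_edges_s": list(bout_edges),
                    "boundary_rule": "truncate totals at window edge; "
                    "episodes counted in the window containing their start",
                },
            )
        )
    return out
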