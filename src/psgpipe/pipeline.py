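"""End-to-end run: simulate -> spectra -> stage -> metrics -> stats.

A run directory holds the exact config used, every intermediate as
delimited text, and a final JSON report including the ground-truth
vs. recovered staging confusion matrix (available because inputs are
simulated). Everything is deterministic in the run seed; per-animal
random streams are derived from (seed, cell index, animal index) so
changing the cohort size never reshuffles existing animals.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .metrics import (
    BOUT_EDGES_SECONDS,
    INTERRUPTION_CAP_SECONDS,
    LATENCY_MIN_BOUT_SECONDS,
    summarize,
)
from .simulate import PRESETS, CohortDesign, generate_cohort
from .spectral import build_band_power_series
from .staging import classify_epochs, fit_thresholds, smooth_hypnogram
from .states import NREM, REM, STATE_NAMES, WAKE
from .stats import cohort_table, one_way_anova_tukey, two_way_anova_bonferroni

log = logging.getLogger("psgpipe")

#: metrics reported in the final group-statistics tables
DEFAULT_STAT_METRICS = (
    "total_w_s",
    "total_n_s",
    "total_r_s",
    "episodes_w",
    "episodes_n",
    "episodes_r",
    "nrem_interruptions",
    "sleep_latency_s",
    "transitions_WN_per_h",
    "transitions_NR_per_h",
)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; YAML-serializable.

    Defaults match the acquisition and scoring protocol this pipeline
    models:
    EEG 125 Hz / EMG 250 Hz, 16-s FFT windows with 50% overlap for EEG
    and 2-s windows for EMG, 8-s epochs, the four standard EEG bands,
    a 300-s latency threshold, and ZT 0-8 / ZT 12-24 analysis windows.
    """

    seed: int = 0
    n_per_group: int = 8
    cells: tuple[tuple[str, str], ...] = tuple(PRESETS)
    duration_hours: float = 8.0
    zt_start: float = 0.0
    latency_min_bout_s: float = LATENCY_MIN_BOUT_SECONDS
    interruption_cap_s: float = INTERRUPTION_CAP_SECONDS
    bout_edges_s: tuple[float, ...] = BOUT_EDGES_SECONDS
    windows_zt_hours: tuple[tuple[float, float], ...] = ((0.0, 8.0), (12.0, 24.0))
    stat_metrics: tuple[str, ...] = DEFAULT_STAT_METRICS
    smooth_min_run: int = 1  # 1 = no smoothing (manual rescoring is out of scope)
    write_signals: bool = False
    signal_format: str = "edf"  # or "csv"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["cells"] = tuple(tuple(c) for c in raw.get("cells", tuple(PRESETS)))
        raw["windows_zt_hours"] = tuple(
            tuple(w) for w in raw.get("windows_zt_hours", ((0.0, 8.0),))
        )
        for key in ("bout_edges_s", "stat_metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def design(self) -> CohortDesign:
        return CohortDesign(
            n_per_group=self.n_per_group,
            cells=self.cells,
            duration_hours=self.duration_hours,
            zt_start=self.zt_start,
            seed=self.seed,
        )

    def applicable_windows(self) -> list[tuple[float, float]]:
        """Configured ZT windows clipped to those inside the recording."""
        lo0 = self.zt_start
        hi0 = self.zt_start + self.duration_hours * 3600.0
        wins = [
            (lo * 3600.0, hi * 3600.0)
            for lo, hi in self.windows_zt_hours
            if lo * 3600.0 >= lo0 - 1e-9 and hi * 3600.0 <= hi0 + 1e-9
        ]
        return wins or [(lo0, hi0)]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline into `outdir`; returns the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    t0 = time.time()

    design = config.design()
    animals, manifest = generate_cohort(design, with_signals=True)
    log.info("simulated %d animals in %.1f s", len(animals), time.time() - t0)

    windows = config.applicable_windows()
    confusion = np.zeros((3, 3), dtype=np.int64)
    long_tables = []
    for rec, truth in animals:
        t_animal = time.time()
        series = build_band_power_series(rec)
        pio.write_table(outdir / f"bandpower_{rec.animal_id}.csv", series)
        pio.write_hypnogram(outdir / f"truth_{rec.animal_id}.csv", truth.hypnogram)

        model = fit_thresholds(series)
        pio.save_thresholds(outdir / f"thresholds_{rec.animal_id}.yaml", model)
        hyp = classify_epochs(
            series,
            model,
            animal_id=rec.animal_id,
            handling=rec.handling,
            treatment=rec.treatment,
        )
        if config.smooth_min_run > 1:
            hyp = smooth_hypnogram(hyp, config.smooth_min_run)
        pio.write_hypnogram(outdir / f"hypnogram_{rec.animal_id}.csv", hyp)
        if config.write_signals:
            if config.signal_format == "edf":
                pio.write_recording_edf(outdir / f"signal_{rec.animal_id}.edf", rec)
            else:
                pio.write_recording_csv(outdir / f"signal_{rec.animal_id}.csv", rec)

        n = min(truth.hypnogram.n_epochs, hyp.n_epochs)
        np.add.at(confusion, (truth.hypnogram.states[:n], hyp.states[:n]), 1)

        for summary in summarize(
            hyp,
            series,
            windows=windows,
            latency_min_bout=config.latency_min_bout_s,
            interruption_cap=config.interruption_cap_s,
            bout_edges=config.bout_edges_s,
        ):
            long_tables.append(
                summary.to_long(rec.animal_id, rec.handling, rec.treatment)
            )
        log.info("processed %s in %.1f s", rec.animal_id, time.time() - t_animal)

    pio.write_table(outdir / "manifest.csv", manifest)
    table = cohort_table(long_tables)
    pio.write_table(outdir / "cohort_metrics.csv", table)

    stat_rows, contrast_rows = [], []
    handlings = sorted({c[0] for c in config.cells})
    treatments = sorted({c[1] for c in config.cells})
    two_way_possible = len(handlings) >= 2 and len(treatments) >= 2
    for win in sorted(table["window"].unique()):
        for metric in config.stat_metrics:
            if metric not in set(table["metric"]):
                continue
            try:
                if two_way_possible:
                    res = two_way_anova_bonferroni(table, metric, win)
                    if res.tested:
                        for _, r in res.anova.iterrows():
                            if r["effect"] == "Residual":
                                continue
                            stat_rows.append(
                                {
                                    "window": win,
                                    "metric": metric,
                                    "effect": r["effect"],
                                    "F": r["F"],
                                    "p": r["p"],
                                }
                            )
                        c = res.contrasts.copy()
                        c.insert(0, "metric", metric)
                        c.insert(0, "window", win)
                        contrast_rows.append(c)
                else:
                    res1 = one_way_anova_tukey(
                        table, metric, win,
                        group_col="handling" if len(handlings) > 1 else "treatment",
                    )
                    if res1.tested:
                        stat_rows.append(
                            {
                                "window": win,
                                "metric": metric,
                                "effect": "group",
                                "F": res1.F,
                                "p": res1.p,
                            }
                        )
            except ValueError as exc:
                log.warning("stats skipped for %s / %s: %s", win, metric, exc)
    anova_table = pd.DataFrame(stat_rows)
    pio.write_table(outdir / "anova.csv", anova_table)
    if contrast_rows:
        pio.write_table(outdir / "contrasts.csv", pd.concat(contrast_rows))

    total = confusion.sum()
    report = {
        "n_animals": len(animals),
        "n_epochs_scored": int(total),
        "staging_agreement": float(np.trace(confusion) / total) if total else float("nan"),
        "confusion_matrix": {
            f"true_{STATE_NAMES[a]}": {
                f"scored_{STATE_NAMES[b]}": int(confusion[a, b]) for b in (WAKE, NREM, REM)
            }
            for a in (WAKE, NREM, REM)
        },
        "per_state_recall": {
            STATE_NAMES[s]: float(confusion[s, s] / confusion[s].sum())
            if confusion[s].sum()
            else float("nan")
            for s in (WAKE, NREM, REM)
        },
        "group_means": {
            win: {
                metric: {
                    f"{h}-{t}": float(
                        table[
                            (table["window"] == win)
                            & (table["metric"] == metric)
                            & (table["handling"] == h)
                            & (table["treatment"] == t)
                        ]["value"].mean()
                    )
                    for (h, t) in config.cells
                }
                for metric in config.stat_metrics
                if metric in set(table["metric"])
            }
            for win in sorted(table["window"].unique())
        },
        "runtime_s": time.time() - t0,
    }
    pio.write_json(outdir / "report.json", report)
    log.info("pipeline finished in %.1f s", report["runtime_s"])
    return report
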