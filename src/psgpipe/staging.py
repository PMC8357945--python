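"""Rule-based wake/NREM/REM staging of 8-s epochs.

The scoring rule compares three per-epoch features against
per-recording thresholds:

* **wake** — high EMG power, low sigma*theta;
* **NREM** — low EMG, high sigma*theta, high delta;
* **REM** — low EMG, high sigma*theta, low delta.

The original description names the comparisons but not the cut values,
so each recording's "high"/"low" split is fitted from its own data: a
two-component Gaussian mixture on the log power (EM, k-means init,
fixed seed) with the cut at equal posterior between the two modes,
falling back to the 25th/75th-percentile midpoint when the mixture
degenerates. The delta cut is fitted only on putatively sleeping
(low-EMG) epochs, since the NREM/REM delta contrast is defined within
sleep.

Rule precedence is EMG first (the wake discriminant), then delta
within sleep. Low-EMG epochs whose sigma*theta is also low fit neither
sleep description; they are conservatively scored as quiet wake and
counted in the diagnostics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .states import NREM, REM, WAKE, Hypnogram

FEATURES = ("emg_power", "sigma_theta", "delta")

_LOG_FLOOR = 1e-300


class StagingFitError(ValueError):
    """Raised when a discriminant channel cannot be split (e.g. constant)."""


def _split_log_power(
    x: np.ndarray, channel: str, random_state: int
) -> tuple[float, dict]:
    """Threshold separating the low and high modes of ``log x``.

    Two-component 1-D Gaussian mixture; the cut is where the posterior
    of the upper component crosses 1/2 between the two means. Falls
    back to the inter-quartile midpoint if EM fails or the modes are
    not separated. Returns the cut in power units plus diagnostics.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise StagingFitError(f"no epochs available to fit the {channel} threshold")
    if np.ptp(x) == 0:
        raise StagingFitError(f"{channel} power is constant; cannot fit a threshold")
    logx = np.log(np.maximum(x, _LOG_FLOOR))

    def _fallback(reason: str) -> tuple[float, dict]:
        q25, q75 = np.percentile(logx, [25, 75])
        cut = 0.5 * (q25 + q75)
        return float(np.exp(cut)), {
            "channel": channel,
            "method": "percentile_midpoint",
            "reason": reason,
            "separation": float("nan"),
        }

    try:
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            init_params="kmeans",
            n_init=1,
            random_state=random_state,
        ).fit(logx.reshape(-1, 1))
    except Exception as exc:  # EM failure on pathological input
        return _fallback(f"EM failed: {exc}")
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    m_lo, m_hi = means[order]
    pooled = float(np.sqrt(0.5 * (sds**2).sum()))
    separation = (m_hi - m_lo) / pooled if pooled > 0 else 0.0
    if separation < 0.5:
        return _fallback(f"modes not separated (d={separation:.2f})")
    grid = np.linspace(m_lo, m_hi, 513)
    post_hi = gm.predict_proba(grid.reshape(-1, 1))[:, order[1]]
    crossing = np.nonzero(np.diff(post_hi >= 0.5))[0]
    if crossing.size == 0:
        return _fallback("no posterior crossing between modes")
    cut = 0.5 * (grid[crossing[0]] + grid[crossing[0] + 1])
    return float(np.exp(cut)), {
        "channel": channel,
        "method": "gmm_equal_posterior",
        "means": [float(m_lo), float(m_hi)],
        "separation": float(separation),
        "weights": [float(gm.weights_[order[0]]), float(gm.weights_[order[1]])],
    }


class ThresholdStager(BaseEstimator, ClassifierMixin):
    """Per-recording threshold model implementing the scoring rule.

    A scikit-learn estimator fitted *unsupervised*, one recording at a
    time: ``fit`` learns the three cuts from the recording's own
    feature distribution, ``predict`` applies the rule. ``X`` is an
    ``(n_epochs, 3)`` array or DataFrame with columns
    ``(emg_power, sigma_theta, delta)``.

    Fitted attributes
    -----------------
    emg_cut_, st_cut_, delta_cut_ : float
        Thresholds in power units (strictly positive).
    diagnostics_ : dict
        Per-threshold fit method and mode-separation statistics.
    """

    def __init__(self, min_epochs: int = 50, min_sleep_epochs: int = 10,
                 random_state: int = 0):
        self.min_epochs = min_epochs
        self.min_sleep_epochs = min_sleep_epochs
        self.random_state = random_state

    @staticmethod
    def _as_features(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in FEATURES if c not in X.columns]
            if missing:
                raise ValueError(f"feature table lacks columns {missing}")
            X = X[list(FEATURES)].to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                "X must be (n_epochs, 3): columns (emg_power, sigma_theta, delta)"
            )
        if not np.isfinite(X).all() or (X < 0).any():
            raise ValueError("powers must be finite and non-negative")
        return X

    def fit(self, X, y=None):
        X = self._as_features(X)
        if X.shape[0] < self.min_epochs:
            warnings.warn(
                f"fitting thresholds on only {X.shape[0]} epochs "
                f"(< {self.min_epochs}); cuts may be unstable",
                stacklevel=2,
            )
        emg, st, delta = X[:, 0], X[:, 1], X[:, 2]
        diagnostics: dict[str, dict] = {}
        self.emg_cut_, diagnostics["emg_power"] = _split_log_power(
            emg, "emg_power", self.random_state
        )
        self.st_cut_, diagnostics["sigma_theta"] = _split_log_power(
            st, "sigma_theta", self.random_state
        )
        sleeping = emg <= self.emg_cut_
        if sleeping.sum() >= self.min_sleep_epochs:
            self.delta_cut_, diagnostics["delta"] = _split_log_power(
                delta[sleeping], "delta", self.random_state
            )
        elif sleeping.any():
            self.delta_cut_ = float(np.median(delta[sleeping]))
            diagnostics["delta"] = {
                "channel": "delta",
                "method": "median_of_sleep",
                "reason": f"only {int(sleeping.sum())} sleep epochs",
            }
        else:
            self.delta_cut_ = float(np.median(delta)) or 1.0
            diagnostics["delta"] = {
                "channel": "delta",
                "method": "median_all",
                "reason": "no epochs below the EMG cut",
            }
        if self.delta_cut_ <= 0:
            self.delta_cut_ = _LOG_FLOOR
        diagnostics["n_epochs"] = int(X.shape[0])
        self.diagnostics_ = diagnostics
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "emg_cut_")
        X = self._as_features(X)
        emg, st, delta = X[:, 0], X[:, 1], X[:, 2]
        out = np.full(X.shape[0], WAKE, dtype=np.int8)
        sleep = (emg <= self.emg_cut_) & (st > self.st_cut_)
        out[sleep & (delta > self.delta_cut_)] = NREM
        out[sleep & (delta <= self.delta_cut_)] = REM
        return out

    def quiet_wake_fraction(self, X) -> float:
        """Fraction of epochs scored wake via the low-EMG, low-sigma*theta tie rule."""
        check_is_fitted(self, "emg_cut_")
        X = self._as_features(X)
        quiet = (X[:, 0] <= self.emg_cut_) & (X[:, 1] <= self.st_cut_)
        return float(quiet.mean())


def fit_thresholds(series: pd.DataFrame, **kwargs) -> ThresholdStager:
    """Fit the per-recording threshold model from a band-power table."""
    return ThresholdStager(**kwargs).fit(series)


def classify_epochs(series: pd.DataFrame, model: ThresholdStager, **hyp_kwargs) -> Hypnogram:
    """Score every epoch of a band-power table with a fitted model."""
    states = model.predict(series)
    zt_start = float(series["zt_seconds"].iloc[0]) if "zt_seconds" in series else 0.0
    return Hypnogram(states, zt_start=zt_start, **hyp_kwargs)


def smooth_hypnogram(hypnogram: Hypnogram, min_run: int = 1) -> Hypnogram:
    """Reassign isolated short runs to their (agreeing) flanking state.

    Optional surrogate for manual rescoring; ``min_run=1`` is the
    identity, and the default pipeline applies no smoothing. A run
    shorter than ``min_run`` epochs is rewritten only when both
    flanking runs exist and agree.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    states = hypnogram.states.copy()
    if min_run == 1 or states.size == 0:
        return Hypnogram(states, hypnogram.epoch_seconds, hypnogram.zt_start,
                         hypnogram.animal_id, hypnogram.handling, hypnogram.treatment)
    # run-length view
    change = np.nonzero(np.diff(states))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    for i in range(1, starts.size - 1):
        if ends[i] - starts[i] < min_run:
            left = states[starts[i] - 1]
            right = states[ends[i]]
            if left == right and left != states[starts[i]]:
                states[starts[i] : ends[i]] = left
    return Hypnogram(states, hypnogram.epoch_seconds, hypnogram.zt_start,
                     hypnogram.animal_id, hypnogram.handling, hypnogram.treatment)
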