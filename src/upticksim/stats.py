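"""Ensemble summaries: mean transcription-rate curves and amplitude metrics.

The experimental observable the model is compared against is a luciferase
reporter whose light output tracks the instantaneous transcription rate of
the promoter, not accumulated product.  The corresponding simulation
quantity is the ensemble-mean transcription event rate: transcription
firings histogrammed over time bins, divided by bin width and ensemble
size.  "Amplitude" of a strain means the peak of this curve after light
smoothing (3-bin moving average, to suppress binning noise); the peak of
the mean mRNA timecourse is reported alongside for the transcripts-per-cell
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ssa import EnsembleResult

#: moving-average window (bins) applied before peak extraction
SMOOTH_WINDOW = 3


class UndefinedRatioError(ZeroDivisionError):
    """Amplitude ratio against a curve with zero peak."""


@dataclass
class RateCurve:
    """Ensemble-mean transcription rate on a uniform time grid.

    ``rate[i]`` is the mean number of transcription events per cell per
    hour in the bin centred at ``times[i]``; ``mrna_mean[i]`` the mean mRNA
    copy number at the nearest snapshot time.
    """

    times: np.ndarray
    rate: np.ndarray
    mrna_mean: np.ndarray
    strain_label: str
    n_runs: int = 0
    warn_zero: bool = False

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.rate) == len(self.mrna_mean)):
            raise ValueError("times, rate and mrna_mean must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.rate < 0):
            raise ValueError("rates must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "rate_per_h": self.rate,
                "mrna_mean": self.mrna_mean,
                "strain": self.strain_label,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def mean_rate_curve(ensemble: EnsembleResult, bin_width: float = 0.1) -> RateCurve:
    """Bin transcription events into a mean rate curve.

    Events from all promoter copies are pooled and normalised per promoter,
    so single- and dual-promoter ensembles are directly comparable.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    if ensemble.n_runs < 1 or not ensemble.tx_times:
        raise ValueError("empty ensemble")
    edges = np.arange(0.0, ensemble.t_end + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    events = [t for run in ensemble.tx_times for t in run]
    allt = np.concatenate(events) if events else np.empty(0)
    hist, _ = np.histogram(allt, bins=edges)
    norm = bin_width * ensemble.n_runs * ensemble.n_promoters
    rate = hist / norm
    # mean mRNA per promoter copy, sampled at the nearest snapshot
    mrna_runs = ensemble.mrna_counts.mean(axis=(0, 1))
    idx = np.clip(
        np.searchsorted(ensemble.grid, centers), 0, len(ensemble.grid) - 1
    )
    return RateCurve(
        times=centers,
        rate=rate,
        mrna_mean=mrna_runs[idx],
        strain_label=ensemble.strain_label,
        n_runs=ensemble.n_runs,
    )


def _smoothed(rate: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    # curves with only a handful of bins carry no binning noise worth
    # smoothing away; take them raw
    if len(rate) < 2 * window:
        return rate.astype(float)
    kernel = np.ones(window) / window
    out = np.convolve(rate, kernel, mode="same")
    # edge bins average over fewer points; renormalise to an unbiased mean
    counts = np.convolve(np.ones_like(rate, dtype=float), kernel, mode="same")
    return out / counts


def peak_amplitude(curve: RateCurve) -> tuple[float, float]:
    """(peak value, peak time) of the lightly smoothed rate curve.

    Ties are broken toward the earliest time.  An all-zero curve returns
    (0.0, first time) and sets ``curve.warn_zero``.
    """
    if len(curve.rate) == 0:
        raise ValueError("empty curve")
    sm = _smoothed(curve.rate)
    if np.all(sm == 0):
        curve.warn_zero = True
        return 0.0, float(curve.times[0])
    i = int(np.argmax(sm))  # argmax returns the first maximum: earliest time
    return float(sm[i]), float(curve.times[i])


def amplitude_ratio(curve_a: RateCurve, curve_b: RateCurve) -> float:
    """Peak-amplitude fold difference a/b between two strains' curves."""
    if len(curve_a.times) != len(curve_b.times) or not np.allclose(
        curve_a.times, curve_b.times
    ):
        raise ValueError(
            "curves must share bin_width and horizon for a meaningful ratio"
        )
    peak_a, _ = peak_amplitude(curve_a)
    peak_b, _ = peak_amplitude(curve_b)
    if peak_b == 0:
        raise UndefinedRatioError(
            f"denominator strain {curve_b.strain_label!r} has zero peak"
        )
    return peak_a / peak_b


def normalize_peak(curve: RateCurve) -> RateCurve:
    """Scale the curve so its (smoothed) peak equals 1."""
    peak, _ = peak_amplitude(curve)
    if peak == 0:
        raise UndefinedRatioError(
            f"cannot normalize all-zero curve for strain {curve.strain_label!r}"
        )
    return replace(curve, rate=curve.rate / peak, mrna_mean=curve.mrna_mean.copy())


def decay_halftime(curve: RateCurve) -> tuple[float, bool]:
    """Time from the peak until the rate first falls to half-peak.

    Linear interpolation between bins.  If the curve never falls below
    half-peak before the horizon, returns (horizon - peak_time, True) --
    the second element is the censored flag.
    """
    peak, t_peak = peak_amplitude(curve)
    if peak <= 0:
        raise ValueError("decay halftime needs a positive peak")
    sm = _smoothed(curve.rate)
    half = 0.5 * peak
    i_peak = int(np.argmin(np.abs(curve.times - t_peak)))
    for i in range(i_peak + 1, len(sm)):
        if sm[i] <= half:
            t_prev, t_cur = curve.times[i - 1], curve.times[i]
            v_prev, v_cur = sm[i - 1], sm[i]
            if v_cur == v_prev:
                t_half = t_cur
            else:
                t_half = t_prev + (v_prev - half) / (v_prev - v_cur) * (t_cur - t_prev)
            return float(t_half - t_peak), False
    return float(curve.times[-1] - t_peak), True


def comparison_report(curves: dict[str, RateCurve], pairs) -> pd.DataFrame:
    """Amplitude-ratio report between strain pairs.

    ``pairs`` is an iterable of (strain_a, strain_b) keys into ``curves``.
    """
    rows = []
    for a, b in pairs:
        peak_a, _ = peak_amplitude(curves[a])
        peak_b, _ = peak_amplitude(curves[b])
        ht_a, _ = decay_halftime(curves[a]) if peak_a > 0 else (np.nan, True)
        ht_b, _ = decay_halftime(curves[b]) if peak_b > 0 else (np.nan, True)
        rows.append(
            {
                "strain_a": a,
                "strain_b": b,
                "ratio": peak_a / peak_b if peak_b else np.nan,
                "peak_a": peak_a,
                "peak_b": peak_b,
                "halftime_a": ht_a,
                "halftime_b": ht_b,
            }
        )
    return pd.DataFrame(rows)
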