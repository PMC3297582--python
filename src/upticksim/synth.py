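"""Synthetic per-cell two-channel intensity tables.

Emulates the statistical structure of the single-cell reporter data the
cytometry pipeline consumes: a uniform autofluorescence floor of 12-16
a.u. in both channels, a log-normal extrinsic spread of the YFP reporter
of Spo0A~P, a competence probability that is a window-shaped function of
YFP (competence transitions happen only at intermediate Spo0A~P), a
competent CFP population strictly above the planted threshold of 36 a.u.,
and an overall competent fraction around the observed 10-20%.

Distribution families (log-normal YFP, truncated log-normal competent
CFP, uniform background) are modelling choices; only the qualitative
structure -- bimodality, window dependence, background floor -- mirrors
the real data.  Competent and non-competent CFP distributions are
separated exactly at the planted threshold, so ground-truth labels are
recoverable and the planted false-positive rate of threshold
classification is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


class GenerationError(ValueError):
    """Requested synthetic population is infeasible."""


@dataclass(frozen=True)
class SynthCellParams:
    """Parameters of the synthetic single-cell population.

    ``window`` is (low_edge, high_edge, peak_prob): the competence
    probability is a raised-cosine bump over that YFP interval, scaled so
    the expected competent fraction equals ``competent_fraction_target``.
    """

    n_cells: int = 10_000
    autofluor_range: tuple[float, float] = (12.0, 16.0)   # a.u., both channels
    competent_fraction_target: float = 0.133
    cfp_threshold_planted: float = 36.0                   # a.u.
    yfp_extrinsic: tuple[float, float] = (4.1, 0.6)       # log-normal mu, sigma
    window: tuple[float, float, float] = (25.0, 160.0, 0.35)
    competent_cfp_dist: tuple[float, float] = (3.65, 0.45)  # log-normal mu, sigma
    basal_cfp_scale: float = 16.0                           # half-normal scale, a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise GenerationError("n_cells must be >= 1")
        if not (0.0 < self.competent_fraction_target < 1.0):
            raise GenerationError("competent_fraction_target must be in (0, 1)")
        low, high, peak = self.window
        if not low < high:
            raise GenerationError("window low_edge must be < high_edge")
        if not (0.0 <= peak <= 1.0):
            raise GenerationError("window peak_prob must be in [0, 1]")
        if self.autofluor_range[0] > self.autofluor_range[1]:
            raise GenerationError("autofluor_range must be (low, high)")


def window_probability(yfp: np.ndarray, window: tuple[float, float, float]) -> np.ndarray:
    """Raised-cosine competence-probability bump over a YFP interval.

    Zero outside [low, high], maximum ``peak_prob`` at the interval centre.
    """
    low, high, peak = window
    y = np.asarray(yfp, dtype=float)
    inside = (y > low) & (y < high)
    phase = (y - low) / (high - low)
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return np.where(inside, peak * bump, 0.0)


def _draw_channels(params: SynthCellParams, rng: np.random.Generator, n: int):
    lo, hi = params.autofluor_range
    background_yfp = rng.uniform(lo, hi, size=n)
    mu, sigma = params.yfp_extrinsic
    yfp = background_yfp + rng.lognormal(mu, sigma, size=n)
    return yfp


def _draw_cfp(
    params: SynthCellParams, rng: np.random.Generator, labels: np.ndarray
) -> np.ndarray:
    n = len(labels)
    lo, hi = params.autofluor_range
    thr = params.cfp_threshold_planted
    cfp = np.empty(n)
    # non-competent: background + sub-threshold basal expression, resampled
    # to stay at or below the planted threshold
    n_off = int((~labels).sum())
    off = rng.uniform(lo, hi, size=n_off) + np.abs(
        rng.normal(0.0, params.basal_cfp_scale, size=n_off)
    )
    bad = off > thr
    while bad.any():
        k = int(bad.sum())
        off[bad] = rng.uniform(lo, hi, size=k) + np.abs(
            rng.normal(0.0, params.basal_cfp_scale, size=k)
        )
        bad = off > thr
    cfp[~labels] = off
    # competent: log-normal ON distribution truncated to lie above threshold
    n_on = int(labels.sum())
    mu, sigma = params.competent_cfp_dist
    on = rng.lognormal(mu, sigma, size=n_on)
    bad = on <= thr
    while bad.any():
        k = int(bad.sum())
        on[bad] = rng.lognormal(mu, sigma, size=k)
        bad = on <= thr
    cfp[labels] = on
    return cfp


def _scaled_probs(params: SynthCellParams, yfp: np.ndarray) -> np.ndarray:
    probs = window_probability(yfp, params.window)
    mean_p = probs.mean()
    if mean_p == 0.0:
        # an everywhere-zero window yields a population with no competent
        # cells regardless of the target
        return probs
    scale = params.competent_fraction_target / mean_p
    if scale * probs.max() > 1.0:
        achievable = mean_p / probs.max()
        raise GenerationError(
            f"target fraction {params.competent_fraction_target} infeasible "
            f"for this window; maximum achievable expected fraction is "
            f"{achievable:.3f}"
        )
    return scale * probs


def generate_cells(params: SynthCellParams) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a cell table and its ground-truth competence labels.

    YFP is drawn from the extrinsic log-normal plus autofluorescence;
    each cell turns competent with probability ``window(yfp)`` rescaled so
    the expected competent fraction matches the target; CFP is then drawn
    from the competent or basal distribution.  Same params (including
    seed) give an identical table.
    """
    rng = np.random.default_rng(params.seed)
    yfp = _draw_channels(params, rng, params.n_cells)
    probs = _scaled_probs(params, yfp)
    labels = rng.random(params.n_cells) < probs
    cfp = _draw_cfp(params, rng, labels)
    table = pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(params.n_cells)],
            "cfp": cfp,
            "yfp": yfp,
        }
    )
    return table, labels


def generate_null_cells(params: SynthCellParams) -> tuple[pd.DataFrame, np.ndarray]:
    """Same marginals, but competence independent of YFP.

    Every cell is competent with the constant target probability, so any
    association between the label and the YFP axis is spurious -- the null
    model for calibrating the boundary proportion test's type-I error.
    """
    rng = np.random.default_rng(params.seed)
    yfp = _draw_channels(params, rng, params.n_cells)
    labels = rng.random(params.n_cells) < params.competent_fraction_target
    cfp = _draw_cfp(params, rng, labels)
    table = pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(params.n_cells)],
            "cfp": cfp,
            "yfp": yfp,
        }
    )
    return table, labels


def generate_calibration_tables(
    params: SynthCellParams, comg_scale: tuple[float, float] = (5.0, 0.5)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(early, late) tables emulating a threshold-calibration experiment.

    The early table is a standard draw from :func:`generate_cells` (its
    YFP channel plays no role in calibration).  The late table's YFP
    channel reports comG expression instead: high log-normal values for
    competent cells, autofluorescence for the rest, so a comG cutoff
    separates the competent cluster cleanly.
    """
    early, _ = generate_cells(params)
    rng = np.random.default_rng(params.seed + 1)
    n = params.n_cells
    labels = rng.random(n) < params.competent_fraction_target
    lo, hi = params.autofluor_range
    mu, sigma = comg_scale
    comg = rng.uniform(lo, hi, size=n)
    comg[labels] += rng.lognormal(mu, sigma, size=int(labels.sum()))
    cfp = _draw_cfp(params, rng, labels)
    late = pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(n)],
            "cfp": cfp,
            "yfp": comg,
        }
    )
    return early, late


def params_metadata(params: SynthCellParams) -> dict:
    """JSON-serialisable record of the generation parameters."""
    return asdict(params)
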