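"""Promoter occupancy logic, equilibrium binding and time-dependent drives.

The comK promoter carries three Spo0A~P activation sites (A1-A3), two
Spo0A~P repression sites (R1-R2) and two Rok repressor sites: a
high-affinity site overlapping A2 (where Rok and Spo0A~P compete for the
same DNA) and an auxiliary lower-affinity site.  Transcription propensity
is the product of a global core-promoter activity g(t), a boost per
Spo0A~P-occupied A site, and repression factors per Rok-occupied site and
per Spo0A~P-occupied R site.  Because Spo0A~P binds the A sites at lower
concentration than the R sites, a rising Spo0A~P pool first anti-represses
(displacing Rok from A2 and boosting) and later represses (at R1/R2) --
the activate-then-repress sequence that carves out the uptick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .params import InvalidParameterError, ModelParams, StrainConfig


class Occupant(str, Enum):
    EMPTY = "empty"
    OAP = "OAP"    # phosphorylated Spo0A
    ROK = "Rok"


class ModelConsistencyError(ValueError):
    """A promoter state or propensity violates the model's structure."""


#: Which occupants each site admits.
_ALLOWED = {
    "A1": (Occupant.EMPTY, Occupant.OAP),
    "A2": (Occupant.EMPTY, Occupant.OAP, Occupant.ROK),
    "A3": (Occupant.EMPTY, Occupant.OAP),
    "R1": (Occupant.EMPTY, Occupant.OAP),
    "R2": (Occupant.EMPTY, Occupant.OAP),
    "RokAux": (Occupant.EMPTY, Occupant.ROK),
}


@dataclass
class PromoterState:
    """Occupancy of one comK promoter copy.

    A2 holds at most one occupant -- Spo0A~P and Rok compete there.  The
    auxiliary Rok site admits only Rok; A1/A3/R1/R2 admit only Spo0A~P.
    """

    occ: dict = field(
        default_factory=lambda: {s: Occupant.EMPTY for s in _ALLOWED}
    )

    def __post_init__(self) -> None:
        extra = set(self.occ) - set(_ALLOWED)
        if extra:
            raise ModelConsistencyError(f"unknown promoter sites {sorted(extra)}")
        for site, allowed in _ALLOWED.items():
            occupant = self.occ.get(site, Occupant.EMPTY)
            if not isinstance(occupant, Occupant):
                occupant = Occupant(occupant)
            self.occ[site] = occupant
            if occupant not in allowed:
                raise ModelConsistencyError(
                    f"site {site} cannot hold occupant {occupant.value!r}"
                )

    @property
    def n_a_occupied(self) -> int:
        return sum(self.occ[s] is Occupant.OAP for s in ("A1", "A2", "A3"))

    @property
    def n_rok_occupied(self) -> int:
        return sum(self.occ[s] is Occupant.ROK for s in ("A2", "RokAux"))

    @property
    def n_r_occupied(self) -> int:
        return sum(self.occ[s] is Occupant.OAP for s in ("R1", "R2"))


def fraction_bound(conc: float, kd: float) -> float:
    """Single-site equilibrium binding isotherm conc / (conc + Kd).

    This translates gel-shift nominal dissociation constants into site
    occupancy: at conc == Kd half the probe is bound.

    Parameters
    ----------
    conc
        Free protein concentration (nM), >= 0.
    kd
        Dissociation constant (nM), > 0.
    """
    if kd <= 0:
        raise InvalidParameterError(f"kd must be > 0, got {kd}")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise InvalidParameterError("concentration must be >= 0")
    out = conc / (conc + kd)
    return float(out) if out.ndim == 0 else out


def global_activity(t, params: ModelParams):
    """Global core-promoter activity g(t), dimensionless in (0, 1].

    Emulates the rise-and-fall of a core sigma-A promoter across entry
    into stationary phase: a Gaussian ramp from a low pre-growth floor to
    a peak of exactly 1 at t = t0, followed by a fast exponential decline
    with a slow "shoulder" component toward a late floor.  Accepts scalar
    or array t (hours).
    """
    shape = params.g_shape
    t = np.asarray(t, dtype=float)
    tau = t - params.t0
    rise = shape.floor_pre + (1.0 - shape.floor_pre) * np.exp(
        -0.5 * (tau / shape.rise_width) ** 2
    )
    s = shape.shoulder_height
    mix = (1.0 - s) * np.exp(-shape.decay_fast * np.clip(tau, 0.0, None)) + s * np.exp(
        -shape.shoulder_decay * np.clip(tau, 0.0, None)
    )
    fall = shape.floor_late + (1.0 - shape.floor_late) * mix
    out = np.where(tau < 0.0, rise, fall)
    return float(out) if out.ndim == 0 else out


def spo0a_rise(t, params: ModelParams):
    """Normalized spo0A transcription drive h(t) in (0, 1].

    Rises like the global activity but is maintained at its plateau after
    t0 (spo0A transcription does not collapse with the core promoters),
    so the Spo0A~P pool keeps accumulating -- the model's clock.
    """
    shape = params.g_shape
    t = np.asarray(t, dtype=float)
    tau = np.clip(t - params.t0, None, 0.0)
    out = shape.floor_pre + (1.0 - shape.floor_pre) * np.exp(
        -0.5 * (tau / shape.rise_width) ** 2
    )
    return float(out) if out.ndim == 0 else out


def spo0a_drive(t, params: ModelParams, strain: StrainConfig):
    """Spo0A~P production propensity (molecules/h) at time t.

    Zero for spo0A-null strains; otherwise ``oap_rate0 * h(t)`` where h is
    :func:`spo0a_rise`.  Phosphorylation is not modeled separately: the
    phosphorelay is assumed fast, so all newly made Spo0A counts as
    Spo0A~P.
    """
    if not strain.spo0a_present:
        out = np.zeros_like(np.asarray(t, dtype=float))
        return float(out) if out.ndim == 0 else out
    return params.oap_rate0 * spo0a_rise(t, params)


def transcription_propensity(
    state: PromoterState, t: float, params: ModelParams, strain: StrainConfig
) -> float:
    """Transcription propensity (events/h) of one promoter copy.

    ``k_tx_base * g(t) * alpha^nA * rho_rok^nRok * rho_R^nR`` where nA is
    the number of Spo0A~P-occupied A sites, nRok the number of Rok-occupied
    sites and nR the number of Spo0A~P-occupied R sites.  The multiplicative
    form makes joint Rok + Spo0A~P repression stronger than either alone,
    and lets Spo0A~P bound at A sites raise transcription even while Rok
    remains bound at the auxiliary site (non-displacing anti-repression).

    With ``activation_mode == "all_or_none"`` the boost is alpha^3 only
    when all three A sites are occupied, and 1 otherwise.
    """
    n_a = state.n_a_occupied
    if params.activation_mode == "per_site":
        boost = params.alpha**n_a
    else:
        boost = params.alpha**3 if n_a == 3 else 1.0
    a = (
        params.k_tx_base
        * global_activity(t, params)
        * boost
        * params.rho_rok**state.n_rok_occupied
        * params.rho_R**state.n_r_occupied
    )
    if not a >= 0:
        raise ModelConsistencyError(f"transcription propensity is negative: {a}")
    return float(a)
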