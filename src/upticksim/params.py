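"""Model parameters and strain configurations for the comK uptick model.

Units convention: time in hours since inoculation, concentrations in nM,
copy numbers in molecules per cell.  With the default cell volume of
1.66 fL, 1 nM corresponds to very nearly 1 molecule per cell
(1.66e-15 L x 6.022e23 /mol x 1e-9 mol/L = 0.9997), so dissociation
constants measured in nM can be used directly as molecule counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

AVOGADRO = 6.02214076e23

#: Promoter site identifiers.  A1-A3 are Spo0A~P activation sites, R1-R2 are
#: Spo0A~P repression sites, RokA2 is the high-affinity Rok site overlapping
#: A2, RokAux the auxiliary lower-affinity Rok site.
SITES = ("A1", "A2", "A3", "R1", "R2", "RokA2", "RokAux")

#: Affinity retained by a mutated Spo0A~P site (point mutations weaken
#: binding roughly 7-fold rather than abolishing it outright; the residual
#: accounts for the small spo0A-dependent activation that survives in the
#: triple A-site mutant).
RESIDUAL_A_AFFINITY = 0.2


class InvalidParameterError(ValueError):
    """A model parameter violates its physical constraints."""


class UnsupportedConfigurationError(ValueError):
    """A strain configuration the model does not support."""


@dataclass(frozen=True)
class GlobalActivityShape:
    """Shape of the global core-promoter activity g(t).

    g(t) rises from ``floor_pre`` during exponential growth as a Gaussian
    ramp of width ``rise_width``, peaks at exactly 1 at t = t0, then decays
    as a mixture of a fast and a slow exponential toward ``floor_late``.
    The slow component (weight ``shoulder_height``, rate ``shoulder_decay``)
    produces the late shoulder seen in core-promoter activity profiles.
    """

    rise_width: float = 0.8        # h, Gaussian sigma of the rise
    floor_pre: float = 0.1         # dimensionless floor before the rise
    decay_fast: float = 2.0        # 1/h, dominant post-peak decay rate
    shoulder_height: float = 0.25  # weight of the slow component in (0, 1)
    shoulder_decay: float = 0.25   # 1/h, slow component decay rate
    floor_late: float = 0.02       # dimensionless late floor

    def __post_init__(self) -> None:
        if not (0.0 < self.floor_pre < 1.0):
            raise InvalidParameterError("floor_pre must be in (0, 1)")
        if not (0.0 <= self.floor_late < 1.0):
            raise InvalidParameterError("floor_late must be in [0, 1)")
        if not (0.0 <= self.shoulder_height < 1.0):
            raise InvalidParameterError("shoulder_height must be in [0, 1)")
        if self.rise_width <= 0 or self.decay_fast <= 0 or self.shoulder_decay <= 0:
            raise InvalidParameterError("rise_width and decay rates must be positive")
        if self.shoulder_decay >= self.decay_fast:
            raise InvalidParameterError(
                "shoulder_decay must be slower than decay_fast (the shoulder is the slow phase)"
            )


@dataclass(frozen=True)
class ModelParams:
    """Rate coefficients and equilibrium constants of the uptick model.

    Dissociation constants come from gel-shift measurements: about 50 nM
    for Spo0A~P at the A sites, 100-150 nM (125 nM default) at the R sites,
    about 15 nM for Rok at the site overlapping A2 and about 50 nM for the
    residual/auxiliary Rok site.  The kinetic and propensity-scale
    parameters are the package's calibrated defaults, fixed so that
    deterministic mean-field ensembles reproduce the measured strain
    amplitude ratios (see :func:`upticksim.meanfield.calibrate_defaults`).
    """

    # transcription / mRNA
    k_tx_base: float = 7.3562      # events/h per promoter at g=1, no regulators
    k_deg_mrna: float = 4.0        # 1/h  (~10 min mRNA half-life)
    # Spo0A~P dissociation constants (nM)
    kd_A1: float = 50.0
    kd_A2: float = 50.0
    kd_A3: float = 50.0
    kd_R1: float = 125.0
    kd_R2: float = 125.0
    # Rok dissociation constants (nM)
    kd_rok_A2: float = 15.0
    kd_rok_aux: float = 50.0
    # binding kinetics
    k_on: float = 20.0             # 1/(molecule h), universal on-rate
    # regulatory strengths
    alpha: float = 2.9             # fold boost per Spo0A~P-occupied A site
    rho_rok: float = 0.02          # residual transcription per Rok-occupied site
    rho_R: float = 0.2             # residual transcription per occupied R site
    # pools and drives
    rok_copies: int = 90           # constant total Rok per cell
    oap_rate0: float = 800.0       # molecules/h, Spo0A~P production scale
    oap_decay: float = 0.05        # 1/h, slow Spo0A~P loss
    t0: float = 2.25               # h, exponential->stationary transition
    g_shape: GlobalActivityShape = field(default_factory=GlobalActivityShape)
    cell_volume_fl: float = 1.66   # fL; 1 nM ~ 1 molecule/cell
    activation_mode: str = "per_site"  # or "all_or_none"

    def __post_init__(self) -> None:
        positive = {
            "k_tx_base": self.k_tx_base, "k_deg_mrna": self.k_deg_mrna,
            "kd_A1": self.kd_A1, "kd_A2": self.kd_A2, "kd_A3": self.kd_A3,
            "kd_R1": self.kd_R1, "kd_R2": self.kd_R2,
            "kd_rok_A2": self.kd_rok_A2, "kd_rok_aux": self.kd_rok_aux,
            "k_on": self.k_on, "cell_volume_fl": self.cell_volume_fl,
            "t0": self.t0,
        }
        for name, value in positive.items():
            if not value > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {value}")
        if self.oap_rate0 < 0 or self.oap_decay < 0 or self.rok_copies < 0:
            raise InvalidParameterError("rates and copy numbers must be >= 0")
        if self.alpha < 1.0:
            raise InvalidParameterError("alpha must be >= 1 (activation boost)")
        if not (0.0 < self.rho_rok < 1.0) or not (0.0 < self.rho_R < 1.0):
            raise InvalidParameterError("repression factors must be in (0, 1)")
        if not (max(self.kd_A1, self.kd_A3) < min(self.kd_R1, self.kd_R2)):
            raise InvalidParameterError(
                "activation sites must bind Spo0A~P more tightly than repression "
                "sites (kd_A1, kd_A3 < kd_R1, kd_R2); this ordering produces the "
                "activate-then-repress sequence"
            )
        if not self.kd_rok_A2 < self.kd_A2:
            raise InvalidParameterError(
                "Rok must out-compete Spo0A~P at A2 at low concentrations "
                "(kd_rok_A2 < kd_A2)"
            )
        if self.activation_mode not in ("per_site", "all_or_none"):
            raise InvalidParameterError(
                f"activation_mode must be 'per_site' or 'all_or_none', got "
                f"{self.activation_mode!r}"
            )

    @property
    def nm_to_molecules(self) -> float:
        """Conversion factor: molecules per cell per nM."""
        return self.cell_volume_fl * 1e-15 * AVOGADRO * 1e-9

    def kd_molecules(self, kd_nm: float) -> float:
        """A dissociation constant expressed in molecules per cell."""
        return kd_nm * self.nm_to_molecules

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass(frozen=True)
class StrainConfig:
    """Genetic configuration of a simulated strain.

    ``site_mult`` maps each promoter site to an affinity multiplier applied
    to its binding on-rate: 1 is wild type, 0 destroys the site, values in
    between model partial loss of affinity in mutant promoters.
    """

    rok_present: bool = True
    spo0a_present: bool = True
    site_mult: Mapping[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in SITES}
    )
    n_promoters: int = 1
    label: str = "wt"

    def __post_init__(self) -> None:
        mult = {s: 1.0 for s in SITES}
        for key, value in dict(self.site_mult).items():
            if key not in SITES:
                raise UnsupportedConfigurationError(f"unknown promoter site {key!r}")
            if value < 0:
                raise UnsupportedConfigurationError("site multipliers must be >= 0")
            mult[key] = float(value)
        object.__setattr__(self, "site_mult", mult)
        if self.n_promoters not in (1, 2):
            raise UnsupportedConfigurationError(
                f"n_promoters must be 1 or 2, got {self.n_promoters}"
            )

    def replace(self, **changes) -> "StrainConfig":
        return dataclasses.replace(self, **changes)


def _preset_table() -> dict[str, StrainConfig]:
    # Mutating A2 also destroys the overlapping high-affinity Rok site;
    # the residual ~50 nM Rok binding observed with A2-mutant probes is
    # carried by the auxiliary Rok site, which all strains retain.
    ra = RESIDUAL_A_AFFINITY
    return {
        # the baseline strain carries a comK null so the positive-feedback
        # loop is absent; the basal promoter model applies directly
        "wt": StrainConfig(label="wt"),
        "d_comK": StrainConfig(label="d_comK"),
        "d_rok": StrainConfig(rok_present=False, label="d_rok"),
        "d_spo0A": StrainConfig(spo0a_present=False, label="d_spo0A"),
        "d_rok_d_spo0A": StrainConfig(
            rok_present=False, spo0a_present=False, label="d_rok_d_spo0A"
        ),
        "A1": StrainConfig(site_mult={"A1": ra}, label="A1"),
        "A2": StrainConfig(site_mult={"A2": ra, "RokA2": 0.0}, label="A2"),
        "A3": StrainConfig(site_mult={"A3": ra}, label="A3"),
        "A123": StrainConfig(
            site_mult={"A1": ra, "A2": ra, "A3": ra, "RokA2": 0.0}, label="A123"
        ),
        "A123_d_spo0A": StrainConfig(
            spo0a_present=False,
            site_mult={"A1": ra, "A2": ra, "A3": ra, "RokA2": 0.0},
            label="A123_d_spo0A",
        ),
        "R1": StrainConfig(site_mult={"R1": 0.0}, label="R1"),
        "R2": StrainConfig(site_mult={"R2": 0.0}, label="R2"),
    }


#: Names accepted by :func:`strain_preset`.
STRAIN_PRESETS = tuple(_preset_table())


def strain_preset(name: str, n_promoters: int = 1) -> StrainConfig:
    """Return a named strain configuration.

    Parameters
    ----------
    name
        One of :data:`STRAIN_PRESETS`.  ``wt`` and ``d_comK`` are synonyms:
        the model never includes the ComK feedback loop, so the wild-type
        promoter configuration corresponds to the comK-null reporter strain.
    n_promoters
        Number of independent identical comK promoter copies (2 for the
        dual-reporter noise analysis).
    """
    table = _preset_table()
    if name not in table:
        raise UnsupportedConfigurationError(
            f"unknown strain preset {name!r}; valid presets: {', '.join(table)}"
        )
    return table[name].replace(n_promoters=n_promoters)


def load_params(path: str | Path) -> tuple[ModelParams, StrainConfig | None]:
    """Read model parameters (and optionally a strain) from a config file.

    Accepts TOML or YAML.  Keys mirror :class:`ModelParams` field names; a
    ``[strain]`` table/key mirrors :class:`StrainConfig` fields or gives a
    ``preset`` name.  Unknown keys raise an error so typos do not silently
    fall back to defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        import tomllib

        data = tomllib.loads(text)
    if not isinstance(data, dict):
        raise InvalidParameterError(f"config file {path} did not parse to a mapping")

    strain_block = data.pop("strain", None)
    g_block = data.pop("g_shape", None)

    known = {f.name for f in dataclasses.fields(ModelParams)} - {"g_shape"}
    unknown = set(data) - known
    if unknown:
        raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = dict(data)
    if g_block is not None:
        kwargs["g_shape"] = GlobalActivityShape(**g_block)
    params = ModelParams(**kwargs)

    strain = None
    if strain_block is not None:
        if "preset" in strain_block:
            block = dict(strain_block)
            name = block.pop("preset")
            strain = strain_preset(name, n_promoters=block.pop("n_promoters", 1))
            if block:
                raise UnsupportedConfigurationError(
                    f"strain preset cannot be combined with keys {sorted(block)}"
                )
        else:
            strain = StrainConfig(**strain_block)
    return params, strain
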