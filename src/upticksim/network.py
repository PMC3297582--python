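"""Executable reaction networks for the stochastic uptick model.

:func:`build_network` turns a (params, strain) pair into a
:class:`ReactionNetwork`: named integer species, mass-action binding and
decay reactions, time-dependent drives, and the special multiplicative
transcription propensity.  Knocked-out regulators contribute no species
and no reactions, and a site with affinity multiplier 0 contributes no
binding reactions, so mutant networks are structurally minimal.

The network object is declarative; :mod:`upticksim.ssa` compiles it to
flat arrays and executes it with Gillespie's algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, StrainConfig, UnsupportedConfigurationError

#: reaction kinds
KIND_MASS = 0   # rate * product of reactant counts (order 0-2) [* drive]
KIND_TX = 1     # k_tx * g(t) * alpha^nA * rho_rok^nRok * rho_R^nR

#: drive identifiers
DRIVE_NONE = 0
DRIVE_G = 1     # global core-promoter activity g(t)
DRIVE_H = 2     # spo0A transcription drive h(t)


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: a state change plus a propensity rule.

    ``reactants`` lists the species whose counts multiply ``rate_const``
    (at most two; mass-action).  For ``kind = KIND_TX`` the propensity is
    instead the promoter transcription rule evaluated over the occupancy
    indicator species in ``tx_a_sites`` / ``tx_rok_sites`` / ``tx_r_sites``.
    """

    name: str
    rate_const: float
    stoich: tuple[tuple[str, int], ...]
    reactants: tuple[str, ...] = ()
    drive: int = DRIVE_NONE
    kind: int = KIND_MASS
    tx_a_sites: tuple[str, ...] = ()
    tx_rok_sites: tuple[str, ...] = ()
    tx_r_sites: tuple[str, ...] = ()
    tx_promoter: int = -1

    def __post_init__(self) -> None:
        if self.rate_const < 0:
            raise UnsupportedConfigurationError(
                f"reaction {self.name!r} has negative rate constant"
            )
        if len(self.reactants) > 2:
            raise UnsupportedConfigurationError(
                f"reaction {self.name!r}: at most bimolecular propensities supported"
            )


@dataclass
class ReactionNetwork:
    """Species, reactions and drives of one simulated cell.

    ``species`` maps names to initial copy numbers (insertion order fixes
    the state-vector layout).  ``mrna_species`` names the mRNA species of
    each promoter copy, in promoter order.
    """

    species: dict[str, int]
    reactions: list[Reaction]
    params: ModelParams
    strain: StrainConfig
    mrna_species: list[str] = field(default_factory=list)
    oap_species: str | None = None

    def __post_init__(self) -> None:
        names = set(self.species)
        for rxn in self.reactions:
            for sp, delta in rxn.stoich:
                if sp not in names:
                    raise UnsupportedConfigurationError(
                        f"reaction {rxn.name!r} touches unknown species {sp!r}"
                    )
            for sp in (
                rxn.reactants + rxn.tx_a_sites + rxn.tx_rok_sites + rxn.tx_r_sites
            ):
                if sp not in names:
                    raise UnsupportedConfigurationError(
                        f"reaction {rxn.name!r} reads unknown species {sp!r}"
                    )

    @property
    def species_names(self) -> list[str]:
        return list(self.species)

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def structure(self) -> tuple:
        """Hashable structural summary (species, reactions, key rates);
        two networks built from equivalent configurations compare equal."""
        return (
            tuple(self.species.items()),
            tuple(
                (
                    r.name, r.rate_const, r.stoich, r.reactants, r.drive, r.kind,
                    r.tx_a_sites, r.tx_rok_sites, r.tx_r_sites, r.tx_promoter,
                )
                for r in self.reactions
            ),
        )


def build_network(strain: StrainConfig, params: ModelParams) -> ReactionNetwork:
    """Assemble the uptick reaction network for a strain.

    Per promoter copy: Spo0A~P binding/unbinding at A1, A2, A3, R1, R2
    (on-rate ``k_on * mult * [OAP]``, off-rate ``k_on * Kd`` in molecule
    units, so the equilibrium constant is Kd/mult), Rok binding/unbinding
    at the A2-overlapping site (competing with Spo0A~P for the same A2
    lattice position) and the auxiliary site, transcription with the
    multiplicative occupancy rule, and first-order mRNA decay.  Globally:
    Spo0A~P production driven by h(t) and slow decay.  Rok is a constant
    pool -- its total is conserved, free copies drop while bound.
    """
    if strain.n_promoters not in (1, 2):
        raise UnsupportedConfigurationError(
            f"n_promoters must be 1 or 2, got {strain.n_promoters}"
        )
    mult = strain.site_mult
    species: dict[str, int] = {}
    reactions: list[Reaction] = []

    oap = "OAP" if strain.spo0a_present else None
    if oap:
        species[oap] = 0
        reactions.append(
            Reaction("oap_production", params.oap_rate0, ((oap, +1),), drive=DRIVE_H)
        )
        if params.oap_decay > 0:
            reactions.append(
                Reaction("oap_decay", params.oap_decay, ((oap, -1),), reactants=(oap,))
            )
    rok = "Rok" if strain.rok_present else None
    if rok:
        species[rok] = int(params.rok_copies)

    kd = {
        "A1": params.kd_A1, "A2": params.kd_A2, "A3": params.kd_A3,
        "R1": params.kd_R1, "R2": params.kd_R2,
    }
    mrna_species: list[str] = []
    for p in range(1, strain.n_promoters + 1):
        pre = f"p{p}."
        a_occ: list[str] = []
        rok_occ: list[str] = []
        r_occ: list[str] = []

        def add_site(site: str, pool: str | None, pool_mult: float, kd_nm: float,
                     occupied: str, free: str, occ_list: list[str]) -> None:
            """Binding/unbinding of `pool` at a two-state site."""
            if pool is None or pool_mult <= 0:
                return
            if free not in species:
                species[free] = 1
            species[occupied] = 0
            occ_list.append(occupied)
            reactions.append(
                Reaction(
                    f"{occupied}.bind",
                    params.k_on * pool_mult,
                    ((pool, -1), (free, -1), (occupied, +1)),
                    reactants=(pool, free),
                )
            )
            reactions.append(
                Reaction(
                    f"{occupied}.unbind",
                    params.k_on * params.kd_molecules(kd_nm),
                    ((pool, +1), (free, +1), (occupied, -1)),
                    reactants=(occupied,),
                )
            )

        for site in ("A1", "A3"):
            add_site(site, oap, mult[site], kd[site],
                     f"{pre}{site}.OAP", f"{pre}{site}.free", a_occ)
        # A2: Spo0A~P and Rok compete for one shared lattice position
        add_site("A2", oap, mult["A2"], kd["A2"],
                 f"{pre}A2.OAP", f"{pre}A2.free", a_occ)
        add_site("A2", rok, mult["RokA2"], params.kd_rok_A2,
                 f"{pre}A2.Rok", f"{pre}A2.free", rok_occ)
        add_site("RokAux", rok, mult["RokAux"], params.kd_rok_aux,
                 f"{pre}RokAux.Rok", f"{pre}RokAux.free", rok_occ)
        for site in ("R1", "R2"):
            add_site(site, oap, mult[site], kd[site],
                     f"{pre}{site}.OAP", f"{pre}{site}.free", r_occ)

        mrna = f"{pre}mRNA"
        species[mrna] = 0
        mrna_species.append(mrna)
        reactions.append(
            Reaction(
                f"{pre}transcription",
                params.k_tx_base,
                ((mrna, +1),),
                drive=DRIVE_G,
                kind=KIND_TX,
                tx_a_sites=tuple(a_occ),
                tx_rok_sites=tuple(rok_occ),
                tx_r_sites=tuple(r_occ),
                tx_promoter=p - 1,
            )
        )
        reactions.append(
            Reaction(
                f"{pre}mrna_decay", params.k_deg_mrna, ((mrna, -1),), reactants=(mrna,)
            )
        )

    return ReactionNetwork(
        species=species,
        reactions=reactions,
        params=params,
        strain=strain,
        mrna_species=mrna_species,
        oap_species=oap,
    )
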