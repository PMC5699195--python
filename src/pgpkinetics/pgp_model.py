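"""Mass-action model of P-gp mediated drug efflux.

The system tracks 16 variables: two drugs (the transported substrate, e.g.
paclitaxel, and a kinase inhibitor) in three compartments (extracellular,
plasma membrane, cytosol), cytosolic ATP, and the nine binding configurations
of the pump.  The pump lattice is the Cartesian product of the
substrate-binding domain (SBD) occupant {empty, substrate, TKI} and the
nucleotide-binding domain (NBD) occupant {empty, ATP, TKI}.

Conventions
-----------
* Every variable is a molar concentration *in its own compartment*; pump
  states live on the membrane-volume basis.
* SBD association draws ligand from the membrane pool, NBD association from
  the cytosolic pool, with fluxes converted mole-consistently through the
  compartment volume ratios.
* Only states with a substrate or TKI in the SBD *and* ATP in the NBD turn
  over: one irreversible ``k_cat`` step ejects the SBD occupant to the
  extracellular pool, consumes the ATP and resets the pump to (empty, empty).
* An infinite dissociation constant removes the corresponding association
  and dissociation fluxes exactly.

A noncompetitive variant (used when fitting calcein-assay data) widens the
SBD alphabet to two independent sub-sites, giving a 12-state lattice; the
same reaction builder produces both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError, InvalidStateError, MisuseError
from .thermo import DEFAULT_GEOMETRY, affinity_to_kd

__all__ = [
    "SbdOccupant",
    "NbdOccupant",
    "PgpState",
    "enumerate_states",
    "KineticParameters",
    "SystemState",
    "ReactionNetwork",
    "build_network",
    "rhs",
    "equilibrium_occupancy",
    "DEFAULT_KD_ATP",
]

#: ATP/NBD dissociation constant derived from the -7.0 kcal/mol docking affinity.
DEFAULT_KD_ATP = affinity_to_kd(-7.0)

# Variable layout (competitive model: 7 compartment species + 9 pump states).
SUB_EXT, SUB_MEM, SUB_CYT, TKI_EXT, TKI_MEM, TKI_CYT, ATP_CYT = range(7)
N_COMPARTMENT_VARS = 7
PGP_OFFSET = N_COMPARTMENT_VARS


class SbdOccupant(Enum):
    """Occupant of the substrate-binding domain."""

    EMPTY = 0
    PACLITAXEL = 1  # the transported substrate (paclitaxel or calcein)
    TKI = 2


class NbdOccupant(Enum):
    """Occupant of the nucleotide-binding domain."""

    EMPTY = 0
    ATP = 1
    TKI = 2


@dataclass(frozen=True, order=True)
class PgpState:
    """One pump configuration: (SBD occupant, NBD occupant)."""

    sbd: SbdOccupant
    nbd: NbdOccupant

    @property
    def index(self) -> int:
        """Position in the documented row-major SBD x NBD ordering."""
        return 3 * self.sbd.value + self.nbd.value

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.sbd.name},{self.nbd.name})"


def enumerate_states() -> list[PgpState]:
    """The nine pump states in fixed row-major (SBD outer, NBD inner) order."""
    return [PgpState(s, n) for s in SbdOccupant for n in NbdOccupant]


@dataclass(frozen=True)
class KineticParameters:
    """Rate and equilibrium constants plus compartment bookkeeping.

    Dissociation constants follow the four-constant scheme: ``Kd_P``
    (substrate at the SBD), ``Kd_N`` (TKI at the SBD), ``Kd_A`` (ATP at the
    NBD) and ``Kd_I`` (TKI at the NBD).  ``Kd_N`` and ``Kd_I`` may be
    ``inf`` — the mechanism-knockout convention — which removes those binding
    fluxes exactly.  Every Kd satisfies ``Kd = k_off / k_on``.
    """

    Kd_P: float
    Kd_N: float
    Kd_A: float = DEFAULT_KD_ATP
    Kd_I: float = math.inf
    k_on_sbd: float = 1e6  # M^-1 s^-1, common diffusion-limited on-rate
    k_on_nbd: float = 1e6
    k_cat: float = 1.0  # s^-1, lumped transport/hydrolysis turnover
    k_passive_sub: float = 1.0  # s^-1, aqueous->membrane, per face
    k_passive_tki: float = 1.0
    pc_sub: float = 3467.0  # membrane/aqueous partition coefficients
    pc_tki: float = 25704.0
    extracellular_clamped: bool = True
    atp_clamped: bool = True
    V_ext: float = 1000.0 * DEFAULT_GEOMETRY.cytosol_volume_liters
    V_mem: float = DEFAULT_GEOMETRY.membrane_volume_liters
    V_cyt: float = DEFAULT_GEOMETRY.cytosol_volume_liters

    def __post_init__(self) -> None:
        for label in ("Kd_P", "Kd_A"):
            v = getattr(self, label)
            if not (v > 0) or math.isinf(v):
                raise InvalidInputError(f"{label} must be positive and finite, got {v}")
        for label in ("Kd_N", "Kd_I"):
            if not (getattr(self, label) > 0):  # inf allowed
                raise InvalidInputError(f"{label} must be > 0 (inf allowed)")
        for label in (
            "k_on_sbd",
            "k_on_nbd",
            "k_passive_sub",
            "k_passive_tki",
            "pc_sub",
            "pc_tki",
            "V_ext",
            "V_mem",
            "V_cyt",
        ):
            v = getattr(self, label)
            if not (v > 0) or math.isinf(v):
                raise InvalidInputError(f"{label} must be positive and finite, got {v}")
        if self.k_cat < 0:
            raise InvalidInputError("k_cat must be >= 0")

    def knockout(self, which: str) -> "KineticParameters":
        """Return a copy with ``Kd_N`` or ``Kd_I`` set to infinity."""
        if which not in ("Kd_N", "Kd_I"):
            raise InvalidInputError(f"can only knock out Kd_N or Kd_I, not {which}")
        return replace(self, **{which: math.inf})


@dataclass
class SystemState:
    """The 16 model variables as named fields plus a pump-state map."""

    pac_extracellular: float
    pac_membrane: float
    pac_cytosol: float
    tki_extracellular: float
    tki_membrane: float
    tki_cytosol: float
    atp_cytosol: float
    pgp: Mapping[PgpState, float]

    def __post_init__(self) -> None:
        states = enumerate_states()
        if set(self.pgp) != set(states):
            raise InvalidStateError("pgp map must cover exactly the 9 pump states")
        self.validate()

    def validate(self) -> None:
        for v in self.to_vector():
            if v < 0 or not math.isfinite(v):
                raise InvalidStateError(f"concentrations must be finite and >= 0, got {v}")

    @property
    def pgp_total(self) -> float:
        return float(sum(self.pgp.values()))

    def to_vector(self) -> np.ndarray:
        y = np.empty(N_COMPARTMENT_VARS + 9)
        y[:N_COMPARTMENT_VARS] = (
            self.pac_extracellular,
            self.pac_membrane,
            self.pac_cytosol,
            self.tki_extracellular,
            self.tki_membrane,
            self.tki_cytosol,
            self.atp_cytosol,
        )
        for s, c in self.pgp.items():
            y[PGP_OFFSET + s.index] = c
        return y

    @classmethod
    def from_vector(cls, y: Sequence[float]) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_COMPARTMENT_VARS + 9,):
            raise InvalidStateError(f"expected 16 variables, got shape {y.shape}")
        pgp = {s: float(y[PGP_OFFSET + s.index]) for s in enumerate_states()}
        return cls(*map(float, y[:N_COMPARTMENT_VARS]), pgp=pgp)


class ReactionNetwork:
    """A list of (at most bimolecular) mass-action reactions.

    Each reaction ``i`` has rate ``k[i] * y[a] * y[b]`` (``b`` optional) and a
    stoichiometry map variable -> signed coefficient.  Coefficients carry the
    compartment volume ratios, so ``dy = S r`` conserves moles by
    construction.  Clamped variables get an exactly zero derivative and zero
    Jacobian row.
    """

    def __init__(self, n_vars: int, clamped: Iterable[int] = ()):  # noqa: D107
        self.n_vars = n_vars
        self.clamped = np.array(sorted(set(clamped)), dtype=int)
        self._k: list[float] = []
        self._reactants: list[tuple[int, ...]] = []
        self._stoich: list[dict[int, float]] = []
        self._finalized = False

    def add(
        self, k: float, reactants: Sequence[int], stoich: Mapping[int, float]
    ) -> None:
        """Register one reaction; a zero rate constant is silently dropped."""
        if self._finalized:
            raise MisuseError("network already finalized")
        if k < 0 or not math.isfinite(k):
            raise InvalidInputError(f"rate constant must be finite and >= 0, got {k}")
        if k == 0.0:
            return
        if not 1 <= len(reactants) <= 2:
            raise InvalidInputError("reactions must have one or two reactant factors")
        self._k.append(float(k))
        self._reactants.append(tuple(int(i) for i in reactants))
        self._stoich.append({int(i): float(c) for i, c in stoich.items()})

    def finalize(self) -> "ReactionNetwork":
        n_rx = len(self._k)
        self.k = np.asarray(self._k)
        self.r0 = np.array([r[0] for r in self._reactants], dtype=int)
        # unimolecular reactions point their second factor at a padded 1.0
        self.r1 = np.array(
            [r[1] if len(r) == 2 else self.n_vars for r in self._reactants], dtype=int
        )
        entries = [
            (irx, v, c)
            for irx, st in enumerate(self._stoich)
            for v, c in st.items()
        ]
        if entries:
            self.s_rx = np.array([e[0] for e in entries], dtype=int)
            self.s_var = np.array([e[1] for e in entries], dtype=int)
            self.s_coef = np.array([e[2] for e in entries])
        else:  # pragma: no cover - degenerate empty network
            self.s_rx = np.empty(0, dtype=int)
            self.s_var = np.empty(0, dtype=int)
            self.s_coef = np.empty(0)
        self.n_reactions = n_rx
        self._finalized = True
        return self

    # -- callables handed to the integrator ---------------------------------

    def rates(self, y: np.ndarray) -> np.ndarray:
        ye = np.append(y, 1.0)
        return self.k * ye[self.r0] * ye[self.r1]

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(self.n_vars)
        r = self.rates(y)
        np.add.at(dy, self.s_var, self.s_coef * r[self.s_rx])
        if self.clamped.size:
            dy[self.clamped] = 0.0
        return dy

    def gross_flux(self, y: np.ndarray) -> np.ndarray:
        """Per-variable sum of absolute flux contributions (M/s).

        Used to scale steady-state residual tests: near equilibrium the net
        derivative is a cancellation of gross fluxes, so roundoff in the net
        is proportional to the gross.
        """
        g = np.zeros(self.n_vars)
        r = self.rates(y)
        np.add.at(g, self.s_var, np.abs(self.s_coef * r[self.s_rx]))
        return g

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        J = np.zeros((self.n_vars, self.n_vars))
        for irx, (k, st) in enumerate(zip(self._k, self._stoich)):
            r = self._reactants[irx]
            if len(r) == 1:
                grads = ((r[0], k),)
            else:
                a, b = r
                grads = ((a, k * y[b]), (b, k * y[a]))
            for var, coef in st.items():
                for col, g in grads:
                    J[var, col] += coef * g
        if self.clamped.size:
            J[self.clamped, :] = 0.0
        return J


# ---------------------------------------------------------------------------
# Network construction


def _sbd_alphabet(noncompetitive: bool) -> list[frozenset[str]]:
    """SBD occupancy sets in documented order.

    Competitive: empty / substrate / TKI (mutually exclusive).
    Noncompetitive: two independent sub-sites, adding the doubly-occupied set.
    """
    base = [frozenset(), frozenset({"SUB"}), frozenset({"TKI"})]
    if noncompetitive:
        base.append(frozenset({"SUB", "TKI"}))
    return base


def pump_state_labels(noncompetitive: bool = False) -> list[tuple[frozenset, str]]:
    """(SBD occupancy set, NBD occupant) labels matching the variable layout."""
    nbd = ["EMPTY", "ATP", "TKI"]
    return [(s, n) for s in _sbd_alphabet(noncompetitive) for n in nbd]


def n_variables(noncompetitive: bool = False) -> int:
    return N_COMPARTMENT_VARS + len(pump_state_labels(noncompetitive))


def build_network(
    params: KineticParameters,
    noncompetitive: bool = False,
    extra_clamped: Iterable[int] = (),
) -> ReactionNetwork:
    """Assemble the mass-action reaction network for the pump system.

    With ``noncompetitive=False`` this is the canonical 16-variable system
    (9 pump states); with ``noncompetitive=True`` the SBD holds two
    independent sub-sites (12 pump states, 19 variables).
    """
    labels = pump_state_labels(noncompetitive)
    state_index = {lab: PGP_OFFSET + i for i, lab in enumerate(labels)}
    n = N_COMPARTMENT_VARS + len(labels)

    clamped: set[int] = set(extra_clamped)
    if params.extracellular_clamped:
        clamped |= {SUB_EXT, TKI_EXT}
    if params.atp_clamped:
        clamped.add(ATP_CYT)

    net = ReactionNetwork(n, clamped=clamped)

    v_mem = params.V_mem
    ratio_ext = v_mem / params.V_ext
    ratio_cyt = v_mem / params.V_cyt

    # Passive aqueous <-> membrane exchange, both faces, each direction.
    # Rates act on the source concentration; the aqueous-side coefficient is
    # scaled by V_mem/V_aq so moles balance.  Reverse rate k_p/PC makes the
    # equilibrium membrane/aqueous ratio equal the partition coefficient.
    for aq, mem, k_p, pc, ratio in (
        (SUB_EXT, SUB_MEM, params.k_passive_sub, params.pc_sub, ratio_ext),
        (SUB_CYT, SUB_MEM, params.k_passive_sub, params.pc_sub, ratio_cyt),
        (TKI_EXT, TKI_MEM, params.k_passive_tki, params.pc_tki, ratio_ext),
        (TKI_CYT, TKI_MEM, params.k_passive_tki, params.pc_tki, ratio_cyt),
    ):
        net.add(k_p, (aq,), {mem: +1.0, aq: -ratio})
        net.add(k_p / pc, (mem,), {mem: -1.0, aq: +ratio})

    def _binding(site_from, site_to, ligand_idx, kd, k_on, ligand_ratio):
        """Reversible ligand binding between two pump states; skipped at Kd=inf."""
        if math.isinf(kd):
            return
        net.add(
            k_on,
            (state_from := site_from, ligand_idx),
            {state_from: -1.0, site_to: +1.0, ligand_idx: -ligand_ratio},
        )
        net.add(
            kd * k_on,
            (site_to,),
            {site_to: -1.0, site_from: +1.0, ligand_idx: +ligand_ratio},
        )

    sbd_sets = _sbd_alphabet(noncompetitive)
    nbd_occ = ["EMPTY", "ATP", "TKI"]

    # SBD association/dissociation (membrane pool; same volume basis => ratio 1)
    for occ, ligand_idx, kd in (
        ("SUB", SUB_MEM, params.Kd_P),
        ("TKI", TKI_MEM, params.Kd_N),
    ):
        for s in sbd_sets:
            if occ in s or (s | {occ}) not in sbd_sets:
                continue
            for nb in nbd_occ:
                _binding(
                    state_index[(s, nb)],
                    state_index[(s | {occ}, nb)],
                    ligand_idx,
                    kd,
                    params.k_on_sbd,
                    1.0,
                )

    # NBD association/dissociation (cytosolic pool)
    for occ, ligand_idx, kd in (("ATP", ATP_CYT, params.Kd_A), ("TKI", TKI_CYT, params.Kd_I)):
        for s in sbd_sets:
            _binding(
                state_index[(s, "EMPTY")],
                state_index[(s, occ)],
                ligand_idx,
                kd,
                params.k_on_nbd,
                ratio_cyt,
            )

    # Efflux: ATP-loaded states eject one SBD occupant to the extracellular
    # pool, consume the ATP and reset the NBD.  No basal (empty-SBD) ATPase.
    for s in sbd_sets:
        for occ, ext_idx in (("SUB", SUB_EXT), ("TKI", TKI_EXT)):
            if occ not in s:
                continue
            net.add(
                params.k_cat,
                (state_index[(s, "ATP")],),
                {
                    state_index[(s, "ATP")]: -1.0,
                    state_index[(s - {occ}, "EMPTY")]: +1.0,
                    ext_idx: +ratio_ext,
                    ATP_CYT: -ratio_cyt,
                },
            )

    return net.finalize()


def pgp_indices(noncompetitive: bool = False) -> np.ndarray:
    """Vector indices of the pump-state variables."""
    return np.arange(PGP_OFFSET, n_variables(noncompetitive))


def rhs(
    state: SystemState,
    params: KineticParameters,
    drugs: Mapping[str, object] | None = None,
) -> SystemState:
    """Time derivative of a validated :class:`SystemState`.

    This is the checked, user-facing entry point; integration uses the raw
    vectorized callables on :class:`ReactionNetwork` directly.  ``drugs``
    (optional) is checked to contain the canonical substrate/ATP entries so
    misconfigured parameter maps fail fast.
    """
    state.validate()
    if drugs is not None:
        missing = {"paclitaxel", "atp"} - {k.lower() for k in drugs}
        if missing:
            raise ConfigurationError(f"unknown/missing drug names: sorted({missing!r})")
    net = build_network(params)
    dy = net.rhs(0.0, state.to_vector())
    pgp = {s: float(dy[PGP_OFFSET + s.index]) for s in enumerate_states()}
    d = SystemState.__new__(SystemState)  # derivative entries may be negative
    (
        d.pac_extracellular,
        d.pac_membrane,
        d.pac_cytosol,
        d.tki_extracellular,
        d.tki_membrane,
        d.tki_cytosol,
        d.atp_cytosol,
    ) = map(float, dy[:N_COMPARTMENT_VARS])
    d.pgp = pgp
    return d


def equilibrium_occupancy(
    params: KineticParameters,
    pac_membrane: float,
    tki_membrane: float,
    atp_cytosol: float,
    tki_cytosol: float,
) -> dict[PgpState, float]:
    """Closed-form equilibrium occupancy of the 9-state lattice at k_cat = 0.

    With site-independent dissociation constants the two sites equilibrate
    independently, so each state's fraction is the product of the SBD and NBD
    competitive-binding isotherms.
    """
    if params.k_cat != 0:
        raise MisuseError("equilibrium occupancy is defined only for k_cat = 0")

    def _iso(loads: list[float]) -> list[float]:
        z = 1.0 + sum(loads)
        return [1.0 / z] + [x / z for x in loads]

    def _load(conc: float, kd: float) -> float:
        return 0.0 if math.isinf(kd) else conc / kd

    p_sbd = _iso([_load(pac_membrane, params.Kd_P), _load(tki_membrane, params.Kd_N)])
    p_nbd = _iso([_load(atp_cytosol, params.Kd_A), _load(tki_cytosol, params.Kd_I)])
    occ = {
        PgpState(s, nb): p_sbd[s.value] * p_nbd[nb.value]
        for s in SbdOccupant
        for nb in NbdOccupant
    }
    return occ
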