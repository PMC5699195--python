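"""Thermodynamic parameter derivation.

Converts the printed physical quantities that parameterize the transport
model into the units the ODE system consumes:

* binding free energy (kcal/mol) <-> dissociation constant (M, 1 M standard
  state),
* aqueous docking affinity + octanol/water partition coefficient ->
  effective membrane-phase binding affinity,
* transporter copy number + cell geometry -> membrane-shell molarity.

All free energies are in kcal/mol, all concentrations molar, all lengths
meters, all volumes liters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import pandas as pd

from .errors import InvalidInputError

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Physiological temperature (K) used for every derivation in this package.
PHYSIOLOGICAL_TEMPERATURE_K = 310.0

#: Avogadro's number (mol^-1).
AVOGADRO = 6.02214076e23

#: Required columns of a drug parameter table.
DRUG_TABLE_COLUMNS = (
    "name",
    "dG_sbd_aqueous_kcal_mol",
    "partition_coefficient",
    "Kd_nbd_M",
    "pc_source",
)


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and gas constant bundle for free-energy conversions."""

    temperature: float = PHYSIOLOGICAL_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise InvalidInputError(f"temperature must be > 0 K, got {self.temperature}")
        if not (self.gas_constant > 0):
            raise InvalidInputError("gas_constant must be positive")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature


DEFAULT_CONTEXT = ThermoContext()


@dataclass(frozen=True)
class CellGeometry:
    """Spherical-cell geometry: outer radius and membrane thickness (meters)."""

    radius: float = 7e-6
    membrane_thickness: float = 8e-9

    def __post_init__(self) -> None:
        if not (self.radius > self.membrane_thickness > 0):
            raise InvalidInputError(
                "require radius > membrane_thickness > 0, got "
                f"r={self.radius}, t={self.membrane_thickness}"
            )

    @property
    def membrane_volume_liters(self) -> float:
        """Thin-shell membrane volume 4*pi*r^2*t, in liters (1 m^3 = 1e3 L)."""
        return 4.0 * math.pi * self.radius**2 * self.membrane_thickness * 1e3

    @property
    def cytosol_volume_liters(self) -> float:
        return cytosol_volume(self)


DEFAULT_GEOMETRY = CellGeometry()


def affinity_to_kd(dG: float, ctx: ThermoContext = DEFAULT_CONTEXT) -> float:
    """Convert a binding free energy (kcal/mol) to a dissociation constant (M).

    Uses Kd = exp(dG / RT) with a 1 M standard state, so dG = -7.0 kcal/mol at
    310 K gives 11.6 uM.
    """
    if not math.isfinite(dG):
        raise InvalidInputError(f"binding free energy must be finite, got {dG}")
    return math.exp(dG / ctx.rt)


def kd_to_affinity(kd: float, ctx: ThermoContext = DEFAULT_CONTEXT) -> float:
    """Inverse of :func:`affinity_to_kd`: dG = RT * ln(Kd)."""
    if not (kd > 0) or math.isinf(kd):
        raise InvalidInputError(f"Kd must be positive and finite, got {kd}")
    return ctx.rt * math.log(kd)


def membrane_affinity(
    dG_aqueous: float, pc: float, ctx: ThermoContext = DEFAULT_CONTEXT
) -> float:
    """Effective membrane-phase binding free energy (kcal/mol).

    The membrane-partition free energy RT*ln(PC) is forfeited when a molecule
    leaves the lipid phase for the binding pocket, so the effective affinity is

        dG_mem = dG_aqueous + RT * ln(PC)

    which is weaker (less negative) than the aqueous affinity whenever PC > 1.
    """
    if not math.isfinite(dG_aqueous):
        raise InvalidInputError(f"binding free energy must be finite, got {dG_aqueous}")
    if not (pc > 0) or math.isinf(pc):
        raise InvalidInputError(f"partition coefficient must be positive, got {pc}")
    return dG_aqueous + ctx.rt * math.log(pc)


def copies_to_membrane_molarity(
    n_copies: float, geom: CellGeometry = DEFAULT_GEOMETRY
) -> float:
    """Molar concentration of ``n_copies`` molecules in the membrane shell."""
    if n_copies < 0:
        raise InvalidInputError(f"copy number must be >= 0, got {n_copies}")
    return n_copies / (AVOGADRO * geom.membrane_volume_liters)


def cytosol_volume(geom: CellGeometry = DEFAULT_GEOMETRY) -> float:
    """Cytosol volume (4/3)*pi*(r - t)^3, in liters."""
    return (4.0 / 3.0) * math.pi * (geom.radius - geom.membrane_thickness) ** 3 * 1e3


@dataclass(frozen=True)
class DrugParams:
    """Per-compound thermodynamic and transport parameters.

    Parameters
    ----------
    name
        Compound identifier (lower case).
    dG_sbd_aqueous
        Docking affinity to the substrate-binding site in aqueous phase,
        kcal/mol.  ``None`` means the compound does not bind the SBD (ATP).
    partition_coefficient
        Octanol/water partition coefficient (dimensionless, > 0).
    Kd_nbd
        Dissociation constant at the nucleotide-binding site, molar.
        ``math.inf`` means no NBD binding (paclitaxel, calcein).
    Kd_sbd_membrane
        Membrane-phase SBD dissociation constant, molar; derived from
        ``dG_sbd_aqueous`` and ``partition_coefficient`` when not supplied.
        ``math.inf`` means no SBD binding.
    passive_rate
        First-order aqueous->membrane exchange rate constant per membrane
        face, s^-1.
    """

    name: str
    dG_sbd_aqueous: float | None
    partition_coefficient: float
    Kd_nbd: float
    Kd_sbd_membrane: float = field(default=math.nan)
    passive_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (self.partition_coefficient > 0) or math.isinf(self.partition_coefficient):
            raise InvalidInputError(
                f"{self.name}: partition coefficient must be positive and finite"
            )
        if not (self.Kd_nbd > 0):  # inf allowed
            raise InvalidInputError(f"{self.name}: Kd_nbd must be > 0 or inf")
        if not (self.passive_rate > 0):
            raise InvalidInputError(f"{self.name}: passive_rate must be > 0")
        if math.isnan(self.Kd_sbd_membrane):
            if self.dG_sbd_aqueous is None:
                derived = math.inf
            else:
                derived = affinity_to_kd(
                    membrane_affinity(self.dG_sbd_aqueous, self.partition_coefficient)
                )
            object.__setattr__(self, "Kd_sbd_membrane", derived)
        if not (self.Kd_sbd_membrane > 0):  # inf allowed
            raise InvalidInputError(f"{self.name}: Kd_sbd_membrane must be > 0 or inf")

    def with_kd_nbd(self, kd: float) -> "DrugParams":
        return replace(self, Kd_nbd=kd)


def _row_to_drug(row: pd.Series, ctx: ThermoContext) -> DrugParams:
    dg = row["dG_sbd_aqueous_kcal_mol"]
    dg = None if pd.isna(dg) else float(dg)
    kd_nbd = row["Kd_nbd_M"]
    kd_nbd = math.inf if pd.isna(kd_nbd) or kd_nbd in ("inf", "") else float(kd_nbd)
    pc = float(row["partition_coefficient"])
    if dg is None:
        kd_sbd = math.inf
    else:
        kd_sbd = affinity_to_kd(membrane_affinity(dg, pc, ctx), ctx)
    passive = row.get("passive_rate_per_s")
    passive = 1.0 if passive is None or pd.isna(passive) else float(passive)
    return DrugParams(
        name=str(row["name"]).lower(),
        dG_sbd_aqueous=dg,
        partition_coefficient=pc,
        Kd_nbd=kd_nbd,
        Kd_sbd_membrane=kd_sbd,
        passive_rate=passive,
    )


def drugs_from_table(
    table: pd.DataFrame, ctx: ThermoContext = DEFAULT_CONTEXT
) -> dict[str, DrugParams]:
    """Build a name -> :class:`DrugParams` map from a parameter table."""
    missing = [c for c in DRUG_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"drug table missing columns: {missing}")
    drugs: dict[str, DrugParams] = {}
    for _, row in table.iterrows():
        d = _row_to_drug(row, ctx)
        drugs[d.name] = d
    return drugs


def load_drug_table(path) -> pd.DataFrame:
    """Read a drug parameter CSV (columns :data:`DRUG_TABLE_COLUMNS`)."""
    return pd.read_csv(path)


def bundled_drug_table() -> pd.DataFrame:
    """The package's reference drug table (docking affinities, PCs, NBD Kds)."""
    with resources.files("pgpkinetics.data").joinpath("drugs.csv").open() as fh:
        return pd.read_csv(fh)


def reference_drugs(ctx: ThermoContext = DEFAULT_CONTEXT) -> Mapping[str, DrugParams]:
    """Drug parameters for nilotinib, imatinib, dasatinib, paclitaxel and ATP."""
    return drugs_from_table(bundled_drug_table(), ctx)
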