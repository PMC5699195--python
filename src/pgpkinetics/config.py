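"""Run configuration, parameter derivation and the batch pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InvalidInputError
from .pgp_model import DEFAULT_KD_ATP, KineticParameters
from .simulate import (
    DEFAULT_SETTINGS,
    Scenario,
    SolverSettings,
    dose_response,
    improvement_screen,
    run_scenario,
    transition_point,
)
from .thermo import (
    DEFAULT_CONTEXT,
    DrugParams,
    ThermoContext,
    bundled_drug_table,
    drugs_from_table,
    load_drug_table,
)

log = logging.getLogger("pgpkinetics")

_KNOWN_KEYS = {
    "drug_table",
    "scenario_file",
    "output_dir",
    "temperature_K",
    "rtol",
    "atol",
    "log_level",
    "seed",
}


@dataclass
class RunConfig:
    """Configuration for a batch run; unknown keys are rejected at load."""

    drug_table: str | None = None  # None -> bundled reference table
    scenario_file: str | None = None
    output_dir: str = "pgpk_output"
    temperature_K: float = DEFAULT_CONTEXT.temperature
    rtol: float = DEFAULT_SETTINGS.rtol
    atol: float = DEFAULT_SETTINGS.atol
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must hold a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for label in ("drug_table", "scenario_file"):
            p = getattr(cfg, label)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{label} path does not exist: {p}")
        return cfg

    @property
    def context(self) -> ThermoContext:
        return ThermoContext(temperature=self.temperature_K)

    @property
    def settings(self) -> SolverSettings:
        return SolverSettings(rtol=self.rtol, atol=self.atol)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def derive_params(
    table: pd.DataFrame | str | Path | None = None,
    ctx: ThermoContext = DEFAULT_CONTEXT,
    substrate: str = "paclitaxel",
    tki: str | None = None,
) -> tuple[dict[str, DrugParams], KineticParameters | None]:
    """Derive the full drug-parameter map (and, when the substrate is
    present, a baseline :class:`KineticParameters`) from a drug table.

    Each derived value is logged with its provenance (input affinity,
    partition coefficient, resulting membrane-phase Kd).
    """
    if table is None:
        table = bundled_drug_table()
    elif not isinstance(table, pd.DataFrame):
        table = load_drug_table(table)
    drugs = drugs_from_table(table, ctx)
    for d in drugs.values():
        log.info(
            "derived %s: dG_aq=%s kcal/mol, PC=%g -> Kd_sbd_membrane=%.4g M; Kd_nbd=%.4g M",
            d.name,
            d.dG_sbd_aqueous,
            d.partition_coefficient,
            d.Kd_sbd_membrane,
            d.Kd_nbd,
        )
    params = None
    if substrate in drugs:
        kd_a = drugs["atp"].Kd_nbd if "atp" in drugs else DEFAULT_KD_ATP
        tki_params = drugs.get(tki) if tki else None
        params = KineticParameters(
            Kd_P=drugs[substrate].Kd_sbd_membrane,
            Kd_N=tki_params.Kd_sbd_membrane if tki_params else math.inf,
            Kd_A=kd_a,
            Kd_I=tki_params.Kd_nbd if tki_params else math.inf,
            k_passive_sub=drugs[substrate].passive_rate,
            k_passive_tki=tki_params.passive_rate if tki_params else 1.0,
            pc_sub=drugs[substrate].partition_coefficient,
            pc_tki=tki_params.partition_coefficient if tki_params else 1.0,
        )
    return drugs, params


def _parse_scenario(raw: Mapping[str, Any]) -> tuple[str, dict[str, Any]]:
    raw = dict(raw)
    kind = raw.pop("type", "dose_response")
    if kind not in ("dose_response", "mechanisms", "transition_point", "improve"):
        raise ConfigurationError(f"unknown scenario type: {kind!r}")
    return kind, raw


def _sweep_frame(results: Mapping[Any, Any]) -> pd.DataFrame:
    rows = []
    for key, res in results.items():
        for v, r in zip(res.values, res.readouts):
            rows.append({"group": key, "axis": res.axis, "value": v, "readout_M": r})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write artifacts plus a manifest.

    Returns the manifest (also written to ``<output_dir>/manifest.json``).
    Deterministic for identical configs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    drugs, _ = derive_params(config.drug_table, config.context)
    derived = pd.DataFrame(
        [
            {
                "name": d.name,
                "dG_sbd_aqueous_kcal_mol": d.dG_sbd_aqueous,
                "partition_coefficient": d.partition_coefficient,
                "Kd_sbd_membrane_M": d.Kd_sbd_membrane,
                "Kd_nbd_M": d.Kd_nbd,
                "passive_rate_per_s": d.passive_rate,
            }
            for d in drugs.values()
        ]
    )
    derived_path = out_dir / "derived_params.csv"
    derived.to_csv(derived_path, index=False)
    artifacts.append(str(derived_path))

    if config.scenario_file:
        with open(config.scenario_file) as fh:
            scenarios = yaml.safe_load(fh) or []
        if not isinstance(scenarios, list):
            raise ConfigurationError("scenario file must hold a list of scenarios")
        for i, raw in enumerate(scenarios):
            kind, kw = _parse_scenario(raw)
            name = kw.pop("name", f"scenario_{i}")
            path = out_dir / f"{name}.csv"
            try:
                frame = _run_one(kind, kw, drugs, config.settings)
            except (TypeError, InvalidInputError) as exc:
                raise ConfigurationError(f"scenario {name!r}: {exc}") from exc
            frame.to_csv(path, index=False)
            artifacts.append(str(path))

    manifest = {
        "config_digest": config.digest(),
        "config": asdict(config),
        "version": __version__,
        "seed": config.seed,
        "artifacts": artifacts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _run_one(
    kind: str,
    kw: dict[str, Any],
    drugs: Mapping[str, DrugParams],
    settings: SolverSettings,
) -> pd.DataFrame:
    tki = kw.pop("tki", "nilotinib")
    doses = [float(d) for d in kw.pop("doses", list(np.logspace(-8, -4, 9)))]
    base = Scenario(
        tki=tki,
        pac_ext=float(kw.pop("pac_ext", 3e-6)),
        atp=float(kw.pop("atp", 3e-3)),
        pgp_total=float(kw.pop("pgp_total", 10e-6)),
    )
    if kind == "dose_response":
        levels = [float(x) for x in kw.pop("pgp_levels", [0.1e-6, 1e-6, 10e-6, 100e-6])]
        if kw:
            raise ConfigurationError(f"unknown scenario keys: {sorted(kw)}")
        return _sweep_frame(dose_response(tki, doses, levels, base, drugs, settings=settings))
    if kind == "mechanisms":
        from dataclasses import replace as _replace

        from .simulate import Mechanism

        atp_values = [float(a) for a in kw.pop("atp_values", list(np.logspace(-6, -2, 9)))]
        if kw:
            raise ConfigurationError(f"unknown scenario keys: {sorted(kw)}")
        results = {}
        for mech in (Mechanism.BOTH, Mechanism.NBD_ONLY, Mechanism.SBD_ONLY):
            scn = _replace(
                base, tki_ext=1e-6, mechanism=mech, sweep=("atp", tuple(atp_values))
            )
            results[mech.value] = run_scenario(scn, drugs, settings=settings)
        return _sweep_frame(results)
    if kind == "transition_point":
        atp_values = [float(a) for a in kw.pop("atp_values", list(np.logspace(-6, -2, 9)))]
        from dataclasses import replace as _replace

        scn = _replace(base, tki_ext=float(kw.pop("tki_ext", 1e-6)))
        if kw:
            raise ConfigurationError(f"unknown scenario keys: {sorted(kw)}")
        tp = transition_point(tki, atp_values, scn, drugs, settings=settings)
        return pd.DataFrame(
            [{"tki": tki, "transition_atp_M": tp.atp, "ambiguous": tp.ambiguous}]
        )
    # improve
    fold = float(kw.pop("fold", 10.0))
    if kw:
        raise ConfigurationError(f"unknown scenario keys: {sorted(kw)}")
    return _sweep_frame(improvement_screen(tki, base, drugs, doses, fold, settings=settings))
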