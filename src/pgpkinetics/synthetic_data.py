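"""Synthetic inputs for end-to-end testing without external downloads.

Generates calcein-efflux inhibition dose-response curves from the model
itself (known ground-truth NBD Kd, additive Gaussian readout noise) and the
reference scenario grid used by the simulation suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InvalidInputError
from .fitting import (
    AssayParams,
    BindingScenario,
    DoseResponseDataset,
    predict_accumulation,
)
from .simulate import DEFAULT_SETTINGS, Scenario, SolverSettings
from .thermo import DrugParams

__all__ = ["GeneratorSpec", "generate_calcein_dataset", "reference_scenarios"]

RNG_ALGORITHM = "PCG64"

_DEFAULT_DOSES = tuple(np.logspace(-9, -4, 11))


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic inhibition dataset."""

    tki: str = "nilotinib"
    true_Kd_nbd: float = 2e-9
    doses: tuple[float, ...] = _DEFAULT_DOSES
    noise_sd: float = 0.02
    n_replicates: int = 1
    seed: int = 0
    assay: AssayParams = field(default_factory=AssayParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if not self.doses or any(d <= 0 for d in self.doses):
            raise InvalidInputError("doses must be positive")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        if not (self.true_Kd_nbd > 0):
            raise InvalidInputError("true_Kd_nbd must be > 0")

    def metadata(self) -> dict:
        return {
            "tki": self.tki,
            "true_Kd_nbd_M": self.true_Kd_nbd,
            "doses_M": list(self.doses),
            "noise_sd": self.noise_sd,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "rng": RNG_ALGORITHM,
        }


def generate_calcein_dataset(
    spec: GeneratorSpec,
    scenario: BindingScenario = BindingScenario.NONCOMPETITIVE,
    drugs: Mapping[str, DrugParams] | None = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
    predictions: np.ndarray | None = None,
) -> DoseResponseDataset:
    """Model curve at the ground-truth Kd plus seeded Gaussian readout noise.

    ``predictions`` may supply the precomputed noiseless curve over
    ``spec.doses`` (one value per dose) to avoid re-simulating when many
    replicates share a spec.  Readouts are clipped at zero; the RNG
    (:data:`RNG_ALGORITHM`) and seed are recorded in the dataset metadata.
    """
    doses = np.tile(np.asarray(spec.doses), spec.n_replicates)
    replicate = np.repeat(np.arange(spec.n_replicates), len(spec.doses))
    base = DoseResponseDataset(
        tki=spec.tki,
        doses=np.asarray(spec.doses),
        readouts=np.zeros(len(spec.doses)),
        assay=spec.assay,
    )
    if predictions is None:
        predictions = predict_accumulation(
            spec.true_Kd_nbd, base, scenario, drugs, settings
        )
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != (len(spec.doses),):
        raise InvalidInputError("predictions must supply one value per dose")
    rng = np.random.default_rng(spec.seed)
    clean = np.tile(predictions, spec.n_replicates)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.size) if spec.noise_sd else clean.copy()
    noisy = np.clip(noisy, 0.0, None)
    ds = DoseResponseDataset(
        tki=spec.tki,
        doses=doses,
        readouts=noisy,
        assay=spec.assay,
        ground_truth_Kd=spec.true_Kd_nbd,
        replicate=replicate,
        noise_allowance=max(0.25, 6.0 * spec.noise_sd),
    )
    ds.metadata = spec.metadata()  # JSON sidecar payload
    return ds


def write_dataset(dataset: DoseResponseDataset, csv_path, sidecar_path=None) -> None:
    """Write the CSV table plus a JSON sidecar with spec and ground truth."""
    dataset.to_csv(csv_path)
    if sidecar_path is not None:
        meta = getattr(dataset, "metadata", {"tki": dataset.tki})
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def reference_scenarios() -> list[Scenario]:
    """The published simulation grid.

    Extracellular paclitaxel {0.03, 0.3, 3} uM, pump levels
    {0.1, 1, 10, 100} uM, ATP swept over 1 uM - 10 mM, for each of the three
    TKIs; ATP defaults to 3 mM and the effective pump level to 10 uM.
    """
    atp_sweep = tuple(np.logspace(-6, -2, 25))
    out: list[Scenario] = []
    for tki in ("nilotinib", "imatinib", "dasatinib"):
        for pac in (0.03e-6, 0.3e-6, 3e-6):
            for pgp in (0.1e-6, 1e-6, 10e-6, 100e-6):
                out.append(
                    Scenario(tki=tki, pac_ext=pac, atp=3e-3, pgp_total=pgp)
                )
        out.append(
            Scenario(
                tki=tki,
                pac_ext=3e-6,
                tki_ext=1e-6,
                pgp_total=10e-6,
                sweep=("atp", atp_sweep),
            )
        )
    return out
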