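"""Synthetic plate-reader datasets with replicate structure and noise.

Emulates the shape of the study's deposited raw data: long-format rows of
(culture_type, environment, replicate, week, time_h, od) covering 30
long-starvation cultures (3 compositions x 2 environments x 5 replicates,
weeks 1-6, 0.5 h grid over 24 h) plus a 16-replicate short-starvation plate
(recorded as week 0).

Replicate variability enters as a per-culture jitter of the lag lengths,
with a standard deviation that scales with each cell type's death rate —
NQ cultures, whose residual division during starvation makes them drift
apart, show more replicate scatter than Q cultures.  Measurement noise is
multiplicative plus additive on OD: ``od * (1 + e_mult) + e_add``,
truncated at 0.  Model biomass below the calibration cubic's intercept
(220,300 cells per well) has no positive OD preimage and is recorded at the
OD 0 detection floor.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .curves import CONVERSION_COEFFS, OD_MAX, biomass_to_od, od_to_biomass
from .model import ModelParams
from .scenarios import Scenario, run_long_starvation, run_short_starvation

__all__ = [
    "PLATE_COLUMNS",
    "NoiseModel",
    "generate_plate_dataset",
    "default_scenarios",
    "write_plate_csv",
    "read_plate_csv",
]

#: Mandatory columns of the plate-series schema, in canonical order.
PLATE_COLUMNS = ("culture_type", "environment", "replicate", "week", "time_h", "od")

_COLUMN_TYPES = {"replicate": int, "week": int, "time_h": float, "od": float}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement and replicate noise for the generator.

    sigma_add / sigma_mult: additive and multiplicative OD noise SDs.
    replicate_effect_sd: SD (hours) of the per-culture lag jitter for a
    hypothetical cell type dying at ``d_nq``; the jitter applied to type X
    is scaled by ``d_X / d_nq``.
    """

    sigma_add: float = 0.005
    sigma_mult: float = 0.01
    replicate_effect_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_add", "sigma_mult", "replicate_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_scenarios(freezing: bool = True, n_replicates: int = 5,
                      short_replicates: int = 16) -> list[Scenario]:
    """The study's plate layout: 6 long-starvation culture types + short plate."""
    out = [
        Scenario(composition=c, environment=e, freezing=freezing,
                 starvation_weeks=6, initial_od=0.8, n_replicates=n_replicates)
        for e in ("simple", "complex")
        for c in ("Q", "NQ", "mixed")
    ]
    out += [
        Scenario(composition=c, environment="simple", freezing=False,
                 starvation_days=4, initial_od=0.4, n_replicates=short_replicates)
        for c in ("Q", "NQ", "mixed")
    ]
    return out


def params_hash(params: ModelParams) -> str:
    blob = json.dumps(asdict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _biomass_to_od_floor(biomass: np.ndarray) -> np.ndarray:
    floor = CONVERSION_COEFFS[3]
    ceiling = od_to_biomass(OD_MAX)
    clipped = np.clip(biomass, floor, ceiling)
    return np.array([biomass_to_od(b) for b in clipped])


def _lag_jitter(rng: np.random.Generator, params: ModelParams,
                noise: NoiseModel) -> tuple[float, float]:
    scale_q = params.d_q / params.d_nq if params.d_nq > 0 else 1.0
    return (
        float(rng.normal(0.0, noise.replicate_effect_sd * scale_q)),
        float(rng.normal(0.0, noise.replicate_effect_sd)),
    )


def generate_plate_dataset(params: ModelParams,
                           scenarios: Optional[Iterable[Scenario]] = None,
                           noise: Optional[NoiseModel] = None,
                           ) -> tuple[pd.DataFrame, dict]:
    """Simulate every scenario x replicate and emit noisy OD readings.

    Returns ``(frame, metadata)`` where ``frame`` follows the plate-series
    schema and ``metadata`` records the seed, parameter hash, noise model
    and the number of noise-truncated readings.  Deterministic under the
    noise model's seed.
    """
    if noise is None:
        noise = NoiseModel()
    scenario_list = list(default_scenarios() if scenarios is None else scenarios)
    if not scenario_list:
        raise ValueError("scenario set must be non-empty")
    params.validate()
    rng = np.random.default_rng(noise.seed)
    rows: list[pd.DataFrame] = []
    truncated = 0
    for scenario in scenario_list:
        for rep in range(1, scenario.n_replicates + 1):
            jitter = _lag_jitter(rng, params, noise)
            if scenario.is_short:
                assays = [run_short_starvation(scenario, params, lag_jitter=jitter)]
            else:
                assays = run_long_starvation(scenario, params, lag_jitter=jitter)
            for assay in assays:
                od_clean = _biomass_to_od_floor(assay.biomass)
                n = len(od_clean)
                od_noisy = (od_clean * (1.0 + rng.normal(0.0, noise.sigma_mult, n))
                            + rng.normal(0.0, noise.sigma_add, n))
                truncated += int(np.sum(od_noisy < 0))
                od_noisy = np.clip(od_noisy, 0.0, None)
                rows.append(pd.DataFrame({
                    "culture_type": scenario.composition,
                    "environment": scenario.environment,
                    "replicate": rep,
                    "week": assay.week,
                    "time_h": assay.times,
                    "od": od_noisy,
                }))
    frame = pd.concat(rows, ignore_index=True)
    metadata = {
        "seed": noise.seed,
        "params_hash": params_hash(params),
        "noise": asdict(noise),
        "n_rows": int(len(frame)),
        "truncated_points": truncated,
    }
    return frame, metadata


def write_plate_csv(data: pd.DataFrame, path, metadata: Optional[dict] = None) -> None:
    """Write a plate-series frame as CSV (plus an optional JSON sidecar)."""
    _check_schema(data, where=str(path))
    path = Path(path)
    ordered = [*PLATE_COLUMNS, *[c for c in data.columns if c not in PLATE_COLUMNS]]
    data[ordered].to_csv(path, index=False)
    if metadata is not None:
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(metadata, indent=2, sort_keys=True)
        )


def read_plate_csv(path) -> pd.DataFrame:
    """Read a plate-series CSV, normalising column dtypes.

    Integer-like strings in ``replicate``/``week`` are parsed to integers.
    Unknown extra columns are preserved with a warning.
    """
    frame = pd.read_csv(path)
    _check_schema(frame, where=str(path))
    extra = [c for c in frame.columns if c not in PLATE_COLUMNS]
    if extra:
        warnings.warn(f"{path}: preserving unknown column(s) {extra}", stacklevel=2)
    for col, typ in _COLUMN_TYPES.items():
        frame[col] = frame[col].astype(typ)
    return frame


def _check_schema(frame: pd.DataFrame, where: str) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{where}: plate series missing column(s) {missing}")
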