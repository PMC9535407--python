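"""Seeded generators for fixture datasets.

Emit template-valid record lists with the statistical structure the
cleaning and allometry routines assume: a dominant adult component
(normal or lognormal), a smaller juvenile component, a configurable
share of records with unknown life stage, and optional gross
contamination (unit-scale errors, digit transpositions). Ground truth
travels in a separate sidecar (never in the template itself), so a
fixture is indistinguishable from real input to the code under test.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from vertraits.records import TraitRecord

__all__ = [
    "PopulationSpec",
    "AllometrySpec",
    "gen_population",
    "gen_allometric_dataset",
    "gen_messy_template",
]


@dataclass(frozen=True)
class PopulationSpec:
    species_name: str = "Otospermophilus beecheyi"
    trait_term: str = "body mass"
    trait_iri: str = "OBA:VT0001259"
    #: "normal" or "lognormal"; location/scale are on the raw scale for
    #: normal, and meanlog10/sdlog10 for lognormal
    adult_distribution: str = "lognormal"
    location: float = np.log10(600.0)
    scale: float = 0.04
    n_adults_labeled: int = 28
    n_juveniles_labeled: int = 0
    n_unknown_adults: int = 194
    n_unknown_juveniles: int = 11
    juvenile_scale: float = 0.4
    #: contamination rates applied after drawing, recorded in the truth sidecar
    rate_unit_error: float = 0.0  # value multiplied or divided by 1000
    rate_transposition: float = 0.0  # two adjacent digits swapped
    unit: str = "g"
    year_collected: int = 1990
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_adults_labeled",
            "n_juveniles_labeled",
            "n_unknown_adults",
            "n_unknown_juveniles",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.juvenile_scale < 1):
            raise ValueError("juvenile_scale must be in (0, 1)")
        for name in ("rate_unit_error", "rate_transposition"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.adult_distribution not in ("normal", "lognormal"):
            raise ValueError("adult_distribution must be 'normal' or 'lognormal'")


@dataclass(frozen=True)
class AllometrySpec:
    intercept: float = 1.45
    slope: float = 2.04
    residual_sd: float = 0.08  # log10 scale
    n: int = 27
    x_range: tuple[float, float] = (29.0, 38.0)  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        lo, hi = self.x_range
        if not (0 < lo <= hi):
            raise ValueError("x_range must be positive")


def _draw_adults(rng: np.random.Generator, spec: PopulationSpec, n: int) -> np.ndarray:
    if spec.adult_distribution == "normal":
        return np.abs(rng.normal(spec.location, spec.scale, n)) + 1e-9
    return 10 ** rng.normal(spec.location, spec.scale, n)


def _draw_juveniles(rng: np.random.Generator, spec: PopulationSpec, n: int) -> np.ndarray:
    if spec.adult_distribution == "normal":
        loc = spec.location * spec.juvenile_scale
        return np.abs(rng.normal(loc, spec.scale * spec.juvenile_scale, n)) + 1e-9
    loc = spec.location + np.log10(spec.juvenile_scale)
    return 10 ** rng.normal(loc, spec.scale, n)


def _transpose_digits(value: float, rng: np.random.Generator) -> float:
    digits = f"{value:.6g}"
    positions = [
        i
        for i in range(len(digits) - 1)
        if digits[i].isdigit() and digits[i + 1].isdigit() and digits[i] != digits[i + 1]
    ]
    if not positions:
        return value * 10  # fallback corruption
    i = int(rng.choice(positions))
    swapped = digits[:i] + digits[i + 1] + digits[i] + digits[i + 2 :]
    return float(swapped)


def gen_population(
    spec: PopulationSpec,
) -> tuple[list[TraitRecord], pd.DataFrame]:
    """Generate a species x trait fixture and its ground-truth sidecar.

    The sidecar has one row per record: diagnosticID, trueStage
    (adult/juvenile) and contamination ("", "unit", "transposed").
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = [
        ("adult", "adult", _draw_adults(rng, spec, spec.n_adults_labeled)),
        ("juvenile", "juvenile", _draw_juveniles(rng, spec, spec.n_juveniles_labeled)),
        ("unknown", "adult", _draw_adults(rng, spec, spec.n_unknown_adults)),
        ("unknown", "juvenile", _draw_juveniles(rng, spec, spec.n_unknown_juveniles)),
    ]

    records: list[TraitRecord] = []
    truth_rows: list[dict] = []
    counter = 0
    for label, true_stage, values in blocks:
        for value in values:
            counter += 1
            contamination = ""
            v = float(value)
            if spec.rate_unit_error and rng.random() < spec.rate_unit_error:
                v = v * 1000.0 if rng.random() < 0.5 else v / 1000.0
                contamination = "unit"
            elif spec.rate_transposition and rng.random() < spec.rate_transposition:
                v = _transpose_digits(v, rng)
                contamination = "transposed"
            genus = spec.species_name.split()[0][:4].lower()
            sample_id = f"{genus}{counter:05d}"
            records.append(
                TraitRecord(
                    diagnostic_id=f"{sample_id}_{spec.trait_term}",
                    material_sample_id=sample_id,
                    scientific_name=spec.species_name,
                    trait_term=spec.trait_term,
                    trait_iri=spec.trait_iri,
                    measurement_value=v,
                    measurement_unit=spec.unit,
                    verbatim_value=repr(v),
                    verbatim_unit=spec.unit,
                    life_stage=label,
                    year_collected=spec.year_collected,
                    basis_of_record="modern",
                )
            )
            truth_rows.append(
                {
                    "diagnosticID": records[-1].diagnostic_id,
                    "trueStage": true_stage,
                    "contamination": contamination,
                }
            )
    return records, pd.DataFrame(truth_rows)


def gen_allometric_dataset(
    spec: AllometrySpec,
) -> tuple[pd.DataFrame, dict]:
    """Paired (x, y) table under the log-log scaling model, plus truth sidecar.

    x is uniform on ``x_range`` (mm); ``log10 y = intercept + slope*log10 x
    + Normal(0, residual_sd)`` with y in grams.
    """
    rng = np.random.default_rng(spec.seed)
    x = rng.uniform(spec.x_range[0], spec.x_range[1], spec.n)
    log_y = spec.intercept + spec.slope * np.log10(x) + rng.normal(
        0.0, spec.residual_sd, spec.n
    )
    df = pd.DataFrame(
        {
            "materialSampleID": [f"spec{i + 1:04d}" for i in range(spec.n)],
            "lengthMm": x,
            "massG": 10**log_y,
        }
    )
    truth = asdict(spec)
    truth["x_range"] = list(spec.x_range)
    return df, truth


def gen_messy_template(
    n_specimens: int = 10,
    traits: Sequence[tuple[str, str]] = (
        ("hindfoot length", "mm"),
        ("total length", "cm"),
        ("weight", "kg"),
    ),
    blank_fraction: float = 0.1,
    species_name: str = "Peromyscus maniculatus",
    seed: int = 0,
) -> pd.DataFrame:
    """Wide-format table with synonym headers, mixed units, and blank cells.

    ``traits`` pairs a synonym column header with its (verbatim) unit.
    Exactly ``round(blank_fraction * n_cells)`` cells are blanked, chosen
    without replacement, deterministically under the seed.
    """
    rng = np.random.default_rng(seed)
    n_traits = len(traits)
    data: dict[str, object] = {
        "materialSampleID": [f"ms{i + 1:04d}" for i in range(n_specimens)],
        "scientificName": [species_name] * n_specimens,
        "lifeStage": ["adult"] * n_specimens,
        "yearCollected": [2000] * n_specimens,
    }
    cells = np.round(rng.uniform(10, 100, (n_specimens, n_traits)), 2)
    n_blank = round(blank_fraction * n_specimens * n_traits)
    flat = rng.choice(n_specimens * n_traits, size=n_blank, replace=False)
    mask = np.zeros(n_specimens * n_traits, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(n_specimens, n_traits)
    for j, (header, _unit) in enumerate(traits):
        column = [
            "" if mask[i, j] else f"{cells[i, j]:g}" for i in range(n_specimens)
        ]
        data[header] = column
    return pd.DataFrame(data)


def write_truth_sidecar(truth: pd.DataFrame | dict, path: str | Path) -> None:
    if isinstance(truth, pd.DataFrame):
        truth.to_csv(path, index=False)
    else:
        Path(path).write_text(json.dumps(truth, indent=2) + "\n")
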