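"""Bundled benchmark dataset and synthetic product panels.

The benchmark is a panel of 42 commercial breakfast cereals (extruded,
flakes, bars, muesli and granola) with macronutrient composition per 100 g,
in-vivo glycemic index, model-predicted GI, and observed/predicted glycemic
load for a 30 g serving.  It is shipped as a CSV fixture with a recorded
digest so transcription drift is caught at load time.

Synthetic panels stand in for proprietary calibration datasets: compositions
are drawn uniformly within the benchmark's per-nutrient ranges, starch
availability uniformly within the rapidly-digestible-starch range observed
for these process types, true GIs come from the forward model, and noisy
GIs add Gaussian measurement error at the in-vivo standard error.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    CoefficientTable,
    Composition,
    GlycoError,
    default_coefficients,
    predict_gi,
)

__all__ = [
    "BenchmarkRecord",
    "SyntheticPanel",
    "load_benchmark",
    "load_benchmark_frame",
    "generate_panel",
    "BENCHMARK_SERVING_G",
    "DEFAULT_COMPOSITION_RANGES",
    "RDS_RANGE",
]

#: serving size (g) on which the benchmark GLs are expressed
BENCHMARK_SERVING_G = 30.0

#: rapidly-digestible-starch fraction range across the benchmark processes
RDS_RANGE = (0.65, 0.88)

#: per-nutrient sampling bounds (g/100 g), the benchmark's min/max envelope
DEFAULT_COMPOSITION_RANGES: dict[str, tuple[float, float]] = {
    "sucrose": (0.7, 30.0),
    "starch": (33.4, 74.7),
    "soluble fiber": (0.7, 3.2),
    "insoluble fiber": (2.0, 9.7),
    "fat": (1.2, 13.7),
    "protein": (4.9, 14.4),
}

#: wider per-nutrient bounds emulating a heterogeneous calibration campaign
#: (infant cereals, cereal bars, biscuits, dairy beverages) rather than the
#: breakfast-cereal envelope; identifies the dilution coefficients far
#: better because fibers, fat and protein vary over their full food ranges
CALIBRATION_RANGES: dict[str, tuple[float, float]] = {
    "sucrose": (1.0, 45.0),
    "lactose": (0.0, 20.0),
    "starch": (0.0, 75.0),
    "soluble fiber": (0.0, 10.0),
    "insoluble fiber": (0.0, 15.0),
    "fat": (0.5, 30.0),
    "protein": (2.0, 30.0),
}

_FIXTURE_NAME = "benchmark_table1.csv"
_FIXTURE_SHA256 = "052b3c427fd5c6c4732d8a0d8e45442595df2d679c0fce338b6c7d582b6d9214"

_NUTRIENT_COLUMNS = {
    "sucrose": "sucrose",
    "starch": "starch",
    "fiber_sol": "soluble fiber",
    "fiber_ins": "insoluble fiber",
    "fat": "fat",
    "protein": "protein",
}


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmark product with its observed and predicted GI/GL."""

    product_id: str
    process: str
    composition: Composition
    gi_observed: int
    gi_predicted_printed: int
    gl_observed_g: float
    gl_predicted_printed_g: float


def _fixture_bytes() -> bytes:
    return resources.files("glyco.data").joinpath(_FIXTURE_NAME).read_bytes()


def load_benchmark_frame() -> pd.DataFrame:
    """The benchmark as a DataFrame with the fixture's original columns."""
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise GlycoError(
            f"benchmark fixture corrupted: sha256 {digest} != {_FIXTURE_SHA256}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_benchmark() -> list[BenchmarkRecord]:
    """All 42 benchmark products, exactly as printed in the source table."""
    df = load_benchmark_frame()
    records = []
    for row in df.itertuples(index=False):
        amounts = {canon: getattr(row, col) for col, canon in _NUTRIENT_COLUMNS.items()}
        records.append(
            BenchmarkRecord(
                product_id=row.product_id,
                process=row.process,
                composition=Composition(amounts=amounts, serving_g=BENCHMARK_SERVING_G),
                gi_observed=int(row.gi_obs),
                gi_predicted_printed=int(row.gi_pred),
                gl_observed_g=float(row.gl_obs),
                gl_predicted_printed_g=float(row.gl_pred),
            )
        )
    return records


@dataclass(frozen=True)
class SyntheticPanel:
    """A reproducible synthetic calibration panel.

    ``gi_true`` comes from the forward model under ``b_true``;
    ``gi_noisy`` adds N(0, noise_sd^2) measurement error.
    """

    records: tuple[tuple[Composition, float, float], ...]
    b_true: Mapping[str, float]
    noise_sd: float
    seed: int

    @property
    def compositions(self) -> list[Composition]:
        return [r[0] for r in self.records]

    @property
    def gi_true(self) -> np.ndarray:
        return np.array([r[1] for r in self.records])

    @property
    def gi_noisy(self) -> np.ndarray:
        return np.array([r[2] for r in self.records])


def generate_panel(
    n_products: int,
    b_true: Mapping[str, float] | None = None,
    noise_sd: float = 3.5,
    seed: int = 0,
    composition_ranges: Mapping[str, tuple[float, float]] | None = None,
    availability_range: tuple[float, float] = RDS_RANGE,
    coeffs: CoefficientTable | None = None,
) -> SyntheticPanel:
    """Simulate a panel of products with known true dilution coefficients.

    Compositions are sampled uniformly and independently per nutrient within
    ``composition_ranges`` (no joint distribution is imposed; amounts are not
    renormalised to 100 g because the model is scale-invariant and water
    absorbs the remainder).
    """
    coeffs = coeffs or default_coefficients()
    ranges = dict(composition_ranges or DEFAULT_COMPOSITION_RANGES)
    if b_true is None:
        b_true = {
            n: coeffs[n].effective_b
            for n in ranges
            if n in coeffs and coeffs[n].role != "glycemic"
        }
    lowering = [n for n in ranges if n in b_true]
    if n_products < len(lowering) + 1:
        raise GlycoError(
            f"need at least {len(lowering) + 1} products to identify {len(lowering)} coefficients"
        )
    for name, (lo, hi) in ranges.items():
        if not (hi > lo >= 0):
            raise GlycoError(f"degenerate sampling bounds for {name!r}: ({lo}, {hi})")
    a_lo, a_hi = availability_range
    if not (0 <= a_lo < a_hi <= 1):
        raise GlycoError("availability range must satisfy 0 <= lo < hi <= 1")

    table = coeffs.with_b(b_true)
    rng = np.random.default_rng(seed)
    names = sorted(ranges)
    records = []
    for _ in range(n_products):
        amounts = {n: rng.uniform(*ranges[n]) for n in names}
        availability = (
            float(rng.uniform(a_lo, a_hi)) if amounts.get("starch", 0.0) > 0 else None
        )
        comp = Composition(amounts=amounts, starch_availability=availability)
        gi_true = predict_gi(comp, table).gi_raw
        gi_noisy = gi_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        records.append((comp, gi_true, gi_noisy))
    return SyntheticPanel(
        records=tuple(records), b_true=dict(b_true), noise_sd=noise_sd, seed=seed
    )
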