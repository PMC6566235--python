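"""Hybrid deterministic/empirical model of glycemic index and glycemic load.

The glycemic index (GI) of a product is modelled as the weighted average of
the GIs of its glycemic carbohydrates, corrected for starch availability and
diluted by the non-glycemic nutrients:

    GI = sum_i(x_i * a_i * GI_i) / (sum_i(x_i) + sum_j(x_j * b_j))

where ``x_i`` are the amounts (g per 100 g) of glycemic carbohydrates with
tabulated GIs ``GI_i`` and availability factors ``a_i`` (1 for everything
except starch, where it equals the rapidly-digestible-starch fraction), and
``x_j`` are the amounts of non-glycemic nutrients with empirical GI-lowering
coefficients ``b_j``.  Glycemic load (GL) for a serving is

    GL = GI * glycemic carbohydrate per serving (g) / 100

in grams of glucose equivalent.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("glyco")

__all__ = [
    "GlycoError",
    "NoGlycemicCarbohydrateError",
    "UnknownNutrientError",
    "NutrientSpec",
    "CoefficientTable",
    "Composition",
    "MealComponent",
    "PredictionResult",
    "default_coefficients",
    "predict_gi",
    "predict_gl",
    "fao_meal_gi",
    "combine_compositions",
    "round_gi",
    "MILK_DENSITY_G_PER_ML",
    "AVAILABILITY_PRESETS",
]

#: density used to convert liquid-milk volumes to mass
MILK_DENSITY_G_PER_ML = 1.03

#: per-process presets for the starch availability factor (fraction of
#: rapidly digestible starch); extruded products digest fastest, granola
#: slowest.  Values outside these two anchors are not tabulated.
AVAILABILITY_PRESETS: dict[str, float] = {
    "extruded": 0.88,
    "granola": 0.65,
}


class GlycoError(ValueError):
    """Base error for model input problems."""


class NoGlycemicCarbohydrateError(GlycoError):
    """Raised when a composition contains no glycemic carbohydrate."""


class UnknownNutrientError(GlycoError):
    """Raised when a nutrient name is absent from the coefficient table."""


# Canonical nutrient naming: lower-case, spaces; common synonyms accepted.
_ALIASES = {
    "fiber_sol": "soluble fiber",
    "fiber sol": "soluble fiber",
    "fiber sol.": "soluble fiber",
    "soluble fibre": "soluble fiber",
    "fibre soluble": "soluble fiber",
    "fiber soluble": "soluble fiber",
    "fiber_ins": "insoluble fiber",
    "fiber ins": "insoluble fiber",
    "fiber ins.": "insoluble fiber",
    "insoluble fibre": "insoluble fiber",
    "fibre insoluble": "insoluble fiber",
    "fiber insoluble": "insoluble fiber",
    "beta glucan": "beta-glucan",
    "beta_glucan": "beta-glucan",
    "b-glucan": "beta-glucan",
    "ash": "ashes",
    "minerals": "ashes",
    "proteins": "protein",
    "fats": "fat",
}


def normalize_nutrient(name: str) -> str:
    """Return the canonical lower-case name for a nutrient."""
    key = " ".join(str(name).strip().lower().replace("_", " ").split())
    return _ALIASES.get(key, key)


@dataclass(frozen=True)
class NutrientSpec:
    """Coefficients of a single nutrient.

    role
        ``"glycemic"`` nutrients carry a tabulated GI (``gi``) and an
        availability factor default (1 for everything except starch);
        ``"lowering"`` nutrients carry a dilution coefficient ``b``;
        ``"inert"`` nutrients behave like lowering nutrients with b = 0.
    """

    name: str
    role: str  # glycemic | lowering | inert
    gi: float | None = None
    availability_default: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_nutrient(self.name))
        if self.role not in ("glycemic", "lowering", "inert"):
            raise GlycoError(f"unknown nutrient role {self.role!r}")
        if self.role == "glycemic":
            if self.gi is None:
                raise GlycoError(f"glycemic nutrient {self.name!r} needs a GI")
            if not 0 <= self.gi <= 110:
                raise GlycoError(f"GI of {self.name!r} outside [0, 110]")
            if self.b is not None:
                raise GlycoError(f"glycemic nutrient {self.name!r} cannot have b")
            if self.availability_default is None:
                object.__setattr__(self, "availability_default", 1.0)
            elif not 0 <= self.availability_default <= 1:
                raise GlycoError(f"availability of {self.name!r} outside [0, 1]")
        else:
            if self.gi is not None or self.availability_default is not None:
                raise GlycoError(f"non-glycemic nutrient {self.name!r} cannot have a GI")
            if self.role == "inert":
                if self.b not in (None, 0.0):
                    raise GlycoError(f"inert nutrient {self.name!r} must have b = 0")
                object.__setattr__(self, "b", 0.0)
            else:
                if self.b is None or self.b < 0:
                    raise GlycoError(f"lowering nutrient {self.name!r} needs b >= 0")

    @property
    def effective_b(self) -> float:
        return 0.0 if self.role == "glycemic" else float(self.b or 0.0)


@dataclass(frozen=True)
class CoefficientTable:
    """Registry of the nutrient coefficients in force for a run."""

    specs: Mapping[str, NutrientSpec]

    def __post_init__(self) -> None:
        normalized = {}
        for name, spec in dict(self.specs).items():
            key = normalize_nutrient(name)
            if key != spec.name:
                spec = replace(spec, name=key)
            if key in normalized:
                raise GlycoError(f"duplicate nutrient name {key!r}")
            normalized[key] = spec
        object.__setattr__(self, "specs", normalized)

    def __contains__(self, name: str) -> bool:
        return normalize_nutrient(name) in self.specs

    def __getitem__(self, name: str) -> NutrientSpec:
        key = normalize_nutrient(name)
        try:
            return self.specs[key]
        except KeyError:
            raise UnknownNutrientError(f"unknown nutrient {name!r}") from None

    def glycemic_names(self) -> list[str]:
        return [n for n, s in self.specs.items() if s.role == "glycemic"]

    def lowering_names(self) -> list[str]:
        return [n for n, s in self.specs.items() if s.role == "lowering"]

    def with_b(self, b_values: Mapping[str, float]) -> "CoefficientTable":
        """Return a copy with updated b coefficients for lowering nutrients."""
        specs = dict(self.specs)
        for name, b in b_values.items():
            key = normalize_nutrient(name)
            old = self[key]
            if old.role == "glycemic":
                raise GlycoError(f"{key!r} is glycemic, cannot set b")
            specs[key] = NutrientSpec(key, "lowering", b=float(b))
        return CoefficientTable(specs)


def default_coefficients() -> CoefficientTable:
    """Coefficient table with the reference GIs, availability factors and
    GI-lowering coefficients for common nutrients of starch-based products."""
    g = lambda n, gi, a=1.0: NutrientSpec(n, "glycemic", gi=gi, availability_default=a)
    l = lambda n, b: NutrientSpec(n, "lowering", b=b)
    specs = [
        g("glucose", 100),
        g("fructose", 20),
        g("galactose", 20),
        g("maltose", 105),
        g("trehalose", 70),
        g("sucrose", 62),
        g("lactose", 47),
        g("isomaltulose", 32),
        g("maltotriose", 110),
        g("maltotetraose", 110),
        g("starch", 110),  # availability_default 1.0; override per product
        g("maltodextrin", 110),
        g("maltitol", 35),
        g("xylitol", 12),
        l("beta-glucan", 0.6),
        l("soluble fiber", 0.3),
        l("insoluble fiber", 0.1),
        l("fat", 0.6),
        l("protein", 0.6),
        l("ashes", 0.1),
        NutrientSpec("water", "inert"),
    ]
    return CoefficientTable({s.name: s for s in specs})


@dataclass(frozen=True)
class Composition:
    """Nutrient amounts of a product, in g per 100 g.

    Amounts need not sum to 100; omitted nutrients (typically water) count
    as zero and the model is invariant to uniform rescaling anyway.
    """

    amounts: Mapping[str, float]
    starch_availability: float | None = None
    serving_g: float | None = None

    def __post_init__(self) -> None:
        norm: dict[str, float] = {}
        for name, amount in dict(self.amounts).items():
            key = normalize_nutrient(name)
            amount = float(amount)
            if not math.isfinite(amount) or amount < 0:
                raise GlycoError(f"amount of {key!r} must be finite and >= 0")
            norm[key] = norm.get(key, 0.0) + amount
        object.__setattr__(self, "amounts", norm)
        if self.starch_availability is not None and not 0 <= self.starch_availability <= 1:
            raise GlycoError("starch_availability must lie in [0, 1]")
        if self.serving_g is not None and not self.serving_g > 0:
            raise GlycoError("serving_g must be positive")

    def scaled(self, k: float) -> "Composition":
        return replace(self, amounts={n: k * a for n, a in self.amounts.items()})


@dataclass(frozen=True)
class MealComponent:
    """One component of a meal: a composition plus the mass consumed."""

    composition: Composition
    mass_g: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mass_g) and self.mass_g > 0):
            raise GlycoError("component mass must be finite and positive")


@dataclass(frozen=True)
class PredictionResult:
    """Predicted GI (raw and rounded) with its diagnostics.

    ``numerator``/``denominator`` expose the two halves of the GI quotient;
    ``gl_g`` is present only when a serving size was known.
    """

    gi_raw: float
    gi_rounded: int
    numerator: float
    denominator: float
    glycemic_carb_per_serving_g: float | None = None
    gl_g: float | None = None
    resolved_availability: float | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {
            "gi_raw": round(self.gi_raw, 1),
            "gi_rounded": self.gi_rounded,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "glycemic_carb_per_serving_g": self.glycemic_carb_per_serving_g,
            "gl_g": None if self.gl_g is None else round(self.gl_g, 2),
            "resolved_availability": self.resolved_availability,
            "warnings": list(self.warnings),
        }


def round_gi(gi_raw: float, mode: str = "half-away") -> int:
    """Round a raw GI to an integer.

    ``half-away`` rounds halves away from zero (62.5 -> 63), the reporting
    convention used everywhere; ``truncate`` discards the fractional part
    (51.5 -> 51), provided only because sugar-syrup GIs are sometimes quoted
    that way.
    """
    if gi_raw < 0:
        raise GlycoError("GI cannot be negative")
    if mode == "half-away":
        return int(math.floor(gi_raw + 0.5))
    if mode == "truncate":
        return int(math.trunc(gi_raw))
    raise GlycoError(f"unknown rounding mode {mode!r}")


def _resolve_availability(
    composition: Composition,
    process: str | None,
    presets: Mapping[str, float],
    warn: list[str],
) -> float:
    if composition.starch_availability is not None:
        return composition.starch_availability
    if process is not None:
        key = process.strip().lower()
        if key in presets:
            return presets[key]
        warn.append(f"no availability preset for process {process!r}; using 1.0")
        logger.warning(warn[-1])
        return 1.0
    warn.append("starch present but availability unspecified; assuming 1.0 (fully available)")
    logger.warning(warn[-1])
    return 1.0


def predict_gi(
    composition: Composition,
    coeffs: CoefficientTable | None = None,
    *,
    process: str | None = None,
    availability_presets: Mapping[str, float] = AVAILABILITY_PRESETS,
    unknown_as_inert: bool = False,
    rounding_mode: str = "half-away",
    count_sugar_alcohols_in_gl: bool = True,
) -> PredictionResult:
    """Predict the GI (and GL, if a serving size is set) of a composition.

    Parameters
    ----------
    composition
        Nutrient amounts in g per 100 g, with optional starch availability
        override and serving size.
    coeffs
        Coefficient table; defaults to the bundled reference values.
    process
        Optional process label used to look up a starch availability preset
        when the composition does not carry one.
    unknown_as_inert
        Treat nutrients missing from the table as inert (b = 0) with a
        warning instead of raising; the nutrient list is adaptable and this
        supports compositions with exotic components.
    count_sugar_alcohols_in_gl
        Whether the mass of partially glycemic sugar alcohols (maltitol,
        xylitol) counts toward the glycemic carbohydrate grams of GL.
    """
    coeffs = coeffs or default_coefficients()
    warn: list[str] = []

    glycemic: list[tuple[str, float, NutrientSpec]] = []
    other: list[tuple[float, float]] = []  # (amount, b)
    for name, amount in composition.amounts.items():
        if name not in coeffs:
            if unknown_as_inert:
                warn.append(f"unknown nutrient {name!r} treated as inert (b = 0)")
                logger.warning(warn[-1])
                continue
            raise UnknownNutrientError(f"unknown nutrient {name!r}")
        spec = coeffs[name]
        if spec.role == "glycemic":
            if amount > 0:
                glycemic.append((name, amount, spec))
        else:
            other.append((amount, spec.effective_b))

    if not glycemic:
        raise NoGlycemicCarbohydrateError("no glycemic carbohydrate in composition")

    resolved_a: float | None = None
    numerator = 0.0
    glycemic_sum = 0.0
    gl_mass_sum = 0.0
    for name, amount, spec in glycemic:
        if name == "starch":
            resolved_a = _resolve_availability(composition, process, availability_presets, warn)
            a = resolved_a
        else:
            a = spec.availability_default
        numerator += amount * a * spec.gi
        glycemic_sum += amount
        if count_sugar_alcohols_in_gl or name not in ("maltitol", "xylitol"):
            gl_mass_sum += amount

    denominator = glycemic_sum + sum(amount * b for amount, b in other)
    gi_raw = numerator / denominator

    carb_per_serving = None
    gl = None
    if composition.serving_g is not None:
        carb_per_serving = gl_mass_sum * composition.serving_g / 100.0
        gl = gi_raw * carb_per_serving / 100.0

    return PredictionResult(
        gi_raw=gi_raw,
        gi_rounded=round_gi(gi_raw, rounding_mode),
        numerator=numerator,
        denominator=denominator,
        glycemic_carb_per_serving_g=carb_per_serving,
        gl_g=gl,
        resolved_availability=resolved_a,
        warnings=tuple(warn),
    )


def predict_gl(
    gi: float | PredictionResult,
    composition: Composition,
    serving_g: float | None = None,
    coeffs: CoefficientTable | None = None,
    *,
    count_sugar_alcohols: bool = True,
) -> float:
    """Glycemic load, in grams of glucose equivalent, for a serving.

    GL = GI x glycemic carbohydrate per serving (g) / 100.  The starch
    availability factor does not weight the carbohydrate mass: GL uses the
    unweighted glycemic carbohydrate grams (the factor already acted on GI).
    """
    if isinstance(gi, PredictionResult):
        gi = gi.gi_raw
    serving = serving_g if serving_g is not None else composition.serving_g
    if serving is None:
        raise GlycoError("serving size required for GL")
    if serving <= 0:
        raise GlycoError("serving size must be positive")
    coeffs = coeffs or default_coefficients()
    carbs = 0.0
    for name, amount in composition.amounts.items():
        if name in coeffs and coeffs[name].role == "glycemic":
            if count_sugar_alcohols or name not in ("maltitol", "xylitol"):
                carbs += amount
    return gi * (carbs * serving / 100.0) / 100.0


def fao_meal_gi(foods: Sequence[tuple[float, float]]) -> float:
    """Meal GI under the classical carbohydrate-weighted averaging of
    component foods: sum(c_i * GI_i) / sum(c_i) for glycemic carbohydrate
    amounts c_i (g) and food GIs.  Ignores cross-component dilution; kept as
    the baseline comparator."""
    if not foods:
        raise GlycoError("at least one food required")
    total_c = sum(c for c, _ in foods)
    if total_c <= 0:
        raise GlycoError("at least one food must contribute glycemic carbohydrate")
    for c, _ in foods:
        if c < 0:
            raise GlycoError("carbohydrate amounts must be >= 0")
    return sum(c * gi for c, gi in foods) / total_c


def combine_compositions(
    components: Iterable[MealComponent],
    coeffs: CoefficientTable | None = None,
) -> Composition:
    """Pool meal components into a single composition per 100 g of meal.

    Nutrient masses are summed and re-expressed per 100 g of total meal, so
    that the dilution model sees the whole meal at once (component fats and
    proteins lower the GI of every component's carbohydrates — the behaviour
    plain carbohydrate-weighted averaging cannot represent).  The pooled
    starch availability is the starch-mass-weighted mean of the component
    availabilities; the pooled serving is the total meal mass.
    """
    components = list(components)
    if not components:
        raise GlycoError("at least one meal component required")
    total_mass = sum(c.mass_g for c in components)

    pooled: dict[str, float] = {}
    starch_mass = 0.0
    starch_weighted_a = 0.0
    any_availability = False
    for comp in components:
        for name, amount in comp.composition.amounts.items():
            pooled[name] = pooled.get(name, 0.0) + comp.mass_g * amount / 100.0
        s = comp.composition.amounts.get("starch", 0.0)
        if s > 0:
            mass = comp.mass_g * s / 100.0
            a = comp.composition.starch_availability
            if a is not None:
                any_availability = True
            starch_mass += mass
            starch_weighted_a += mass * (a if a is not None else 1.0)

    amounts = {n: m / total_mass * 100.0 for n, m in pooled.items()}
    availability = None
    if starch_mass > 0 and any_availability:
        availability = starch_weighted_a / starch_mass
    return Composition(amounts=amounts, starch_availability=availability, serving_g=total_mass)
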