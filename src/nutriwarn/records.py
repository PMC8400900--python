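"""Core product-record types shared by every pipeline stage.

A :class:`NutrientPanel` stores nutrient amounts per reference quantity
(100 g for foods, 100 ml for beverages) on either an ``as_sold`` or
``as_consumed`` basis.  Absent nutrients stay ``None`` — they are never
imputed to zero, because missingness drives the exclusion cascade.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Optional

#: Closed set of nutrient field names, in canonical order.
NUTRIENTS: tuple[str, ...] = (
    "energy",
    "total_fat",
    "saturated_fat",
    "total_sugar",
    "added_sugar",
    "sodium",
)

#: Internal units per nutrient (amounts per reference quantity).
NUTRIENT_UNITS: dict[str, str] = {
    "energy": "kcal",
    "total_fat": "g",
    "saturated_fat": "g",
    "total_sugar": "g",
    "added_sugar": "g",
    "sodium": "mg",
}


class Basis(str, enum.Enum):
    AS_SOLD = "as_sold"
    AS_CONSUMED = "as_consumed"


class PerUnit(str, enum.Enum):
    PER_100G = "100g"
    PER_100ML = "100ml"


class TriState(str, enum.Enum):
    """Tri-state ingredient flag: declared present, declared absent, or unknown."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"

    @classmethod
    def coerce(cls, value: object) -> "TriState":
        if isinstance(value, TriState):
            return value
        if value is None:
            return cls.UNKNOWN
        text = str(value).strip().lower()
        if text in ("yes", "y", "true", "1"):
            return cls.YES
        if text in ("no", "n", "false", "0"):
            return cls.NO
        if text in ("", "unknown", "na", "nan", "none"):
            return cls.UNKNOWN
        raise ValueError(f"not a tri-state flag value: {value!r}")


@dataclass(frozen=True)
class NutrientPanel:
    """Nutrient amounts per reference quantity; ``None`` means not declared."""

    energy: Optional[float] = None
    total_fat: Optional[float] = None
    saturated_fat: Optional[float] = None
    total_sugar: Optional[float] = None
    added_sugar: Optional[float] = None
    sodium: Optional[float] = None
    basis: Basis = Basis.AS_CONSUMED
    per: PerUnit = PerUnit.PER_100G

    def get(self, nutrient: str) -> Optional[float]:
        if nutrient not in NUTRIENTS:
            raise KeyError(f"unknown nutrient: {nutrient!r}")
        return getattr(self, nutrient)

    def present(self, nutrient: str) -> bool:
        return self.get(nutrient) is not None

    def amounts(self) -> Iterator[tuple[str, float]]:
        for name in NUTRIENTS:
            value = getattr(self, name)
            if value is not None:
                yield name, value

    def validation_errors(self) -> list[str]:
        """Nutrient-error conditions: negative/non-finite amounts or
        component exceeding its total (saturated fat vs total fat,
        added sugar vs total sugar)."""
        errors: list[str] = []
        for name, value in self.amounts():
            if not math.isfinite(value):
                errors.append(f"{name}: non-finite amount")
            elif value < 0:
                errors.append(f"{name}: negative amount")
        if (
            self.saturated_fat is not None
            and self.total_fat is not None
            and self.saturated_fat > self.total_fat
        ):
            errors.append("saturated_fat exceeds total_fat")
        if (
            self.added_sugar is not None
            and self.total_sugar is not None
            and self.added_sugar > self.total_sugar
        ):
            errors.append("added_sugar exceeds total_sugar")
        return errors

    def is_valid(self) -> bool:
        return not self.validation_errors()

    def scaled(self, factor: float) -> "NutrientPanel":
        """Multiply every present amount by ``factor`` (basis/per untouched)."""
        updates = {name: value * factor for name, value in self.amounts()}
        return replace(self, **updates)


@dataclass(frozen=True)
class IngredientFlags:
    """Added-ingredient declarations used by CWO gating and the SEARO NNS rule."""

    added_sugar: TriState = TriState.UNKNOWN
    added_sodium: TriState = TriState.UNKNOWN
    added_sat_fat: TriState = TriState.UNKNOWN
    nns: TriState = TriState.UNKNOWN

    def get(self, name: str) -> TriState:
        if name not in FLAG_NAMES:
            raise KeyError(f"unknown ingredient flag: {name!r}")
        return getattr(self, name)


FLAG_NAMES: tuple[str, ...] = tuple(f.name for f in fields(IngredientFlags))


@dataclass
class ProductRecord:
    """One packaged product as read from a database extract."""

    barcode: str
    name: str
    category_code: str
    panel: NutrientPanel
    flags: IngredientFlags = field(default_factory=IngredientFlags)
    dilution_factor: Optional[float] = None
    variety_pack: bool = False
    baby_food: bool = False
    nutrient_error: bool = False  # set by the reader on malformed numeric cells

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError("barcode must be non-empty")
        if self.dilution_factor is not None and not self.dilution_factor > 0:
            raise ValueError("dilution_factor must be > 0 when present")
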