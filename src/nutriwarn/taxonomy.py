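"""Registry of the 25 SEARO food categories and the food/beverage split.

The registry ships as a version-controlled CSV (``data/searo_categories.csv``)
carrying code, display name, beverage flag, and the nutrients a category's
rules reference.  Codes are plain strings ("1", "5A", "14B"); the letter
suffix is matched case-insensitively.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional


class UnknownCategoryError(KeyError):
    """Raised for codes outside the registry; callers map this to the
    "no category" exclusion."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown SEARO category code: {self.code!r}"


class ProductForm(str, enum.Enum):
    """The food/beverage dichotomy used by form-scoped models (CWO)."""

    FOOD = "food"
    BEVERAGE = "beverage"


@dataclass(frozen=True)
class SearoCategory:
    code: str
    name: str
    is_beverage: bool
    required_nutrients: frozenset[str]


def _normalize_code(code: str) -> str:
    return code.strip().upper()


class Taxonomy:
    """Immutable lookup table of SEARO categories."""

    def __init__(self, categories: list[SearoCategory]):
        self._by_code: dict[str, SearoCategory] = {}
        for cat in categories:
            key = _normalize_code(cat.code)
            if key in self._by_code:
                raise ValueError(f"duplicate category code: {cat.code}")
            self._by_code[key] = cat

    @classmethod
    def from_csv(cls, path: Path | str) -> "Taxonomy":
        categories = []
        with open(path, newline="", encoding="utf-8") as handle:
            for row in csv.DictReader(handle):
                nutrients = frozenset(
                    n for n in row["required_nutrients"].split(";") if n
                )
                categories.append(
                    SearoCategory(
                        code=row["code"].strip(),
                        name=row["name"].strip(),
                        is_beverage=row["is_beverage"].strip().lower() == "true",
                        required_nutrients=nutrients,
                    )
                )
        return cls(categories)

    @classmethod
    def default(cls) -> "Taxonomy":
        ref = resources.files("nutriwarn.data") / "searo_categories.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def lookup_category(self, code: str) -> SearoCategory:
        if not isinstance(code, str) or not code.strip():
            raise ValueError("category code must be a non-empty string")
        try:
            return self._by_code[_normalize_code(code)]
        except KeyError:
            raise UnknownCategoryError(code) from None

    def __contains__(self, code: str) -> bool:
        try:
            self.lookup_category(code)
        except (UnknownCategoryError, ValueError):
            return False
        return True

    def __iter__(self) -> Iterator[SearoCategory]:
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    def codes(self) -> list[str]:
        return [c.code for c in self]

    def category_for(self, record_code: str) -> Optional[SearoCategory]:
        """Like :meth:`lookup_category` but returns ``None`` instead of raising."""
        try:
            return self.lookup_category(record_code)
        except (UnknownCategoryError, ValueError):
            return None


def product_form(category: SearoCategory) -> ProductForm:
    return ProductForm.BEVERAGE if category.is_beverage else ProductForm.FOOD
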