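"""Deficit codebook: item definitions, validation and schema loading.

A deficit-accumulation frailty index is built from a *codebook* of
age-related health deficits.  Each item maps raw survey response codes to
deficit scores in ``[0, 1]`` (0 = deficit absent, 1 = fully expressed).
The default codebook ships with the package and encodes 41 items covering
chronic diseases, ADL/IADL limitations, sensory and mobility impairment,
self-rated health, somatic and psychological symptoms, body mass and
physical activity; four cardiovascular diagnosis/risk-factor items carry a
flag so they can be dropped in a 37-item sensitivity index.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

__all__ = [
    "DeficitSpec",
    "DeficitSchema",
    "SchemaError",
    "load_schema",
    "default_schema",
    "DEFAULT_N_ITEMS",
    "N_CVD_ITEMS",
]

DEFAULT_N_ITEMS = 41
N_CVD_ITEMS = 4

VALID_KINDS = ("binary", "ordinal", "bmi_band")


class SchemaError(ValueError):
    """Raised when a codebook fails validation."""


@dataclass(frozen=True)
class DeficitSpec:
    """One health-deficit item.

    Parameters
    ----------
    item_id
        Short unique key, used as the column name in cohort tables.
    label
        Human-readable item name.
    kind
        ``binary`` (no/yes), ``ordinal`` (graded severity) or ``bmi_band``
        (a graded item that additionally accepts a numeric body-mass index
        and bins it into bands).
    level_map
        Ordered mapping from raw response code to deficit score in [0, 1].
    cvd_related
        True for cardiovascular diagnosis/risk-factor items excluded from
        the sensitivity index.
    target_prevalence
        Optional mapping level code -> population fraction in percent; used
        only by the synthetic-cohort generator.
    """

    item_id: str
    label: str
    kind: str
    level_map: Mapping[str, float]
    cvd_related: bool = False
    target_prevalence: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise SchemaError(
                f"item {self.item_id!r}: unknown kind {self.kind!r}; "
                f"expected one of {VALID_KINDS}"
            )
        scores = list(self.level_map.values())
        if len(scores) < 2:
            raise SchemaError(f"item {self.item_id!r}: needs at least 2 levels")
        for code, s in self.level_map.items():
            if not (0.0 <= float(s) <= 1.0):
                raise SchemaError(
                    f"item {self.item_id!r}: score {s} for level {code!r} "
                    "outside [0, 1]"
                )
        if self.kind == "binary":
            if sorted(scores) != [0.0, 1.0]:
                raise SchemaError(
                    f"item {self.item_id!r}: binary items must map exactly "
                    "{absent -> 0, present -> 1}"
                )
        else:
            # graded items: lowest level is deficit-free, highest is full
            if scores[0] != 0.0 or scores[-1] != 1.0:
                raise SchemaError(
                    f"item {self.item_id!r}: ordinal scores must start at 0 "
                    "and end at 1"
                )
            if any(b <= a for a, b in zip(scores, scores[1:])):
                raise SchemaError(
                    f"item {self.item_id!r}: ordinal scores must be strictly "
                    "increasing"
                )

    @property
    def n_levels(self) -> int:
        return len(self.level_map)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.level_map)


@dataclass(frozen=True)
class DeficitSchema:
    """An ordered, validated collection of :class:`DeficitSpec` items."""

    items: tuple[DeficitSpec, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate item_ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> DeficitSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def cvd_item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items if it.cvd_related)

    def without_cvd_items(self) -> "DeficitSchema":
        """Sensitivity subset: drop the flagged cardiovascular items.

        Returns the schema unchanged (same object) when no item is flagged.
        The frailty-index missingness rule downstream re-evaluates against
        the reduced item count automatically.
        """
        kept = tuple(it for it in self.items if not it.cvd_related)
        if len(kept) == len(self.items):
            return self
        return DeficitSchema(items=kept, name=f"{self.name}_no_cvd")

    def content_hash(self) -> str:
        """Stable hash of the schema content, for provenance logging."""
        payload = [
            (it.item_id, it.kind, sorted(it.level_map.items()), it.cvd_related)
            for it in self.items
        ]
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _parse_item(entry: Mapping) -> DeficitSpec:
    required = {"item_id", "kind", "levels"}
    missing = required - set(entry)
    if missing:
        raise SchemaError(f"codebook entry missing fields {sorted(missing)}: {entry}")
    levels = entry["levels"]
    level_map = {str(lv["code"]): float(lv["score"]) for lv in levels}
    if len(level_map) != len(levels):
        raise SchemaError(f"item {entry['item_id']!r}: duplicate level codes")
    prev = {
        str(lv["code"]): float(lv["prevalence"])
        for lv in levels
        if "prevalence" in lv
    }
    return DeficitSpec(
        item_id=str(entry["item_id"]),
        label=str(entry.get("label", entry["item_id"])),
        kind=str(entry["kind"]),
        level_map=level_map,
        cvd_related=bool(entry.get("cvd_related", False)),
        target_prevalence=prev or None,
    )


def load_schema(
    source: str | Path | Mapping | Sequence[Mapping],
    *,
    strict_default: bool = False,
    name: Optional[str] = None,
) -> DeficitSchema:
    """Load and validate a deficit codebook.

    Parameters
    ----------
    source
        A YAML/JSON file path, a parsed mapping with an ``items`` key, or a
        sequence of item entries.
    strict_default
        When True, require exactly 41 items with exactly 4 flagged as
        cardiovascular (the shape of the built-in default codebook).
    name
        Optional schema name; defaults to the file stem or ``"custom"``.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if name is None:
            name = path.stem
    else:
        doc = source
    if isinstance(doc, Mapping):
        entries = doc.get("items")
        if entries is None:
            raise SchemaError("codebook document has no 'items' key")
    else:
        entries = doc
    items = tuple(_parse_item(e) for e in entries)
    schema = DeficitSchema(items=items, name=name or "custom")
    if strict_default:
        if len(schema) != DEFAULT_N_ITEMS:
            raise SchemaError(
                f"strict schema requires {DEFAULT_N_ITEMS} items, got {len(schema)}"
            )
        n_cvd = len(schema.cvd_item_ids)
        if n_cvd != N_CVD_ITEMS:
            raise SchemaError(
                f"strict schema requires {N_CVD_ITEMS} cardiovascular items, "
                f"got {n_cvd}"
            )
    return schema


def default_schema() -> DeficitSchema:
    """The built-in 41-item codebook (4 items flagged cardiovascular)."""
    ref = resources.files("fraildex") / "_data" / "codebook_default.yaml"
    with resources.as_file(ref) as path:
        return load_schema(path, strict_default=True, name="default_41")
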