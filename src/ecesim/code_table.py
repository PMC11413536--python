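"""The genetic code: a total map from the 64 triplet codons to developmental roles.

Genomes are strands of quaternary digits (0-3) read in a fixed,
non-overlapping triplet frame.  Each codon is either a START or STOP
punctuation mark, codes for one of five kinds of body part (segment,
joint, touch sensor, neuron, wire), or acts as a regulatory element: a
FEATURE codon sets a categorical attribute of the part expressed by its
gene, and a MAGNITUDE codon increments a numeric attribute.

The default table honours the published pinned assignments (segments
redundantly coded by 000 and 001; sensor 100; joint 200; the feature
codons 300, 110, 120, 130, 101, 102, 103) and allots the majority of the
codon space (44 of 64 codons) to FEATURE roles.  Assignments the source
model leaves open -- neuron and wire part codons, the START/STOP pair,
and the magnitude block -- are explicit, editable defaults: the table is
shipped as a JSON data asset so alternative codes can be swapped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

N_CODONS = 64

__all__ = [
    "Category",
    "PartKind",
    "CodonRole",
    "CodeTable",
    "codon_index",
    "codon_str",
    "default_code_table",
]


class Category(str, Enum):
    START = "START"
    STOP = "STOP"
    PART = "PART"
    FEATURE = "FEATURE"
    MAGNITUDE = "MAGNITUDE"


class PartKind(str, Enum):
    SEGMENT = "SEGMENT"
    JOINT = "JOINT"
    SENSOR = "SENSOR"
    NEURON = "NEURON"
    WIRE = "WIRE"


def codon_index(a: int, b: int, c: int) -> int:
    """Flat index in [0, 64) of the codon with bases ``(a, b, c)``."""
    return 16 * a + 4 * b + c


def codon_str(index: int) -> str:
    """Three-digit string form of a codon index, e.g. 18 -> ``"102"``."""
    return f"{index // 16}{(index // 4) % 4}{index % 4}"


@dataclass(frozen=True)
class CodonRole:
    """Role of a single codon.

    ``part_kind`` is set iff the category is PART; ``feature_kind`` iff
    FEATURE; ``magnitude_attr``/``magnitude_level`` iff MAGNITUDE.
    """

    category: Category
    part_kind: PartKind | None = None
    feature_kind: str | None = None
    magnitude_attr: str | None = None
    magnitude_level: int | None = None

    def __post_init__(self) -> None:
        if (self.part_kind is not None) != (self.category is Category.PART):
            raise ValueError("part_kind must be set iff category is PART")
        if (self.feature_kind is not None) != (self.category is Category.FEATURE):
            raise ValueError("feature_kind must be set iff category is FEATURE")
        has_mag = self.magnitude_attr is not None or self.magnitude_level is not None
        if has_mag != (self.category is Category.MAGNITUDE):
            raise ValueError("magnitude fields must be set iff category is MAGNITUDE")


# Assignments required of every valid table: (codon digits) -> checker.
_PINNED: dict[tuple[int, int, int], tuple[Category, str]] = {
    (0, 0, 0): (Category.PART, PartKind.SEGMENT.value),
    (0, 0, 1): (Category.PART, PartKind.SEGMENT.value),
    (1, 0, 0): (Category.PART, PartKind.SENSOR.value),
    (2, 0, 0): (Category.PART, PartKind.JOINT.value),
    (3, 0, 0): (Category.FEATURE, "joint"),
    (1, 1, 0): (Category.FEATURE, "sphere-sensor-x"),
    (1, 2, 0): (Category.FEATURE, "sphere-sensor-z"),
    (1, 3, 0): (Category.FEATURE, "wire-connections"),
    (1, 0, 1): (Category.FEATURE, "sensor-output-1"),
    (1, 0, 2): (Category.FEATURE, "sensor-output-2"),
    (1, 0, 3): (Category.FEATURE, "sensor-output-3"),
}


class CodeTable:
    """Total, validated map ``Codon -> CodonRole`` over all 64 codons.

    Internally keeps parallel numpy arrays so whole genomes can be
    classified in one vectorised lookup.
    """

    def __init__(self, roles: Iterable[CodonRole]):
        self.roles: tuple[CodonRole, ...] = tuple(roles)
        if len(self.roles) != N_CODONS:
            raise ValueError(f"code table must have exactly {N_CODONS} entries, "
                             f"got {len(self.roles)}")
        cats = list(Category)
        self._cat_codes = np.array(
            [cats.index(r.category) for r in self.roles], dtype=np.int8
        )
        kinds = list(PartKind)
        self._part_codes = np.array(
            [kinds.index(r.part_kind) if r.part_kind is not None else -1
             for r in self.roles],
            dtype=np.int8,
        )
        self.validate()

    # -- vectorised views ------------------------------------------------
    def categories_of(self, codon_indices: np.ndarray) -> np.ndarray:
        """int8 category codes (order of ``Category``) for an index array."""
        return self._cat_codes[codon_indices]

    @property
    def start_code(self) -> int:
        return list(Category).index(Category.START)

    @property
    def stop_code(self) -> int:
        return list(Category).index(Category.STOP)

    def role(self, codon: int | tuple[int, int, int]) -> CodonRole:
        if isinstance(codon, tuple):
            codon = codon_index(*codon)
        return self.roles[codon]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` unless every structural requirement holds."""
        n_start = sum(r.category is Category.START for r in self.roles)
        n_stop = sum(r.category is Category.STOP for r in self.roles)
        if n_start < 1 or n_stop < 1:
            raise ValueError("code table needs at least one START and one STOP codon")
        for digits, (cat, label) in _PINNED.items():
            role = self.roles[codon_index(*digits)]
            if role.category is not cat:
                raise ValueError(f"codon {digits} must be {cat.value}")
            if cat is Category.PART and role.part_kind.value != label:
                raise ValueError(f"codon {digits} must code a {label}")
            if cat is Category.FEATURE and role.feature_kind != label:
                raise ValueError(f"codon {digits} must be the {label!r} feature")
        n_feature = sum(r.category is Category.FEATURE for r in self.roles)
        if n_feature <= 32:
            raise ValueError("feature codons must occupy the majority (>32) of "
                             f"the codon space; table has {n_feature}")

    # -- serialisation ---------------------------------------------------
    def to_json(self) -> str:
        entries = []
        for i, r in enumerate(self.roles):
            e: dict = {"codon": codon_str(i), "category": r.category.value}
            if r.part_kind is not None:
                e["kind"] = r.part_kind.value
            if r.feature_kind is not None:
                e["kind"] = r.feature_kind
            if r.magnitude_attr is not None:
                e["attr"] = r.magnitude_attr
                e["level"] = r.magnitude_level
            entries.append(e)
        return json.dumps(entries, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CodeTable":
        entries = json.loads(text)
        roles: list[CodonRole | None] = [None] * N_CODONS
        for e in entries:
            digits = tuple(int(d) for d in e["codon"])
            if len(digits) != 3 or any(d not in (0, 1, 2, 3) for d in digits):
                raise ValueError(f"bad codon {e['codon']!r}")
            i = codon_index(*digits)
            if roles[i] is not None:
                raise ValueError(f"duplicate codon {e['codon']!r}")
            cat = Category(e["category"])
            if cat is Category.PART:
                roles[i] = CodonRole(cat, part_kind=PartKind(e["kind"]))
            elif cat is Category.FEATURE:
                roles[i] = CodonRole(cat, feature_kind=e["kind"])
            elif cat is Category.MAGNITUDE:
                roles[i] = CodonRole(cat, magnitude_attr=e["attr"],
                                     magnitude_level=int(e["level"]))
            else:
                roles[i] = CodonRole(cat)
        if any(r is None for r in roles):
            missing = [codon_str(i) for i, r in enumerate(roles) if r is None]
            raise ValueError(f"table is not total; missing codons {missing[:5]}...")
        return cls(roles)  # type: ignore[arg-type]

    @classmethod
    def from_file(cls, path: str | Path) -> "CodeTable":
        return cls.from_json(Path(path).read_text())

    @classmethod
    def default(cls) -> "CodeTable":
        return _load_default()


def _build_default_roles() -> list[CodonRole]:
    """Construct the default code in memory (source of the packaged asset)."""
    roles: list[CodonRole | None] = [None] * N_CODONS

    def put(a: int, b: int, c: int, role: CodonRole) -> None:
        roles[codon_index(a, b, c)] = role

    # part codons (segment redundantly coded)
    put(0, 0, 0, CodonRole(Category.PART, part_kind=PartKind.SEGMENT))
    put(0, 0, 1, CodonRole(Category.PART, part_kind=PartKind.SEGMENT))
    put(1, 0, 0, CodonRole(Category.PART, part_kind=PartKind.SENSOR))
    put(2, 0, 0, CodonRole(Category.PART, part_kind=PartKind.JOINT))
    put(0, 1, 0, CodonRole(Category.PART, part_kind=PartKind.NEURON))
    put(0, 2, 0, CodonRole(Category.PART, part_kind=PartKind.WIRE))
    # punctuation
    put(3, 3, 3, CodonRole(Category.START))
    put(3, 3, 2, CodonRole(Category.STOP))
    # pinned feature codons
    put(3, 0, 0, CodonRole(Category.FEATURE, feature_kind="joint"))
    put(1, 1, 0, CodonRole(Category.FEATURE, feature_kind="sphere-sensor-x"))
    put(1, 2, 0, CodonRole(Category.FEATURE, feature_kind="sphere-sensor-z"))
    put(1, 3, 0, CodonRole(Category.FEATURE, feature_kind="wire-connections"))
    for c in (1, 2, 3):
        put(1, 0, c, CodonRole(Category.FEATURE, feature_kind=f"sensor-output-{c}"))
    # magnitude block: three attribute rows x four levels
    for c in range(4):
        put(0, 3, c, CodonRole(Category.MAGNITUDE, magnitude_attr="size",
                               magnitude_level=c + 1))
        put(2, 3, c, CodonRole(Category.MAGNITUDE, magnitude_attr="mounts",
                               magnitude_level=c + 1))
        put(3, 2, c, CodonRole(Category.MAGNITUDE, magnitude_attr="connectors",
                               magnitude_level=c + 1))
    # every remaining codon is a feature with no modelled structural effect
    for i in range(N_CODONS):
        if roles[i] is None:
            roles[i] = CodonRole(Category.FEATURE, feature_kind="generic")
    return roles  # type: ignore[return-value]


def default_code_table() -> CodeTable:
    """The packaged default genetic code."""
    return _load_default()


@lru_cache(maxsize=1)
def _load_default() -> CodeTable:
    try:
        text = (resources.files("ecesim") / "data" / "default_code_table.json").read_text()
        return CodeTable.from_json(text)
    except FileNotFoundError:  # pragma: no cover - asset always packaged
        return CodeTable(_build_default_roles())
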