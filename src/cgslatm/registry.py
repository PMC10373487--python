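"""Bead-type registry and interaction-channel indexing.

A coarse-grained (CG) force field defines a finite alphabet of bead types
(e.g. Martini's ``P4`` or the reduced solute alphabet ``T1..T5, Q0``).  SLATM
treats the bead type the way atomistic representations treat the chemical
element: each type ``I`` carries a unique, otherwise arbitrary identity
number ``Z_I``.  The registry freezes the alphabet, the ``Z`` assignment and
-- crucially -- the ordering, which fixes the channel layout of every
downstream feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "BeadType",
    "BeadTypeRegistry",
    "ChannelIndex",
    "build_registry",
    "build_channel_index",
    "default_cg_registry",
    "channel_key_to_str",
    "channel_key_from_str",
]

CATEGORIES = ("solute", "lipid", "solvent")
PHYS_CLASSES = ("polar", "charged", "hbond", "apolar")

# delimiters used by the string form of channel keys; type names must avoid them
_PAIR_SEP = "~"
_CENTER_SEP = "|"


@dataclass(frozen=True)
class BeadType:
    """One registered bead type: name, identity number Z, and category."""

    name: str
    Z: int
    category: str
    phys_class: str | None = None

    def __post_init__(self) -> None:
        if not self.name or _PAIR_SEP in self.name or _CENTER_SEP in self.name:
            raise ValueError(f"invalid bead type name {self.name!r}")
        if int(self.Z) <= 0:
            raise ValueError(f"Z must be a positive integer, got {self.Z!r}")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not one of {CATEGORIES}"
            )
        if self.phys_class is not None and self.phys_class not in PHYS_CLASSES:
            raise ValueError(
                f"phys_class {self.phys_class!r} not one of {PHYS_CLASSES}"
            )


class BeadTypeRegistry:
    """Frozen, ordered alphabet of bead types.

    The construction order is the canonical channel order everywhere
    downstream; two registries with the same types in different orders are
    different registries.
    """

    def __init__(self, entries: Iterable[BeadType]):
        entries = tuple(entries)
        if not entries:
            raise ValueError("registry needs at least one bead type")
        names = [e.name for e in entries]
        zs = [int(e.Z) for e in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate bead type names: {dupes}")
        if len(set(zs)) != len(zs):
            dupes = sorted({z for z in zs if zs.count(z) > 1})
            raise ValueError(f"duplicate Z values: {dupes}")
        self._entries = entries
        self._index = {e.name: i for i, e in enumerate(entries)}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> BeadType:
        return self._entries[self._index[name]]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BeadTypeRegistry)
            and self._entries == other._entries
        )

    def __repr__(self) -> str:
        return f"BeadTypeRegistry({[e.name for e in self._entries]})"

    # -- lookups -------------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self._entries)

    def z_of(self, name: str) -> int:
        return self._entries[self._index[name]].Z

    def category_of(self, name: str) -> str:
        return self._entries[self._index[name]].category

    def index_of(self, name: str) -> int:
        if name not in self._index:
            raise KeyError(f"bead type {name!r} not in registry")
        return self._index[name]

    def sort_pair(self, a: str, b: str) -> tuple[str, str]:
        """Canonical (registry-ordered) form of an unordered type pair."""
        return (a, b) if self.index_of(a) <= self.index_of(b) else (b, a)

    # -- serialisation -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "type_name": [e.name for e in self._entries],
                "Z": [e.Z for e in self._entries],
                "category": [e.category for e in self._entries],
                "phys_class": [e.phys_class for e in self._entries],
            }
        )

    def to_toml(self, path) -> None:
        lines = []
        for e in self._entries:
            lines.append("[[bead_type]]")
            lines.append(f'name = "{e.name}"')
            lines.append(f"Z = {e.Z}")
            lines.append(f'category = "{e.category}"')
            if e.phys_class is not None:
                lines.append(f'phys_class = "{e.phys_class}"')
            lines.append("")
        with open(path, "w") as fh:
            fh.write("\n".join(lines))

    @classmethod
    def from_toml(cls, path) -> "BeadTypeRegistry":
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        rows = doc.get("bead_type", [])
        return build_registry(rows)


def build_registry(
    table: pd.DataFrame | Sequence[Mapping] | Sequence[tuple],
) -> BeadTypeRegistry:
    """Build a frozen registry from a bead-type table.

    ``table`` may be a DataFrame or a sequence of mappings with columns
    ``type_name`` (or ``name``), optional ``Z``, ``category`` and optional
    ``phys_class``.  When ``Z`` is absent it is assigned ``1..N`` in table
    order; explicit Z values must be unique.
    """
    if isinstance(table, pd.DataFrame):
        rows = table.to_dict("records")
    else:
        rows = [dict(r) for r in table]
    if not rows:
        raise ValueError("bead-type table is empty")
    entries = []
    for i, row in enumerate(rows):
        name = row.get("type_name", row.get("name"))
        if name is None:
            raise ValueError(f"row {i} has no type name")
        z = row.get("Z")
        if z is None or (isinstance(z, float) and pd.isna(z)):
            z = i + 1
        category = row.get("category", "solute") or "solute"
        phys = row.get("phys_class")
        if isinstance(phys, float) and pd.isna(phys):
            phys = None
        entries.append(BeadType(str(name), int(z), str(category), phys))
    return BeadTypeRegistry(entries)


def default_cg_registry() -> BeadTypeRegistry:
    """The 14-type alphabet monitored in CL/PG membrane screening.

    Six solute types from the reduced 5+1 force field (five neutral beads
    ``T1..T5`` plus the charged ``Q0``), six Martini lipid types and the
    polarizable water/ion types.  Z is assigned 1..14 in this order.
    """
    rows = [
        ("T1", "solute", "polar"),
        ("T2", "solute", "polar"),
        ("T3", "solute", "hbond"),
        ("T4", "solute", "apolar"),
        ("T5", "solute", "apolar"),
        ("Q0", "solute", "charged"),
        ("Nda", "lipid", None),
        ("P4", "lipid", None),
        ("Qa", "lipid", None),
        ("Na", "lipid", None),
        ("C1", "lipid", None),
        ("C3", "lipid", None),
        ("POL", "solvent", None),
        ("PQd", "solvent", None),
    ]
    return build_registry(
        [
            {"type_name": n, "category": c, "phys_class": p}
            for n, c, p in rows
        ]
    )


# ---------------------------------------------------------------------------
# Channel index
# ---------------------------------------------------------------------------

PairKey = tuple[str, str]
TripletKey = tuple[str, tuple[str, str]]


@dataclass(frozen=True)
class ChannelIndex:
    """Canonical ordering of one-, two- and three-body channels.

    One-body channels are the N registered types; two-body channels the
    N(N+1)/2 unordered type pairs (with repetition); three-body channels the
    (center type, unordered neighbour pair) combinations, N * N(N+1)/2 of
    them when fully enumerated.  Order is lexicographic over the registry
    order and deterministic.
    """

    one_body: tuple[str, ...]
    two_body: tuple[PairKey, ...]
    three_body: tuple[TripletKey, ...]
    triplet_policy: str = "all"

    @property
    def n_one(self) -> int:
        return len(self.one_body)

    @property
    def n_two(self) -> int:
        return len(self.two_body)

    @property
    def n_three(self) -> int:
        return len(self.three_body)

    @property
    def n_channels(self) -> int:
        return self.n_one + self.n_two + self.n_three

    def keys(self) -> list:
        """All channel keys in canonical flattened order."""
        return list(self.one_body) + list(self.two_body) + list(self.three_body)

    def position(self, key) -> int:
        return self._positions()[key]

    def _positions(self) -> dict:
        # frozen dataclass: cache on the instance via object.__setattr__
        cache = self.__dict__.get("_pos_cache")
        if cache is None:
            cache = {k: i for i, k in enumerate(self.keys())}
            object.__setattr__(self, "_pos_cache", cache)
        return cache

    def __contains__(self, key) -> bool:
        return key in self._positions()


def build_channel_index(
    registry: BeadTypeRegistry, triplet_policy: str = "observed-only"
) -> ChannelIndex:
    """Enumerate the channel index for a registry.

    ``triplet_policy`` is ``"all"`` or ``"observed-only"``.  Both enumerate
    the full N * N(N+1)/2 triplet set here; under ``"observed-only"`` the
    dataset assembler later drops channels never observed across the dataset
    (see :func:`cgslatm.reduction.assemble_difference_matrix`).
    """
    if triplet_policy not in ("all", "observed-only"):
        raise ValueError(f"unknown triplet_policy {triplet_policy!r}")
    names = registry.names
    pairs = tuple(combinations_with_replacement(names, 2))
    triplets = tuple((c, jk) for c in names for jk in pairs)
    return ChannelIndex(
        one_body=tuple(names),
        two_body=pairs,
        three_body=triplets,
        triplet_policy=triplet_policy,
    )


def channel_key_to_str(key) -> str:
    """String form of a channel key: ``T1``, ``T1~Q0`` or ``Nda|T1~Q0``."""
    if isinstance(key, str):
        return key
    if len(key) == 2 and isinstance(key[1], tuple):
        center, (a, b) = key
        return f"{center}{_CENTER_SEP}{a}{_PAIR_SEP}{b}"
    a, b = key
    return f"{a}{_PAIR_SEP}{b}"


def channel_key_from_str(s: str):
    if _CENTER_SEP in s:
        center, pair = s.split(_CENTER_SEP)
        a, b = pair.split(_PAIR_SEP)
        return (center, (a, b))
    if _PAIR_SEP in s:
        a, b = s.split(_PAIR_SEP)
        return (a, b)
    return s
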