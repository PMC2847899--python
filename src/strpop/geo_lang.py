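"""Linguistic distances from a dated language tree; great-circle geography.

The linguistic distance between two populations is the age (years
before present) of the most recent common ancestor of their language
groups on a rooted, dated tree.  Ages decrease from root to tip, so the
resulting matrix is ultrametric by construction.  The shipped default
tree fixes only three ages — Chinese/Tibeto-Burman at 7,000 yrs BP,
Mongolian/Turkic at 8,000 yrs BP, and a 50,000 yrs BP root joining
everything else — with all finer structure collapsed; trees with more
resolution can be supplied as config.

Geographic distances are great-circle arc lengths (haversine) on a
sphere of radius 6,371 km, deliberately untransformed: a logarithm
would distort non-linearly and maps same-location pairs to minus
infinity, whereas the plain arc length keeps them at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dataset import PopulationMeta
from .distance import DistanceMatrix

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "LanguageTree",
    "linguistic_distance_matrix",
    "geographic_distance_matrix",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    """A sampling location in decimal degrees (latitude north, longitude east)."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass
class _LangNode:
    name: str
    age: float
    children: list["_LangNode"] = field(default_factory=list)


class LanguageTree:
    """Rooted language tree with dated internal nodes.

    Built from a nested config: each node is a mapping with ``name``,
    optional ``age`` (years BP; required on internal nodes) and optional
    ``children``.  An ``age`` on a leaf sets the within-group distance
    for populations sharing that leaf (default 0).  ``mapping`` sends
    every population to exactly one leaf label.
    """

    def __init__(self, config: Mapping, mapping: Mapping[str, str]):
        self.root = self._parse(config, parent_age=math.inf)
        self.mapping = dict(mapping)
        self._leaf_ages: dict[str, float] = {}
        self._ancestry: dict[str, list[_LangNode]] = {}

        def walk(node: _LangNode, path: list[_LangNode]) -> None:
            path = path + [node]
            if not node.children:
                if node.name in self._ancestry:
                    raise ValueError(f"duplicate leaf label {node.name!r}")
                self._ancestry[node.name] = path
                self._leaf_ages[node.name] = node.age
            for c in node.children:
                walk(c, path)

        walk(self.root, [])
        unknown = {leaf for leaf in self.mapping.values() if leaf not in self._ancestry}
        if unknown:
            raise ValueError(f"populations mapped to unknown leaves: {sorted(unknown)}")

    @classmethod
    def _parse(cls, cfg: Mapping, parent_age: float) -> _LangNode:
        children_cfg = cfg.get("children", [])
        age = float(cfg.get("age", 0.0))
        if children_cfg and "age" not in cfg:
            raise ValueError(f"internal node {cfg.get('name')!r} must carry an age")
        if age >= parent_age:
            raise ValueError(
                f"node {cfg.get('name')!r} age {age} is not younger than its parent"
            )
        node = _LangNode(name=str(cfg["name"]), age=age)
        node.children = [cls._parse(c, age if children_cfg else parent_age) for c in children_cfg]
        return node

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LanguageTree":
        """Load ``{tree: <nested nodes>, populations: {name: leaf}}`` YAML."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(cfg["tree"], cfg["populations"])

    def to_yaml(self, path: str | Path) -> None:
        def dump(node: _LangNode) -> dict:
            out: dict = {"name": node.name}
            if node.children:
                out["age"] = node.age
                out["children"] = [dump(c) for c in node.children]
            elif node.age:
                out["age"] = node.age
            return out

        with open(path, "w") as fh:
            yaml.safe_dump({"tree": dump(self.root), "populations": self.mapping}, fh,
                           sort_keys=False)

    def leaf_of(self, population: str) -> str:
        try:
            return self.mapping[population]
        except KeyError:
            raise KeyError(f"population {population!r} is not mapped to a language group") from None

    def mrca_age(self, pop_x: str, pop_y: str) -> float:
        """Age (yrs BP) of the most recent common ancestor of two populations' leaves."""
        lx, ly = self.leaf_of(pop_x), self.leaf_of(pop_y)
        if lx == ly:
            return self._leaf_ages[lx]
        px, py = self._ancestry[lx], self._ancestry[ly]
        mrca = self.root
        for nx, ny in zip(px, py):
            if nx is not ny:
                break
            mrca = nx
        return mrca.age


def linguistic_distance_matrix(
    tree: LanguageTree, populations: Sequence[str]
) -> DistanceMatrix:
    """Pairwise MRCA-age distances (years) for the given populations."""
    for p in populations:
        tree.leaf_of(p)  # raises on unmapped
    n = len(populations)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.mrca_age(populations[i], populations[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(populations), values, kind="linguistic")


def _haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geographic_distance_matrix(
    coords: Mapping[str, GeoPoint] | Sequence[PopulationMeta],
) -> DistanceMatrix:
    """Great-circle distance matrix (km) from population coordinates.

    Accepts either a population -> :class:`GeoPoint` mapping or a list
    of :class:`PopulationMeta`.  Same-location pairs get distance 0.
    """
    if isinstance(coords, Mapping):
        items = [(name, pt.latitude, pt.longitude) for name, pt in coords.items()]
    else:
        items = [(m.name, m.latitude, m.longitude) for m in coords]
    labels = [name for name, _, _ in items]
    n = len(items)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _haversine_km(items[i][1], items[i][2], items[j][1], items[j][2])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values, kind="geographic")
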