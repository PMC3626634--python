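"""The 19-channel 10-20 scalp montage as a geometric grid.

Electrodes are laid out on a signed integer grid (columns negative on the
left, row 0 through the central line).  All inter-electrode distances used
downstream — the neighbor exclusion, the short/long range split, and the
homologous (mirror-image) pairing — are derived from plain Euclidean
distance on this grid:

* ``d < 2``       — neighbor (dropped from range ratios: volume conduction)
* ``2 <= d < 3``  — short range
* ``d >= 3``      — long range (3 is 75% of the maximum aligned distance, 4)

The modern temporal labels T7/T8/P7/P8 are accepted as aliases of the
classic T3/T4/T5/T6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

import pandas as pd

__all__ = [
    "Electrode",
    "PairClass",
    "ElectrodeMontage",
    "build_standard_montage",
    "classify_pair",
    "CHANNEL_ALIASES",
]

#: classic-label aliases used by newer amplifier conventions
CHANNEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

# (name, grid_x, grid_y); x < 0 left hemisphere, x = 0 midline
_GRID = [
    ("Fp1", -1, 2), ("Fp2", 1, 2),
    ("F7", -2, 1), ("F3", -1, 1), ("Fz", 0, 1), ("F4", 1, 1), ("F8", 2, 1),
    ("T3", -2, 0), ("C3", -1, 0), ("Cz", 0, 0), ("C4", 1, 0), ("T4", 2, 0),
    ("T5", -2, -1), ("P3", -1, -1), ("Pz", 0, -1), ("P4", 1, -1), ("T6", 2, -1),
    ("O1", -1, -2), ("O2", 1, -2),
]


@dataclass(frozen=True)
class Electrode:
    name: str
    grid_x: int
    grid_y: int

    @property
    def hemisphere(self) -> str:
        if self.grid_x < 0:
            return "left"
        if self.grid_x > 0:
            return "right"
        return "midline"


@dataclass(frozen=True)
class PairClass:
    """Classification of one unordered electrode pair."""

    a: str
    b: str
    distance: float
    dist_class: str  # neighbor | short | long
    homologous_interhemispheric: bool
    intra_nonmidline: bool


class ElectrodeMontage:
    """The fixed 19-electrode montage with pre-computed pair classes."""

    def __init__(self, electrodes: list[Electrode]):
        names = [e.name for e in electrodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate electrode names")
        coords = {(e.grid_x, e.grid_y) for e in electrodes}
        if len(coords) != len(electrodes):
            raise ValueError("duplicate grid coordinates")
        self.electrodes = list(electrodes)
        self._by_name = {e.name: e for e in electrodes}
        self._pair_classes: dict[frozenset[str], PairClass] = {}
        for ea, eb in combinations(electrodes, 2):
            pc = _classify(ea, eb)
            self._pair_classes[frozenset((ea.name, eb.name))] = pc

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.electrodes]

    def __len__(self) -> int:
        return len(self.electrodes)

    def resolve(self, name: str) -> str:
        """Resolve a channel label (case-insensitive, aliases allowed)."""
        cand = name.strip()
        for known in self._by_name:
            if cand.upper() == known.upper():
                return known
        alias = CHANNEL_ALIASES.get(cand.upper())
        if alias is not None:
            return alias
        raise KeyError(f"unknown electrode name: {name!r}")

    def electrode(self, name: str) -> Electrode:
        return self._by_name[self.resolve(name)]

    def index(self, name: str) -> int:
        return self.names.index(self.resolve(name))

    def pair_class(self, a: str, b: str) -> PairClass:
        ra, rb = self.resolve(a), self.resolve(b)
        if ra == rb:
            raise ValueError(f"pair requires two distinct electrodes, got {a!r}, {b!r}")
        return self._pair_classes[frozenset((ra, rb))]

    def pairs(self) -> Iterator[PairClass]:
        """All 171 unordered pair classifications, in montage order."""
        names = self.names
        for a, b in combinations(names, 2):
            yield self._pair_classes[frozenset((a, b))]

    def pair_indices(self, *, dist_class: str | None = None,
                     homologous: bool | None = None,
                     intra_nonmidline: bool | None = None) -> list[tuple[int, int]]:
        """Index pairs (i < j) filtered by class/flags."""
        out = []
        idx = {n: i for i, n in enumerate(self.names)}
        for pc in self.pairs():
            if dist_class is not None and pc.dist_class != dist_class:
                continue
            if homologous is not None and pc.homologous_interhemispheric != homologous:
                continue
            if intra_nonmidline is not None and pc.intra_nonmidline != intra_nonmidline:
                continue
            i, j = sorted((idx[pc.a], idx[pc.b]))
            out.append((i, j))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Plain-text audit table of the layout."""
        return pd.DataFrame(
            [(e.name, e.grid_x, e.grid_y, e.hemisphere) for e in self.electrodes],
            columns=["name", "grid_x", "grid_y", "hemisphere"],
        )


def _classify(ea: Electrode, eb: Electrode) -> PairClass:
    d = math.hypot(ea.grid_x - eb.grid_x, ea.grid_y - eb.grid_y)
    if d < 2:
        dist_class = "neighbor"
    elif d < 3:
        dist_class = "short"
    else:
        dist_class = "long"
    homologous = (
        ea.grid_x == -eb.grid_x and ea.grid_x != 0 and ea.grid_y == eb.grid_y
    )
    intra = (
        ea.hemisphere == eb.hemisphere and ea.hemisphere in ("left", "right")
    )
    return PairClass(ea.name, eb.name, d, dist_class, homologous, intra)


def build_standard_montage() -> ElectrodeMontage:
    """The standard clinical 19-electrode 10-20 montage (deterministic)."""
    return ElectrodeMontage([Electrode(n, x, y) for n, x, y in _GRID])


def classify_pair(montage: ElectrodeMontage, a: str, b: str) -> PairClass:
    """Classify the unordered pair (a, b); raises KeyError on unknown labels."""
    return montage.pair_class(a, b)
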