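"""Leaflet composition bookkeeping and initial lipid placement.

Lipid species are represented by their headgroup bead only: a name, a net
headgroup charge in valence units, a lateral diffusion coefficient and a
bead radius. The default registry covers the species used in simple
asymmetric inner leaflets (PC, PS, PIP2) plus the species that appear in
complex-membrane compositions (PE, GM3, CHOL), which participate here only
in composition bookkeeping.

Charge convention: PIP2 carries -4 (bis-phosphorylated inositol headgroup
at physiological pH, coarse-grained net charge), PS -1, GM3 -1, and PC, PE
and cholesterol are neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np

from .errors import CompositionError, PackingError, UnknownSpeciesError

#: Default bead radius, Angstrom. Contact distance between two beads is
#: 2 * radius = 4.7 A, comparable to a coarse-grained headgroup bead, so the
#: first interaction shell sits naturally near 5 A.
DEFAULT_BEAD_RADIUS = 2.35

#: Default lateral diffusion coefficient, A^2/ns. Coarse-grained lipid
#: dynamics are several-fold faster than atomistic; a uniform value is used
#: for all species.
DEFAULT_DIFFUSION = 10.0


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid headgroup bead type."""

    name: str
    charge: int
    diffusion_coefficient: float = DEFAULT_DIFFUSION
    bead_radius: float = DEFAULT_BEAD_RADIUS


#: Registry of known species. Only the headgroup charge differs between
#: entries; diffusion and size are uniform by default.
SPECIES_REGISTRY: Dict[str, LipidSpecies] = {
    "PC": LipidSpecies("PC", 0),
    "PE": LipidSpecies("PE", 0),
    "PS": LipidSpecies("PS", -1),
    "PIP2": LipidSpecies("PIP2", -4),
    "GM3": LipidSpecies("GM3", -1),
    "CHOL": LipidSpecies("CHOL", 0),
}


def get_species(name: str) -> LipidSpecies:
    try:
        return SPECIES_REGISTRY[name]
    except KeyError:
        raise UnknownSpeciesError(
            f"unknown lipid species {name!r}; known: {sorted(SPECIES_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class LeafletComposition:
    """Named lipid species with mole fractions summing to 1."""

    fractions: Mapping[str, float]
    tolerance: float = field(default=1e-9, compare=False)

    def __post_init__(self) -> None:
        if not self.fractions:
            raise CompositionError("empty composition")
        for name, frac in self.fractions.items():
            get_species(name)
            if frac < 0:
                raise CompositionError(f"negative fraction for {name}: {frac}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > self.tolerance:
            raise CompositionError(f"fractions sum to {total}, expected 1")

    def species_names(self) -> list[str]:
        return list(self.fractions)

    def fraction(self, name: str) -> float:
        if name not in self.fractions:
            raise UnknownSpeciesError(f"species {name!r} not in composition")
        return float(self.fractions[name])


#: The simple asymmetric inner-leaflet composition used throughout:
#: PC:PS:PIP2 = 80:10:10 mole percent.
INNER_LEAFLET_SIMPLE = LeafletComposition({"PC": 0.8, "PS": 0.1, "PIP2": 0.1})

#: Complex inner leaflet, PC:PE:PS:PIP2:CHOL = 10:40:15:10:25.
INNER_LEAFLET_COMPLEX = LeafletComposition(
    {"PC": 0.10, "PE": 0.40, "PS": 0.15, "PIP2": 0.10, "CHOL": 0.25}
)

#: Complex outer leaflet, PC:PE:GM3:CHOL = 50:15:10:25. Bookkeeping only:
#: outer-leaflet dynamics are out of scope.
OUTER_LEAFLET_COMPLEX = LeafletComposition(
    {"PC": 0.50, "PE": 0.15, "GM3": 0.10, "CHOL": 0.25}
)


def apportion_counts(composition: LeafletComposition, n_lipids: int) -> Dict[str, int]:
    """Integer species counts by largest-remainder apportionment.

    Each species receives floor(n * fraction); the leftover seats go to the
    species with the largest fractional remainders, ties broken by
    lexicographic species name so the result is deterministic.
    """
    if n_lipids < 0:
        raise ValueError("n_lipids must be non-negative")
    names = sorted(composition.fractions)
    quotas = {name: n_lipids * composition.fractions[name] for name in names}
    counts = {name: int(math.floor(quotas[name])) for name in names}
    leftover = n_lipids - sum(counts.values())
    # Sort by descending remainder, then ascending name.
    order = sorted(names, key=lambda nm: (-(quotas[nm] - counts[nm]), nm))
    for name in order[:leftover]:
        counts[name] += 1
    return counts


def build_leaflet(
    composition: LeafletComposition,
    n_lipids: int,
    box_edge: float,
    seed: int,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
    exclude_xy: np.ndarray | None = None,
    max_attempts_per_bead: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign species and draw non-overlapping initial positions.

    Positions are drawn uniformly in the periodic square box by rejection
    sampling: a candidate is rejected if it lies within 2 * bead_radius
    (minimum image) of any accepted bead or of any position in
    ``exclude_xy`` (typically the protein anchors).

    Returns
    -------
    species : (n,) array of str
        Species label per bead, grouped by sorted species name.
    positions : (n, 2) float array
        Initial coordinates in [0, box_edge).

    Raises
    ------
    PackingError
        If a bead cannot be placed within ``max_attempts_per_bead`` draws,
        indicating the box is too crowded.
    """
    counts = apportion_counts(composition, n_lipids)
    labels = [name for name in sorted(counts) for _ in range(counts[name])]
    rng = np.random.default_rng(seed)
    min_d2 = (2.0 * bead_radius) ** 2
    placed = np.empty((n_lipids, 2))
    obstacles = exclude_xy if exclude_xy is not None else np.empty((0, 2))
    n_placed = 0
    for i in range(n_lipids):
        for _ in range(max_attempts_per_bead):
            cand = rng.uniform(0.0, box_edge, size=2)
            others = np.vstack([placed[:n_placed], obstacles])
            if others.size:
                delta = others - cand
                delta -= box_edge * np.round(delta / box_edge)
                if np.min(np.einsum("ij,ij->i", delta, delta)) < min_d2:
                    continue
            placed[i] = cand
            n_placed += 1
            break
        else:
            raise PackingError(
                f"could not place bead {i + 1}/{n_lipids} in box of edge "
                f"{box_edge} A without overlap; enlarge the box or reduce n_lipids"
            )
    return np.array(labels, dtype="U8"), placed
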