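"""Shrake–Rupley solvent-accessible surface area and burial statistics.

SASA is estimated by placing test points quasi-uniformly on each atom's
solvent-inflated sphere (van der Waals radius + probe radius, probe
1.4 Å ≈ water) and counting the points not buried inside any neighbouring
atom's inflated sphere.  Points come from a deterministic golden-spiral
lattice, so results are bit-reproducible — no RNG involved.

Burial statistics for receptor–ligand complexes:

* ``ΔSASA = (SASA_receptor + SASA_ligand) − SASA_complex`` — the
  solvent-exposed area lost on binding, i.e. the degree of ligand burial.
* ``Differential SASA = ΔSASA_inactive − ΔSASA_active`` — positive values
  mean the ligand is buried more deeply in the inactive receptor
  conformation, consistent with antagonist-like stabilization.

Van der Waals radii are the Bondi set; hydrogens are used if present in
the input and never added.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Structure",
    "SasaRecord",
    "DifferentialSasa",
    "BONDI_RADII",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_N_POINTS",
    "golden_spiral_points",
    "shrake_rupley",
    "delta_sasa",
    "differential_sasa",
    "read_pdb",
]

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 1.4   # Å, water-sized probe
DEFAULT_N_POINTS = 240       # surface test points per atom

#: Bondi van der Waals radii (Å).
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_FALLBACK_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    el = element.strip().upper()
    if el not in BONDI_RADII:
        warnings.warn(f"unknown element {element!r}; using fallback vdW radius "
                      f"{_FALLBACK_RADIUS} Å")
        return _FALLBACK_RADIUS
    return BONDI_RADII[el]


@dataclass
class Structure:
    """A bag of atoms: elements, Cartesian coordinates (Å) and vdW radii."""

    elements: list[str]
    coords: np.ndarray              # (n, 3) Å
    radii: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.radii is None:
            self.radii = np.array([vdw_radius(e) for e in self.elements])
        else:
            self.radii = np.asarray(self.radii, float)
            if np.any(self.radii <= 0):
                raise ValueError("all vdW radii must be positive")

    def __len__(self) -> int:
        return len(self.elements)

    def __add__(self, other: "Structure") -> "Structure":
        """Union of two structures (e.g. receptor + ligand = complex)."""
        return Structure(
            elements=list(self.elements) + list(other.elements),
            coords=np.vstack([self.coords, other.coords]),
            radii=np.concatenate([self.radii, other.radii]),
        )


@dataclass(frozen=True)
class SasaRecord:
    """Surface areas (Å²) of a receptor–ligand pose and the derived burial."""

    sasa_receptor: float
    sasa_ligand: float
    sasa_complex: float
    conformer: str = ""

    @property
    def delta_sasa(self) -> float:
        return self.sasa_receptor + self.sasa_ligand - self.sasa_complex


@dataclass(frozen=True)
class DifferentialSasa:
    """ΔSASA_inactive − ΔSASA_active (Å²); positive ⇒ deeper inactive burial."""

    value: float

    @property
    def prefers_inactive(self) -> bool:
        return self.value > 0


def golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points on the golden-spiral lattice."""
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley(
    structure: Structure,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[np.ndarray, float]:
    """Per-atom and total solvent-accessible surface area (Å²).

    For each atom, ``n_points`` lattice points are placed on its inflated
    sphere of radius r_vdw + probe; a point is accessible when it lies
    outside every other atom's inflated sphere.  Atom SASA is the
    accessible fraction times the inflated sphere area; the total is exact
    (at any n_points) for an isolated atom and additive for
    non-interacting structures.
    """
    if n_points < 12:
        raise ValueError("n_points must be >= 12 for a usable estimate")
    n = len(structure)
    if n == 0:
        raise ValueError("empty structure")
    coords = structure.coords
    inflated = structure.radii + probe

    # coincident identical atoms would double-count surface silently
    tree = cKDTree(coords)
    dup = tree.query_pairs(r=1e-9)
    for i, j in dup:
        if structure.elements[i] == structure.elements[j]:
            raise ValueError(
                f"atoms {i} and {j} ({structure.elements[i]}) share one coordinate"
            )

    unit = golden_spiral_points(n_points)
    per_atom = np.zeros(n)
    max_reach = inflated.max()
    for i in range(n):
        pts = coords[i] + inflated[i] * unit
        neighbours = tree.query_ball_point(coords[i], r=inflated[i] + max_reach)
        neighbours = [j for j in neighbours if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > inflated[j] ** 2
            if not accessible.any():
                break
        per_atom[i] = accessible.mean() * 4.0 * np.pi * inflated[i] ** 2
    return per_atom, float(per_atom.sum())


def delta_sasa(
    receptor: Structure,
    ligand: Structure,
    complex_: Structure | None = None,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    conformer: str = "",
) -> SasaRecord:
    """Compute the three totals and the buried area ΔSASA for one pose.

    If no explicit complex structure is given, the union of receptor and
    ligand (as posed) is used.
    """
    if len(receptor) == 0 or len(ligand) == 0:
        raise ValueError("receptor and ligand must be non-empty")
    if complex_ is None:
        complex_ = receptor + ligand
    elif len(complex_) < len(receptor) + len(ligand):
        raise ValueError(
            f"complex has {len(complex_)} atoms, fewer than receptor+ligand "
            f"({len(receptor)}+{len(ligand)})"
        )
    _, sr = shrake_rupley(receptor, probe, n_points)
    _, sl = shrake_rupley(ligand, probe, n_points)
    _, sc = shrake_rupley(complex_, probe, n_points)
    return SasaRecord(sasa_receptor=sr, sasa_ligand=sl, sasa_complex=sc,
                      conformer=conformer)


def differential_sasa(inactive: SasaRecord, active: SasaRecord) -> DifferentialSasa:
    """ΔSASA_inactive − ΔSASA_active for the same ligand in two conformers."""
    if inactive.conformer and inactive.conformer == active.conformer:
        raise ValueError(
            f"both records carry the same conformer tag {inactive.conformer!r}"
        )
    return DifferentialSasa(value=inactive.delta_sasa - active.delta_sasa)


def read_pdb(path) -> Structure:
    """Read ATOM/HETATM records from a PDB file into a Structure.

    Occupancy alternates other than altloc A (or blank) are dropped; the
    element column is preferred, with an atom-name-based fallback.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="first")
    elements = []
    for el, name in zip(atoms.element, atoms.atom_name):
        el = el.strip()
        if not el:
            # fallback: first alphabetic character of the atom name
            el = next((ch for ch in name if ch.isalpha()), "C")
        elements.append(el.upper())
    return Structure(elements=elements, coords=np.asarray(atoms.coord, float))
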