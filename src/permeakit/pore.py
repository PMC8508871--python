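"""HOLE-style pore-radius profiling and structural superposition.

For each slice z along the membrane normal, the pore radius is the radius
of the largest sphere centered at (x, y, z) that touches no atom:

    r(z) = max_{x,y} min_i ( |p − a_i| − r_i ),

maximized by multi-start Nelder–Mead continued from the previous slice's
optimal center.  Profiles from replica structures can be averaged with SEM,
and a Kabsch least-squares superposition utility provides RMSD between two
conformations (e.g. closed vs. open states of a channel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomSet",
    "PoreProfile",
    "BONDI_RADII",
    "atomset_from_structure",
    "read_pdb",
    "pore_radius_profile",
    "average_profiles",
    "kabsch_rmsd",
    "kabsch_superpose",
]

#: Bondi van der Waals radii (Å) by element symbol.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70

#: residue names treated as solvent/ions and excluded by default
_SOLVENT_RES = {"HOH", "WAT", "TIP3", "SOL", "NA", "K", "CL", "CA", "MG", "ZN"}


@dataclass(frozen=True)
class AtomSet:
    """Coordinates (N, 3) Å, per-atom vdW radii (N,) Å, and labels."""

    coordinates: np.ndarray
    radii: np.ndarray
    residue_names: Optional[np.ndarray] = None
    chain_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")
        if radii.shape != (coords.shape[0],):
            raise ValueError("radii must have shape (N,)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if not np.all(radii > 0):
            raise ValueError("all vdW radii must be positive")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "radii", radii)

    def __len__(self) -> int:
        return len(self.coordinates)


def read_pdb(
    path,
    radii: str = "bondi",
    include_solvent: bool = False,
) -> AtomSet:
    """Load an AtomSet from a PDB file.

    radii : "bondi" (element lookup) or "occupancy" (per-atom radii stored
            in the occupancy column, the convention of the synthetic pore
            fixtures).
    Waters and common ions are excluded unless include_solvent is True.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, extra_fields=["occupancy"])
    if not include_solvent:
        keep = ~np.isin(atoms.res_name, list(_SOLVENT_RES))
        atoms = atoms[keep]
    if len(atoms) == 0:
        raise ValueError(f"no atoms read from {path}")
    if radii == "occupancy":
        r = np.asarray(atoms.occupancy, dtype=float)
        if not np.all(r > 0):
            raise ValueError("occupancy column does not hold positive radii")
    elif radii == "bondi":
        r = np.array([
            BONDI_RADII.get(str(e).upper(), _DEFAULT_RADIUS)
            for e in atoms.element
        ])
    else:
        raise ValueError("radii must be 'bondi' or 'occupancy'")
    return AtomSet(
        coordinates=np.asarray(atoms.coord, dtype=float),
        radii=r,
        residue_names=np.asarray(atoms.res_name),
        chain_ids=np.asarray(atoms.chain_id),
    )


def atomset_from_structure(atoms: struc.AtomArray,
                           radii: str = "occupancy") -> AtomSet:
    """Adapt a biotite AtomArray (e.g. a synthetic pore fixture) to an
    AtomSet; radii from the occupancy annotation or the Bondi table."""
    if radii == "occupancy":
        r = np.asarray(atoms.occupancy, dtype=float)
    elif radii == "bondi":
        r = np.array([BONDI_RADII.get(str(e).upper(), _DEFAULT_RADIUS)
                      for e in atoms.element])
    else:
        raise ValueError("radii must be 'bondi' or 'occupancy'")
    return AtomSet(coordinates=np.asarray(atoms.coord, dtype=float), radii=r,
                   residue_names=np.asarray(atoms.res_name),
                   chain_ids=np.asarray(atoms.chain_id))


@dataclass(frozen=True)
class PoreProfile:
    """Radius profile r(z) with the optimized center path."""

    z: np.ndarray
    radius: np.ndarray
    center_xy: np.ndarray          # (n_slices, 2)
    capped: np.ndarray             # slices where the radius hit the cap
    n_function_evals: int = 0


def _slice_objective(coords: np.ndarray, radii: np.ndarray, z: float):
    def clearance(p):
        d = np.sqrt((coords[:, 0] - p[0]) ** 2 + (coords[:, 1] - p[1]) ** 2
                    + (coords[:, 2] - z) ** 2)
        return float(np.min(d - radii))
    return clearance


def pore_radius_profile(
    atoms: AtomSet,
    z_range: Tuple[float, float],
    dz: float = 0.5,
    restarts: int = 6,
    seed: int = 0,
    radius_cap: float = 15.0,
    initial_center: Tuple[float, float] = (0.0, 0.0),
    search_radius: float = 3.0,
) -> PoreProfile:
    """Largest-inscribed-sphere radius at each z slice.

    Each slice is maximized by Nelder–Mead from the previous slice's center
    plus ``restarts`` seeded random restarts.  The search is softly confined
    to a disc of ``search_radius`` Å around the continuation center —
    initial_center must lie inside the pore, exactly like HOLE's seed point
    — which keeps the optimizer from wandering across the wall into the
    unbounded exterior.  Slices whose clearance exceeds ``radius_cap`` (an
    effectively unbounded slice, e.g. past the pore mouth) are set to the
    cap and flagged.
    """
    if len(atoms) < 4:
        raise ValueError("pore profiling needs at least 4 atoms")
    z_lo, z_hi = z_range
    if not z_hi >= z_lo:
        raise ValueError("z_range must be increasing")
    rng = np.random.default_rng(seed)
    z_slices = np.arange(z_lo, z_hi + 0.5 * dz, dz)
    coords, radii = atoms.coordinates, atoms.radii

    centers = np.empty((len(z_slices), 2))
    rr = np.empty(len(z_slices))
    capped = np.zeros(len(z_slices), dtype=bool)
    nfev = 0
    prev = np.asarray(initial_center, dtype=float)
    for i, z in enumerate(z_slices):
        clearance = _slice_objective(coords, radii, float(z))
        anchor = prev.copy()

        def neg_objective(p):
            excess = np.hypot(p[0] - anchor[0], p[1] - anchor[1]) - search_radius
            penalty = 10.0 * excess * excess if excess > 0 else 0.0
            return -(min(clearance(p), radius_cap + 1.0) - penalty)

        starts = [anchor]
        for _ in range(restarts):
            rho = search_radius * np.sqrt(rng.random())
            phi = 2.0 * np.pi * rng.random()
            starts.append(anchor + rho * np.array([np.cos(phi), np.sin(phi)]))
        best_p, best_r = anchor, clearance(anchor)
        for p0 in starts:
            res = minimize(neg_objective, p0, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6,
                                    "maxfev": 400})
            nfev += res.nfev
            r_here = clearance(res.x)
            if r_here > best_r:
                best_r, best_p = r_here, res.x
        if best_r > radius_cap:
            best_r = radius_cap
            capped[i] = True
        rr[i] = max(best_r, 0.0)
        centers[i] = best_p
        prev = np.asarray(best_p, dtype=float)
    return PoreProfile(z=z_slices, radius=rr, center_xy=centers,
                       capped=capped, n_function_evals=nfev)


def average_profiles(profiles: Sequence[PoreProfile],
                     grid: Optional[np.ndarray] = None):
    """Mean radius and SEM (n−1 denominator) over replica profiles.

    Profiles on different z grids are linearly interpolated onto ``grid``
    (default: the first profile's grid).  A single profile yields SEM None.
    Returns (z, mean, sem).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if grid is None:
        grid = profiles[0].z
    grid = np.asarray(grid, dtype=float)
    stack = np.stack([np.interp(grid, p.z, p.radius) for p in profiles])
    mean = stack.mean(axis=0)
    if len(profiles) == 1:
        return grid, mean, None
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(profiles))
    return grid, mean, sem


# --------------------------------------------------------------------------
# Kabsch superposition
# --------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares optimal proper rotation R and translation t such that
    mobile @ R.T + t best fits target.  Returns (R, t)."""
    a = np.asarray(mobile, dtype=float)
    b = np.asarray(target, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both have shape (N, 3)")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    return r, t


def kabsch_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    selection: Optional[np.ndarray] = None,
) -> float:
    """RMSD (Å) after optimal rigid superposition of B onto A.

    selection: optional index/boolean array applied to both sets; the
    superposition is fitted on (and the RMSD reported over) the selection.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if selection is not None:
        a, b = a[selection], b[selection]
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape} vs {b.shape}")
    r, t = kabsch_superpose(b, a)
    fitted = b @ r.T + t
    return float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
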