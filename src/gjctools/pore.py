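"""Pore-radius profiling of channel structures (inscribed-sphere method).

At each height z along the pore axis the profiler finds the largest sphere
centred in that plane that touches no atom, i.e. it maximises over the
in-plane centre c the clearance

    f(c) = min_i ( |c - x_i| - r_vdw,i )

where x_i, r_vdw,i are atom centres and van der Waals radii. Twice the
minimum of the resulting radius profile is the solvent-accessible pore
diameter at the constriction — the quantity that decides whether a hydrated
ion or a dye molecule can pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy.optimize import minimize

__all__ = [
    "VDW_RADII",
    "AtomSet",
    "PoreProfile",
    "load_structure",
    "pore_profile",
    "min_constriction_diameter",
]

#: Bondi-style van der Waals radii (Angstrom) for the elements that occur in
#: protein structures; unknown elements fall back to DEFAULT_VDW with a warning.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "FE": 1.80,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
}
DEFAULT_VDW = 1.70

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SOL"}


@dataclass
class AtomSet:
    """Heavy-atom coordinates with per-atom van der Waals radii."""

    coords: np.ndarray          # (n, 3) Angstrom
    vdw: np.ndarray             # (n,)
    elements: np.ndarray        # (n,) str
    labels: np.ndarray | None = None  # chain/residue tags, optional

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.vdw = np.asarray(self.vdw, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if np.any(self.vdw <= 0):
            raise ValueError("van der Waals radii must be positive")
        self.elements = np.asarray(self.elements, dtype=object)

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class PoreProfile:
    """Axial inscribed-sphere radius r(z) with the optimised in-plane centres."""

    z: np.ndarray
    radius: np.ndarray
    center_xy: np.ndarray       # (n, 2)
    unconstrained: np.ndarray   # bool: no atoms within cutoff, radius = r_max
    r_max: float


def load_structure(
    path: str | Path,
    include_waters: bool = False,
    include_hetero: bool = False,
    include_hydrogens: bool = False,
    radius_table: dict[str, float] | None = None,
) -> AtomSet:
    """Load a PDB or mmCIF file into an :class:`AtomSet`.

    Waters and hetero compounds are excluded by default; unknown elements get
    the default radius with a warning.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    table = radius_table if radius_table is not None else VDW_RADII

    coords: list[tuple[float, float, float]] = []
    vdw: list[float] = []
    elements: list[str] = []
    labels: list[str] = []
    warned: set[str] = set()
    model = st[0]
    for chain in model:
        for residue in chain:
            resname = residue.name.upper()
            if resname in _WATER_NAMES and not include_waters:
                continue
            is_het = residue.het_flag == "H" and resname not in _WATER_NAMES
            if is_het and not include_hetero:
                continue
            for atom in residue:
                el = atom.element.name.upper()
                if el == "H" and not include_hydrogens:
                    continue
                if el in table:
                    r = table[el]
                else:
                    r = DEFAULT_VDW
                    if el not in warned:
                        warnings.warn(
                            f"unknown element {el!r}: using default radius {DEFAULT_VDW} A",
                            stacklevel=2,
                        )
                        warned.add(el)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                vdw.append(r)
                elements.append(el)
                labels.append(f"{chain.name}/{residue.seqid.num}{residue.name}")
    if not coords:
        raise ValueError(f"{path}: no atoms after filtering")
    return AtomSet(
        coords=np.asarray(coords),
        vdw=np.asarray(vdw),
        elements=np.asarray(elements, dtype=object),
        labels=np.asarray(labels, dtype=object),
    )


def _clearance(cxy: np.ndarray, z: float, coords: np.ndarray, vdw: np.ndarray) -> float:
    d = np.sqrt(
        (coords[:, 0] - cxy[0]) ** 2
        + (coords[:, 1] - cxy[1]) ** 2
        + (coords[:, 2] - z) ** 2
    )
    return float(np.min(d - vdw))


def _penalized(cxy: np.ndarray, z: float, coords: np.ndarray, vdw: np.ndarray,
               axis_xy: tuple[float, float], max_shift: float) -> float:
    """Clearance with a quadratic penalty outside the allowed centre disk.

    The centre is confined to within ``max_shift`` of the nominal axis so the
    optimiser tracks the pore lumen instead of escaping sideways out of the
    structure, where the clearance grows without bound.
    """
    excess = math.hypot(cxy[0] - axis_xy[0], cxy[1] - axis_xy[1]) - max_shift
    pen = 1e4 * excess**2 if excess > 0 else 0.0
    return _clearance(cxy, z, coords, vdw) - pen


def pore_profile(
    atoms: AtomSet,
    z_range: tuple[float, float] | None = None,
    step: float = 0.5,
    axis_xy: tuple[float, float] = (0.0, 0.0),
    r_max: float = 20.0,
    influence_cutoff: float = 15.0,
    n_starts: int = 5,
    max_center_shift: float = 5.0,
) -> PoreProfile:
    """Inscribed-sphere pore-radius profile along the z axis.

    At each z sample the in-plane centre of the largest clearance sphere is
    found by multi-start Nelder-Mead local search seeded on the nominal axis,
    the previous plane's optimum, and the best points of a coarse grid, with
    the centre confined to within ``max_center_shift`` of the axis (so the
    search tracks the lumen instead of escaping sideways). Atoms further than
    ``influence_cutoff`` from the plane (plus the largest vdW radius) are
    culled. The radius is clamped to ``[0, r_max]``; planes with no atoms in
    reach report ``r_max`` and are flagged unconstrained.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    zlo_atoms = atoms.coords[:, 2].min()
    zhi_atoms = atoms.coords[:, 2].max()
    if z_range is None:
        z_range = (zlo_atoms, zhi_atoms)
    zlo, zhi = z_range
    if zlo > zhi:
        raise ValueError("empty z range")
    z_samples = np.arange(zlo, zhi + step / 2, step)

    max_vdw = float(atoms.vdw.max())
    radii = np.empty(len(z_samples))
    centers = np.empty((len(z_samples), 2))
    flags = np.zeros(len(z_samples), dtype=bool)

    prev_center: np.ndarray | None = None
    for i, z in enumerate(z_samples):
        near = np.abs(atoms.coords[:, 2] - z) <= influence_cutoff + max_vdw
        coords = atoms.coords[near]
        vdw = atoms.vdw[near]
        if len(coords) == 0:
            radii[i] = r_max
            centers[i] = axis_xy
            flags[i] = True
            continue

        starts = [np.asarray(axis_xy, dtype=float)]
        if prev_center is not None:
            starts.append(prev_center)
        # coarse grid candidates inside the allowed centre disk
        g1 = np.linspace(-max_center_shift, max_center_shift, 7)
        GX, GY = np.meshgrid(axis_xy[0] + g1, axis_xy[1] + g1)
        grid = np.column_stack([GX.ravel(), GY.ravel()])
        inside = np.hypot(grid[:, 0] - axis_xy[0], grid[:, 1] - axis_xy[1]) <= max_center_shift
        grid = grid[inside]
        vals = [_clearance(g, z, coords, vdw) for g in grid]
        order = np.argsort(vals)[::-1]
        for j in order[: max(0, n_starts - len(starts))]:
            starts.append(grid[j])

        best_val = -np.inf
        best_c = starts[0]
        for s in starts[:n_starts]:
            res = minimize(
                lambda c: -_penalized(c, z, coords, vdw, axis_xy, max_center_shift),
                s,
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
            )
            val = _clearance(res.x, z, coords, vdw)
            if val > best_val:
                best_val = val
                best_c = res.x
        radii[i] = float(np.clip(best_val, 0.0, r_max))
        centers[i] = best_c
        prev_center = np.asarray(best_c, dtype=float)
    return PoreProfile(z=z_samples, radius=radii, center_xy=centers,
                       unconstrained=flags, r_max=r_max)


def min_constriction_diameter(
    profile: PoreProfile, z_window: tuple[float, float] | None = None
) -> float:
    """Solvent-accessible diameter at the constriction: 2 * min r(z) in window."""
    if z_window is None:
        mask = np.ones(len(profile.z), dtype=bool)
    else:
        lo, hi = z_window
        mask = (profile.z >= lo) & (profile.z <= hi)
    if not mask.any():
        raise ValueError("empty z window")
    return float(2.0 * profile.radius[mask].min())
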