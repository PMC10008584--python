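"""Ionic currents, conductance and spatial ion statistics from trajectories.

The channel axis is z, with the junction midplane at z = 0. Currents are
estimated from complete gate passages: an ion that was last below the lower
gate plane and first rises above the upper plane has made one up-crossing
(two-plane hysteresis suppresses diffusive recrossing noise at a single
plane). With net crossings ``n`` of charge ``q`` over duration ``T`` the
current is ``I = q e n / T`` and the single-channel conductance ``g = I/V``.
Simulated conductances carry a water-model viscosity correction: the common
rigid three-site water models are roughly three times less viscous than real
water, inflating diffusion coefficients and therefore currents by about the
same factor, so ``g_corrected = g / 3`` by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ELEMENTARY_CHARGE_C",
    "IonTrajectory",
    "CrossingCount",
    "CurrentEstimate",
    "ConcentrationProfile",
    "DensityFluxMap",
    "count_crossings",
    "current_with_error",
    "ionic_current",
    "conductance",
    "selectivity_ratio",
    "concentration_profile",
    "density_flux_map",
    "axial_current_profile",
    "read_trajectory_text",
    "write_trajectory_text",
    "trajectory_from_mdanalysis",
]

ELEMENTARY_CHARGE_C = 1.602176634e-19
AVOGADRO = 6.02214076e23
#: 1 ion per A^3 expressed in mol/L (1 / (N_A * 1e-27 L))
IONS_PER_A3_TO_MOLAR = 1.0 / (AVOGADRO * 1e-27)


@dataclass
class IonTrajectory:
    """Per-frame ion coordinates with the metadata needed for current analysis.

    Attributes
    ----------
    positions:
        array of shape ``(n_frames, n_ions, 3)`` in Angstrom; wrapped into the
        periodic box along z.
    species:
        length ``n_ions`` array of labels (e.g. ``"NA"``, ``"CL"``).
    charges:
        species -> signed charge in elementary units.
    dt_ps:
        time between stored frames, picoseconds.
    box:
        orthorhombic box lengths (3,) in Angstrom; z-periodic.
    voltage_mV:
        applied transjunctional bias along +z.
    """

    positions: np.ndarray
    species: np.ndarray
    charges: Mapping[str, int]
    dt_ps: float
    box: np.ndarray
    voltage_mV: float = 0.0
    temperature_K: float = 300.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_ions, 3)")
        if self.species.shape[0] != self.positions.shape[1]:
            raise ValueError("species length must match n_ions")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite coordinates in trajectory")
        if self.dt_ps <= 0:
            raise ValueError("dt must be positive")
        for sp in np.unique(self.species):
            if sp not in self.charges:
                raise ValueError(f"no charge given for species {sp!r}")
            if self.charges[sp] == 0:
                raise ValueError(f"species {sp!r} has zero charge")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_ions(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_ns(self) -> float:
        """Sampled duration (n_frames - 1) * dt, in nanoseconds."""
        return (self.n_frames - 1) * self.dt_ps * 1e-3

    def select(self, species: str) -> np.ndarray:
        return np.flatnonzero(self.species == species)

    def unwrapped_z(self, ion_indices: np.ndarray | None = None) -> np.ndarray:
        """z(t) per ion with periodic wrap jumps removed (minimum image)."""
        z = self.positions[:, :, 2] if ion_indices is None else self.positions[:, ion_indices, 2]
        lz = self.box[2]
        dz = np.diff(z, axis=0)
        dz -= lz * np.round(dz / lz)
        return np.vstack([z[:1], z[:1] + np.cumsum(dz, axis=0)])


@dataclass
class CrossingCount:
    species: str
    n_up: int
    n_down: int
    gate: tuple[float, float]

    @property
    def net(self) -> int:
        return self.n_up - self.n_down


@dataclass
class CurrentEstimate:
    """Current and conductance, raw and viscosity-corrected."""

    I_nA: float
    V_mV: float
    g_pS: float
    g_corrected_pS: float
    correction_factor: float


@dataclass
class ConcentrationProfile:
    z_edges: np.ndarray
    molarity: dict[str, np.ndarray]
    radius: float

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


@dataclass
class DensityFluxMap:
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    density: dict[str, np.ndarray]  # ions / A^3, time-averaged
    flux: dict[str, np.ndarray]     # (nx, ny, nz, 3) mean velocity A/ps
    spacing: float

    @property
    def voxel_volume(self) -> float:
        d = [e[1] - e[0] for e in self.edges]
        return d[0] * d[1] * d[2]


def count_crossings(
    traj: IonTrajectory,
    z_lo: float,
    z_hi: float,
    species: str | None = None,
) -> CrossingCount:
    """Count complete gate passages with two-plane hysteresis.

    An up-crossing is recorded when an ion that was last below ``z_lo`` first
    exceeds ``z_hi`` (mirror for down-crossings); oscillation inside the gate
    is not counted. Periodic wrap jumps (|dz| > box_z/2) move the ion between
    the reservoir ends without passing the gate and re-arm the detector
    without counting.
    """
    if not z_lo < z_hi:
        raise ValueError("need z_lo < z_hi")
    lz = traj.box[2]
    if z_hi - z_lo >= lz:
        raise ValueError("gate wider than the periodic box")
    idx = traj.select(species) if species is not None else np.arange(traj.n_ions)
    if species is None:
        uniq = np.unique(traj.species)
        if len(uniq) > 1:
            raise ValueError("trajectory has several species; pass species=")
        species = str(uniq[0])

    z = traj.positions[:, idx, 2]
    n_up = n_down = 0
    for j in range(z.shape[1]):
        zj = z[:, j]
        # armed side: -1 below gate, +1 above, 0 not yet armed (started inside)
        side = -1 if zj[0] < z_lo else (1 if zj[0] > z_hi else 0)
        for t in range(1, len(zj)):
            zt = zj[t]
            if abs(zt - zj[t - 1]) > lz / 2:
                # wrap through the periodic boundary: re-arm, never count
                side = -1 if zt < z_lo else (1 if zt > z_hi else side)
                continue
            if zt > z_hi:
                if side == -1:
                    n_up += 1
                side = 1
            elif zt < z_lo:
                if side == 1:
                    n_down += 1
                side = -1
    return CrossingCount(species=species, n_up=n_up, n_down=n_down, gate=(z_lo, z_hi))


def ionic_current(crossings: CrossingCount, duration_ns: float, charge_e: int) -> float:
    """Current in nA from net gate crossings: I = q e (n_up - n_down) / T."""
    if duration_ns <= 0:
        raise ValueError("duration must be positive")
    coulombs = charge_e * ELEMENTARY_CHARGE_C * crossings.net
    return coulombs / (duration_ns * 1e-9) * 1e9  # A -> nA


def current_with_error(
    traj: IonTrajectory,
    z_lo: float,
    z_hi: float,
    species: str,
    n_blocks: int = 20,
) -> tuple[float, float]:
    """Crossing-count current (nA) with a block-averaged standard error.

    The trajectory is split into ``n_blocks`` contiguous time blocks; the
    current is estimated in each and the standard error of the mean over
    blocks is returned alongside the full-trajectory estimate.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    q = traj.charges[species]
    full = ionic_current(count_crossings(traj, z_lo, z_hi, species), traj.duration_ns, q)
    bounds = np.linspace(0, traj.n_frames, n_blocks + 1).astype(int)
    block_I = []
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        if hi - lo < 2:
            continue
        sub = IonTrajectory(
            positions=traj.positions[lo:hi],
            species=traj.species,
            charges=traj.charges,
            dt_ps=traj.dt_ps,
            box=traj.box,
            voltage_mV=traj.voltage_mV,
            temperature_K=traj.temperature_K,
        )
        block_I.append(
            ionic_current(count_crossings(sub, z_lo, z_hi, species), sub.duration_ns, q)
        )
    block_I = np.asarray(block_I)
    se = float(block_I.std(ddof=1) / math.sqrt(len(block_I)))
    return full, se


def conductance(
    I_total_nA: float,
    V_mV: float,
    correction_factor: float = 3.0,
) -> CurrentEstimate:
    """Single-channel conductance g = I/V, with viscosity correction.

    Unit chain: ``g[pS] = 1e6 * I[nA] / V[mV]`` (1 nA / 1 mV = 1 uS = 1e6 pS).
    The corrected value divides by ``correction_factor`` (default 3.0) to
    compensate the ~3x-too-fast diffusion of standard simulation water.
    """
    if V_mV == 0:
        raise ValueError("V must be nonzero")
    if correction_factor <= 0:
        raise ValueError("correction factor must be positive")
    g = 1e6 * I_total_nA / V_mV
    return CurrentEstimate(
        I_nA=I_total_nA,
        V_mV=V_mV,
        g_pS=g,
        g_corrected_pS=g / correction_factor,
        correction_factor=correction_factor,
    )


def selectivity_ratio(I_cation_nA: float, I_anion_nA: float) -> tuple[float, bool]:
    """|I_cation| / |I_anion|; returns (ratio, unbounded_flag).

    A zero anion current makes the ratio unbounded (perfect cation
    selectivity); it is returned as ``(inf, True)``. Both currents zero is
    undefined and returned as ``(nan, True)``.
    """
    ic, ia = abs(I_cation_nA), abs(I_anion_nA)
    if ic == 0 and ia == 0:
        return math.nan, True
    if ia == 0:
        return math.inf, True
    return ic / ia, False


def concentration_profile(
    traj: IonTrajectory,
    radius: float,
    z_edges: Sequence[float],
    center_xy: tuple[float, float] = (0.0, 0.0),
) -> ConcentrationProfile:
    """Axial molarity profile inside a cylinder around the pore axis.

    Per bin: mean ion count / (N_A * bin volume), with the bin volume
    ``pi r^2 dz`` converted to litres (1 A^3 = 1e-27 L).
    """
    z_edges = np.asarray(z_edges, dtype=float)
    if radius <= 0:
        raise ValueError("cylinder radius must be positive")
    if len(z_edges) < 2 or np.any(np.diff(z_edges) <= 0):
        raise ValueError("z_edges must be increasing with >= 2 entries")

    dz = np.diff(z_edges)
    bin_vol_L = math.pi * radius**2 * dz * 1e-27
    molarity: dict[str, np.ndarray] = {}
    cx, cy = center_xy
    r2 = (traj.positions[:, :, 0] - cx) ** 2 + (traj.positions[:, :, 1] - cy) ** 2
    inside = r2 <= radius**2
    for sp in np.unique(traj.species):
        cols = traj.select(str(sp))
        zs = traj.positions[:, cols, 2][inside[:, cols]]
        counts, _ = np.histogram(zs, bins=z_edges)
        mean_occ = counts / traj.n_frames
        molarity[str(sp)] = mean_occ / (AVOGADRO * bin_vol_L)
    return ConcentrationProfile(z_edges=z_edges, molarity=molarity, radius=radius)


def density_flux_map(traj: IonTrajectory, spacing: float) -> DensityFluxMap:
    """Time-averaged 3D number density and occupancy-weighted flux per voxel.

    The flux vector in a voxel is the mean frame-to-frame displacement rate
    (periodic-unwrapped, in A/ps) of ions whose step midpoint falls in the
    voxel — the discrete analogue of the local drift velocity. Multiplying by
    the local density gives the current-density field.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if np.any(spacing > traj.box):
        raise ValueError("spacing larger than the box")
    lo = traj.positions.reshape(-1, 3).min(axis=0) - 1e-9
    hi = traj.positions.reshape(-1, 3).max(axis=0) + 1e-9
    edges = tuple(
        np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)
    )
    nbins = tuple(len(e) - 1 for e in edges)

    density: dict[str, np.ndarray] = {}
    flux: dict[str, np.ndarray] = {}
    lz = traj.box[2]
    voxel_vol = float(np.prod([e[1] - e[0] for e in edges]))
    for sp in np.unique(traj.species):
        cols = traj.select(str(sp))
        pos = traj.positions[:, cols, :]
        pts = pos.reshape(-1, 3)
        h, _ = np.histogramdd(pts, bins=edges)
        density[str(sp)] = h / (traj.n_frames * voxel_vol)

        disp = np.diff(pos, axis=0)
        disp[:, :, 2] -= lz * np.round(disp[:, :, 2] / lz)
        vel = disp / traj.dt_ps
        mid = pos[:-1] + 0.5 * disp
        mid_pts = mid.reshape(-1, 3)
        vel_pts = vel.reshape(-1, 3)
        vsum = np.zeros(nbins + (3,))
        count = np.zeros(nbins)
        ix = [
            np.clip(np.searchsorted(edges[d], mid_pts[:, d], side="right") - 1, 0, nbins[d] - 1)
            for d in range(3)
        ]
        np.add.at(count, tuple(ix), 1)
        for d in range(3):
            np.add.at(vsum[..., d], tuple(ix), vel_pts[:, d])
        with np.errstate(invalid="ignore"):
            mean_v = np.where(count[..., None] > 0, vsum / np.maximum(count, 1)[..., None], 0.0)
        flux[str(sp)] = mean_v
    return DensityFluxMap(edges=edges, density=density, flux=flux, spacing=spacing)


def axial_current_profile(
    traj: IonTrajectory, z_edges: Sequence[float], species: str | None = None
) -> np.ndarray:
    """Current (nA) carried through each axial slab, displacement estimator.

    Per slab of thickness ``L_b``: ``I_b = (q e / T) * sum(dz steps in slab) / L_b``
    with step z-displacements assigned to the step midpoint. For a stationary
    current this is flat in z and equals the crossing-count current.
    """
    z_edges = np.asarray(z_edges, dtype=float)
    idx = traj.select(species) if species is not None else np.arange(traj.n_ions)
    if species is None:
        uniq = np.unique(traj.species)
        if len(uniq) > 1:
            raise ValueError("trajectory has several species; pass species=")
        species = str(uniq[0])
    q = traj.charges[species]
    z = traj.positions[:, idx, 2]
    lz = traj.box[2]
    dz = np.diff(z, axis=0)
    dz -= lz * np.round(dz / lz)
    zmid = z[:-1] + 0.5 * dz
    zmid = ((zmid - z_edges[0]) % lz) + z_edges[0]  # fold midpoints into range
    sums, _ = np.histogram(zmid.ravel(), bins=z_edges, weights=dz.ravel())
    widths = np.diff(z_edges)
    T_s = traj.duration_ns * 1e-9
    return q * ELEMENTARY_CHARGE_C * (sums / widths) / T_s * 1e9


# ---------------------------------------------------------------------------
# Trajectory I/O: columnar text contract + optional MDAnalysis adapter
# ---------------------------------------------------------------------------

def write_trajectory_text(traj: IonTrajectory, path: str | Path) -> Path:
    """Write the columnar text format: header metadata then one row per
    (frame, ion): ``frame ion_id species x y z``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# gjctools ion trajectory v1\n")
        fh.write(f"# dt_ps {traj.dt_ps:.9g}\n")
        fh.write(f"# box {traj.box[0]:.9g} {traj.box[1]:.9g} {traj.box[2]:.9g}\n")
        fh.write(f"# voltage_mV {traj.voltage_mV:.9g}\n")
        fh.write(f"# temperature_K {traj.temperature_K:.9g}\n")
        for sp, q in traj.charges.items():
            fh.write(f"# charge {sp} {q}\n")
        fh.write("# columns frame ion_id species x y z\n")
        for t in range(traj.n_frames):
            for j in range(traj.n_ions):
                x, y, z = traj.positions[t, j]
                fh.write(f"{t} {j} {traj.species[j]} {x:.4f} {y:.4f} {z:.4f}\n")
    return path


def read_trajectory_text(path: str | Path) -> IonTrajectory:
    """Read the columnar text trajectory format written by
    :func:`write_trajectory_text`."""
    path = Path(path)
    meta: dict[str, object] = {"charges": {}}
    rows: list[tuple[int, int, str, float, float, float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if not parts:
                    continue
                key = parts[0]
                if key == "dt_ps":
                    meta["dt_ps"] = float(parts[1])
                elif key == "box":
                    meta["box"] = [float(v) for v in parts[1:4]]
                elif key == "voltage_mV":
                    meta["voltage_mV"] = float(parts[1])
                elif key == "temperature_K":
                    meta["temperature_K"] = float(parts[1])
                elif key == "charge":
                    meta["charges"][parts[1]] = int(parts[2])  # type: ignore[index]
                continue
            f, i, sp, x, y, z = line.split()
            rows.append((int(f), int(i), sp, float(x), float(y), float(z)))
    if "dt_ps" not in meta or "box" not in meta:
        raise ValueError(f"{path}: missing dt_ps/box header lines")
    n_frames = max(r[0] for r in rows) + 1
    n_ions = max(r[1] for r in rows) + 1
    positions = np.full((n_frames, n_ions, 3), np.nan)
    species = np.empty(n_ions, dtype=object)
    for f, i, sp, x, y, z in rows:
        positions[f, i] = (x, y, z)
        species[i] = sp
    return IonTrajectory(
        positions=positions,
        species=species,
        charges=meta["charges"],  # type: ignore[arg-type]
        dt_ps=float(meta["dt_ps"]),  # type: ignore[arg-type]
        box=np.asarray(meta["box"], dtype=float),
        voltage_mV=float(meta.get("voltage_mV", 0.0)),  # type: ignore[arg-type]
        temperature_K=float(meta.get("temperature_K", 300.0)),  # type: ignore[arg-type]
    )


def trajectory_from_mdanalysis(
    universe,
    selection: str,
    charges: Mapping[str, int],
    voltage_mV: float = 0.0,
    temperature_K: float = 300.0,
) -> IonTrajectory:
    """Adapter for standard MD trajectory formats via an MDAnalysis Universe.

    ``selection`` picks the ion atoms; species labels are taken from atom
    names. Frames are loaded into memory, so select ions, not water.
    """
    ions = universe.select_atoms(selection)
    frames = []
    for ts in universe.trajectory:
        frames.append(ions.positions.copy())
    dt_ps = float(universe.trajectory.dt)
    box = np.asarray(universe.dimensions[:3], dtype=float)
    return IonTrajectory(
        positions=np.asarray(frames),
        species=np.asarray([a.name.upper() for a in ions], dtype=object),
        charges=charges,
        dt_ps=dt_ps,
        box=box,
        voltage_mV=voltage_mV,
        temperature_K=temperature_K,
    )
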