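"""Synthetic inputs with known ground truth for every analysis in the package.

Three generators:

* classification metadata — symmetry-expanded particle tables in which each
  protomer is pore-lining with probability ``p``, optionally with a
  nearest-neighbour Ising coupling ``J`` on each hexameric ring (J = 0 is
  exact independence; the external field is solved numerically so the
  marginal stays at ``p`` for any J);
* ion trajectories — overdamped (Brownian/Langevin) drift-diffusion in a
  cylindrical pore with a constant field from the applied voltage, optional
  Gaussian axial potential wells mimicking acidic binding bands, radial
  reflection at the pore wall and a z-periodic box. For a uniform field the
  steady-state current has the constant-field Nernst–Planck closed form,
  which serves as an exact oracle for the crossing-count estimator;
* toy pore structures — rings of atoms writable as PDB, whose inscribed-
  sphere radius is known in closed form.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .metadata import ParticleTable
from .permeation import AVOGADRO, IonTrajectory
from .pore import AtomSet, VDW_RADII

__all__ = [
    "MetadataSimConfig",
    "PoreSimConfig",
    "simulate_metadata",
    "exact_ring_distribution",
    "ring_states",
    "sample_rings",
    "simulate_ion_trajectory",
    "closed_form_current",
    "simulate_toy_pore",
    "write_toy_pdb",
]

KB_MEV_PER_K = 8.617333262e-2  # Boltzmann constant, meV/K
RING_LEN = 6

# ---------------------------------------------------------------------------
# Classification metadata with a ring-Ising ground truth
# ---------------------------------------------------------------------------


@dataclass
class MetadataSimConfig:
    """Ground-truth parameters for synthetic classification metadata.

    ``p_pln`` is the marginal probability that a protomer is pore-lining;
    ``coupling_J`` the nearest-neighbour Ising coupling on each 6-ring in
    units of kT (0 = independent protomers; positive favours like
    neighbours). ``class_map`` lists the class ids emitted for each state;
    defaults mirror an eight-class protomer classification with five
    pore-lining and three flexible classes.
    """

    n_particles: int = 1000
    p_pln: float = 0.57
    coupling_J: float = 0.0
    symmetry: str = "D6"
    class_map: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {"PLN": (1, 2, 3, 4, 7), "FN": (5, 6, 8)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if not 0.0 <= self.p_pln <= 1.0:
            raise ValueError("p_pln must lie in [0, 1]")
        if self.symmetry not in ("C6", "D6"):
            raise ValueError("symmetry must be C6 or D6")
        if not self.class_map.get("PLN") or not self.class_map.get("FN"):
            raise ValueError("class_map must list class ids for both PLN and FN")


def ring_states() -> list[tuple[int, ...]]:
    """All 64 labellings of a 6-ring as tuples over {0 (=F), 1 (=P)}."""
    return list(itertools.product((0, 1), repeat=RING_LEN))


def _ring_log_weights(h: float, J: float) -> np.ndarray:
    states = np.array(ring_states(), dtype=float)
    sigma = 2 * states - 1
    nn = (sigma * np.roll(sigma, -1, axis=1)).sum(axis=1)
    return J * nn + h * sigma.sum(axis=1)


def _marginal_p(h: float, J: float) -> float:
    lw = _ring_log_weights(h, J)
    w = np.exp(lw - lw.max())
    w /= w.sum()
    k = np.array([sum(s) for s in ring_states()], dtype=float)
    return float((w * k).sum() / RING_LEN)


def solve_field_for_marginal(p: float, J: float) -> float:
    """External field h (units of kT) giving marginal P(pore-lining) = p on a
    6-ring with coupling J, by root finding on the exact ring marginal."""
    if not 0.0 < p < 1.0:
        raise ValueError("marginal must be strictly inside (0, 1)")
    lo, hi = -60.0, 60.0
    flo, fhi = _marginal_p(lo, J) - p, _marginal_p(hi, J) - p
    if flo > 0 or fhi < 0:
        raise ValueError(f"marginal {p} unattainable for coupling J={J}")
    return float(brentq(lambda h: _marginal_p(h, J) - p, lo, hi, xtol=1e-12))


def exact_ring_distribution(p: float, J: float) -> dict[str, float]:
    """Exact probability of every length-6 ring string under the Ising model.

    Enumerates the 64 states with Boltzmann weights ``exp(J sum sigma_i
    sigma_{i+1} + h sum sigma_i)`` where sigma = +1 for a pore-lining ('P')
    protomer, and h is solved so the single-site marginal equals ``p``.
    J = 0 reduces to product Bernoulli(p).
    """
    states = ring_states()
    if p <= 0.0 or p >= 1.0:
        degenerate = "P" * RING_LEN if p >= 1.0 else "F" * RING_LEN
        return {
            "".join("P" if b else "F" for b in s): (
                1.0 if "".join("P" if b else "F" for b in s) == degenerate else 0.0
            )
            for s in states
        }
    h = solve_field_for_marginal(p, J)
    lw = _ring_log_weights(h, J)
    w = np.exp(lw - lw.max())
    w /= w.sum()
    return {
        "".join("P" if b else "F" for b in s): float(wi) for s, wi in zip(states, w)
    }


def sample_rings(
    n_rings: int,
    p: float,
    J: float,
    rng: np.random.Generator,
    burn_in: int = 500,
) -> np.ndarray:
    """Sample ring labellings; (n_rings, 6) int array, 1 = pore-lining.

    Independent Bernoulli draws when J = 0; otherwise a Gibbs sampler on the
    6-cycle Ising model, vectorised across rings, with ``burn_in`` full
    sweeps from a Bernoulli(p) start.
    """
    if p in (0.0, 1.0):
        return np.full((n_rings, RING_LEN), int(p), dtype=np.int8)
    if J == 0.0:
        return (rng.random((n_rings, RING_LEN)) < p).astype(np.int8)
    h = solve_field_for_marginal(p, J)
    sigma = np.where(rng.random((n_rings, RING_LEN)) < p, 1, -1).astype(np.int8)
    for _ in range(burn_in):
        for i in range(RING_LEN):
            nb = sigma[:, (i - 1) % RING_LEN] + sigma[:, (i + 1) % RING_LEN]
            p_up = 1.0 / (1.0 + np.exp(-2.0 * (h + J * nb)))
            sigma[:, i] = np.where(rng.random(n_rings) < p_up, 1, -1)
    return ((sigma + 1) // 2).astype(np.int8)


def simulate_metadata(config: MetadataSimConfig) -> tuple[ParticleTable, dict]:
    """Generate a symmetry-expanded, state-assigned particle table.

    Each particle gets one ring per hemichannel (two for D6, one for C6),
    sampled from the ring-Ising ground truth; records carry the expansion
    rotation (60-degree grid), hemichannel/position indices and a class id
    drawn uniformly from the configured ids for the protomer's state — i.e.
    exactly what symmetry expansion plus subunit-focused classification
    would leave in the metadata.

    Returns the table and a ground-truth record (parameters, realised
    pore-lining fraction, ring arrays).
    """
    rng = np.random.default_rng(config.seed)
    n_hemi = 2 if config.symmetry == "D6" else 1
    n_rings = config.n_particles * n_hemi
    rings = sample_rings(n_rings, config.p_pln, config.coupling_J, rng)
    rings = rings.reshape(config.n_particles, n_hemi, RING_LEN)

    n_rec = config.n_particles * n_hemi * RING_LEN
    particle_ids = np.repeat(
        np.array(
            [f"{i + 1:06d}@sim_particles.mrcs" for i in range(config.n_particles)],
            dtype=object,
        ),
        n_hemi * RING_LEN,
    )
    hemi = np.tile(np.repeat(np.arange(n_hemi), RING_LEN), config.n_particles)
    pos = np.tile(np.arange(RING_LEN), config.n_particles * n_hemi)
    states_flat = rings.reshape(-1)

    pln_ids = np.asarray(config.class_map["PLN"], dtype=int)
    fn_ids = np.asarray(config.class_map["FN"], dtype=int)
    class_id = np.where(
        states_flat == 1,
        pln_ids[rng.integers(0, len(pln_ids), n_rec)],
        fn_ids[rng.integers(0, len(fn_ids), n_rec)],
    )

    df = pd.DataFrame(
        {
            "particle_id": particle_ids,
            "class_id": class_id,
            "state": np.where(states_flat == 1, "PLN", "FN"),
            "rot_deg": pos * 60.0,
            "tilt_deg": hemi * 180.0,
            "psi_deg": 0.0,
            "tilt_flipped": hemi.astype(bool),
            "hemichannel_index": pd.array(hemi, dtype="Int64"),
            "position_index": pd.array(pos, dtype="Int64"),
        }
    )
    table = ParticleTable(
        df=df,
        symmetry_group=config.symmetry,
        provenance=f"simulate_metadata(seed={config.seed})",
    )
    truth = {
        "p_pln": config.p_pln,
        "coupling_J": config.coupling_J,
        "seed": config.seed,
        "symmetry": config.symmetry,
        "n_particles": config.n_particles,
        "realized_p_pln": float(states_flat.mean()),
        "rings": rings,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Drift-diffusion ion trajectories with a Nernst-Planck oracle
# ---------------------------------------------------------------------------


@dataclass
class PoreSimConfig:
    """Overdamped drift-diffusion simulation of ions in a cylindrical pore.

    The box is a cylinder of ``pore_radius`` and length ``box_length`` (A),
    z-periodic. The applied ``voltage_mV`` drops uniformly across the pore
    segment of ``pore_length`` centred at z = 0 (field zero elsewhere); with
    ``pore_length == box_length`` the system is homogeneous and the
    constant-field closed form is exact. ``wells`` adds Gaussian axial
    potential wells (depth kT, centre A, width A) per species to mimic
    binding bands. ``n_ions`` per species defaults to
    concentration x cylinder volume.
    """

    species: tuple[str, ...] = ("NA", "CL")
    charges: Mapping[str, int] = field(default_factory=lambda: {"NA": 1, "CL": -1})
    diffusion_A2_per_ps: Mapping[str, float] = field(
        default_factory=lambda: {"NA": 0.13, "CL": 0.20}
    )
    pore_radius: float = 10.0
    pore_length: float = 200.0
    box_length: float = 200.0
    voltage_mV: float = 200.0
    concentration_M: float = 0.15
    n_ions: Mapping[str, int] | None = None
    wells: Mapping[str, Sequence[tuple[float, float, float]]] = field(default_factory=dict)
    temperature_K: float = 300.0
    dt_ps: float = 1.0
    n_steps: int = 20_000
    stride: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pore_length > self.box_length:
            raise ValueError("pore_length cannot exceed box_length")
        if self.dt_ps <= 0 or self.n_steps < 1:
            raise ValueError("need positive dt and at least one step")
        # overdamped stability: drift per step well under the gate scale
        if self.dt_ps * self.max_drift_per_ps() > 0.5:
            raise ValueError("dt too large: drift per step exceeds 0.5 A")

    @property
    def volume_A3(self) -> float:
        return math.pi * self.pore_radius**2 * self.box_length

    @property
    def kT_meV(self) -> float:
        return KB_MEV_PER_K * self.temperature_K

    def field_mV_per_A(self) -> float:
        return self.voltage_mV / self.pore_length

    def max_drift_per_ps(self) -> float:
        e = abs(self.field_mV_per_A())
        drifts = [
            self.diffusion_A2_per_ps[sp] * abs(self.charges[sp]) * e / self.kT_meV
            for sp in self.species
        ]
        for sp, ws in self.wells.items():
            for depth, _, width in ws:
                # max slope of a Gaussian well of depth d (kT), width w
                drifts.append(
                    self.diffusion_A2_per_ps[sp]
                    * abs(depth)
                    / (width * math.sqrt(math.e))
                )
        return max(drifts)

    def ion_counts(self) -> dict[str, int]:
        if self.n_ions is not None:
            counts = dict(self.n_ions)
        else:
            per = self.concentration_M * self.volume_A3 / (1e27 / AVOGADRO)
            counts = {sp: int(round(per)) for sp in self.species}
        expected = self.concentration_M * self.volume_A3 * AVOGADRO * 1e-27
        for sp, n in counts.items():
            if expected > 0 and abs(n - expected) / expected > 0.10:
                warnings.warn(
                    f"{sp}: {n} ions vs {expected:.1f} expected from "
                    f"{self.concentration_M} M x volume (>10% off)",
                    stacklevel=2,
                )
        return counts


def _well_force(z: np.ndarray, wells: Sequence[tuple[float, float, float]],
                kT: float) -> np.ndarray:
    """-dU/dz (meV/A) for a sum of Gaussian wells U = -sum d_k kT exp(-(z-z_k)^2/2w^2)."""
    f = np.zeros_like(z)
    for depth_kT, z0, width in wells:
        u = (z - z0) / width
        f += -depth_kT * kT * u / width * np.exp(-0.5 * u**2)
    return f


def simulate_ion_trajectory(config: PoreSimConfig) -> IonTrajectory:
    """Overdamped Langevin trajectory of all ions in the cylindrical pore.

    Per step and ion: ``dz = (D q E(z)/kT + D F_well(z)/kT) dt + sqrt(2 D dt) xi``
    plus isotropic diffusion in x, y with reflection at the pore wall; z is
    wrapped periodically. Frames are stored every ``stride`` steps.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.ion_counts()
    kT = config.kT_meV
    L = config.box_length
    Lp = config.pore_length
    R = config.pore_radius
    E = config.field_mV_per_A()

    species_arr = []
    pos_blocks = []
    for sp in config.species:
        n = counts.get(sp, 0)
        if n == 0:
            continue
        r = R * np.sqrt(rng.random(n))
        theta = 2 * math.pi * rng.random(n)
        z = (rng.random(n) - 0.5) * L
        pos_blocks.append(np.column_stack([r * np.cos(theta), r * np.sin(theta), z]))
        species_arr.extend([sp] * n)
    pos = np.vstack(pos_blocks)
    species = np.asarray(species_arr, dtype=object)

    D = np.array([config.diffusion_A2_per_ps[sp] for sp in species])
    q = np.array([config.charges[sp] for sp in species], dtype=float)

    n_saved = config.n_steps // config.stride + 1
    frames = np.empty((n_saved, len(pos), 3))
    frames[0] = pos
    sqrt2Ddt = np.sqrt(2 * D * config.dt_ps)

    save_i = 1
    for step in range(1, config.n_steps + 1):
        z = pos[:, 2]
        in_pore = np.abs(z) <= Lp / 2
        force = q * E * in_pore  # meV/A along +z for positive V
        for sp, ws in config.wells.items():
            m = species == sp
            if m.any():
                force[m] += _well_force(z[m], ws, kT)
        drift = D * force / kT * config.dt_ps
        noise = sqrt2Ddt[:, None] * rng.standard_normal((len(pos), 3))
        pos = pos + noise
        pos[:, 2] += drift

        # radial reflection at the pore wall
        r2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
        out = r2 > R**2
        if out.any():
            r = np.sqrt(r2[out])
            scale = (2 * R - r) / r
            pos[out, 0] *= scale
            pos[out, 1] *= scale
        # z-periodic wrap into [-L/2, L/2)
        pos[:, 2] = (pos[:, 2] + L / 2) % L - L / 2

        if step % config.stride == 0:
            frames[save_i] = pos
            save_i += 1

    return IonTrajectory(
        positions=frames,
        species=species,
        charges=dict(config.charges),
        dt_ps=config.dt_ps * config.stride,
        box=np.array([2 * R, 2 * R, L]),
        voltage_mV=config.voltage_mV,
        temperature_K=config.temperature_K,
    )


def closed_form_current(config: PoreSimConfig, species: str) -> float:
    """Constant-field Nernst-Planck current (nA) for the generator's dynamics.

    ``I = q e c A v`` with drift ``v = D q E / kT``, concentration
    ``c = n/V`` in ions/A^3 and cross-section ``A = pi r^2``. Exact in steady
    state for a homogeneous system, so it requires no wells and a field that
    spans the whole box (``pore_length == box_length``).
    """
    if config.wells:
        raise ValueError("closed form invalid with potential wells present")
    if config.pore_length != config.box_length:
        raise ValueError("closed form requires a uniform pore (pore_length == box_length)")
    n = config.ion_counts().get(species, 0)
    c = n / config.volume_A3  # ions per A^3
    A = math.pi * config.pore_radius**2
    qe = config.charges[species]
    v = config.diffusion_A2_per_ps[species] * qe * config.field_mV_per_A() / config.kT_meV
    # ions/ps -> A: x e, /1e-12 s; -> nA: x 1e9  => factor e * 1e21
    return qe * c * A * v * 1.602176634e-19 * 1e21


# ---------------------------------------------------------------------------
# Toy pore structures
# ---------------------------------------------------------------------------


def simulate_toy_pore(
    rings: Sequence[tuple[float, float, int]],
    atom_vdw: float = 1.70,
    element: str = "C",
) -> AtomSet:
    """Atoms equally spaced on horizontal circles: ``rings`` is a list of
    (z, ring_radius, n_atoms). The inscribed-sphere radius at a ring plane is
    ``ring_radius - atom_vdw`` (for dense rings), so toy profiles have exact
    expected values.
    """
    coords = []
    for z, radius, n_atoms in rings:
        if radius <= 0:
            raise ValueError("ring radius must be positive")
        if n_atoms < 8:
            raise ValueError("need at least 8 atoms per ring")
        ang = 2 * math.pi * np.arange(n_atoms) / n_atoms
        coords.append(np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                                       np.full(n_atoms, float(z))]))
    xyz = np.vstack(coords)
    return AtomSet(
        coords=xyz,
        vdw=np.full(len(xyz), atom_vdw),
        elements=np.array([element] * len(xyz), dtype=object),
    )


def write_toy_pdb(atoms: AtomSet, path: str | Path) -> Path:
    """Write an AtomSet as a minimal PDB file (ATOM records, one GLY chain)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "toy_pore"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (xyz, el) in enumerate(zip(atoms.coords, atoms.elements), start=1):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA" if el == "C" else str(el)
        atom.element = gemmi.Element(str(el))
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path
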