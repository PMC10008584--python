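"""Classification-metadata bookkeeping for symmetry-expanded gap-junction particles.

A gap-junction channel (GJC) is a dodecamer: two hexameric hemichannels docked
end to end. Subunit-focused 3D classification assigns every symmetry-expanded
copy of a particle (one copy per protomer) a class number, and the class maps to
a conformational state of the N-terminal helix: pore-lining (``PLN``), flexible
(``FN``), or some other label. This module reads and writes the RELION-3.1 STAR
tables that carry those assignments, performs the symmetry-expansion bookkeeping
(D6: 12 copies per particle, C6: 6), and folds expanded records back into
per-particle state compositions.

Conventions
-----------
* particle identity is the string in ``rlnImageName`` (never parsed further);
* ``rot_deg`` is the in-plane symmetry-expansion rotation, one of
  {0, 60, ..., 300} for a clean expansion; ``position_index`` is
  ``round(rot_deg / 60) mod 6`` with ``rot_deg`` reduced into [0, 360);
* ``hemichannel_index`` is 1 iff ``tilt_flipped`` (the copy that views the
  particle from the other membrane, tilt > 90 deg in the STAR file).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gemmi import cif

__all__ = [
    "STATES",
    "ProtomerRecord",
    "ParticleTable",
    "ClassStateMap",
    "ParticleComposition",
    "read_star",
    "write_star",
    "expand_symmetry",
    "assign_states",
    "group_by_particle",
    "select_hetero_junctional",
]

#: Recognised conformational-state labels.
STATES = ("PLN", "FN", "OTHER", "UNASSIGNED")

#: one-letter codes used in ring strings
_STATE_CHAR = {"PLN": "P", "FN": "F", "OTHER": "O", "UNASSIGNED": "U"}

_GROUP_ORDER = {"C1": 1, "C6": 6, "D6": 12}


class StarFormatError(ValueError):
    """Raised when a STAR file is syntactically or structurally invalid."""


@dataclass(frozen=True)
class ProtomerRecord:
    """One symmetry-expanded copy of a particle with its protomer metadata."""

    particle_id: str
    class_id: int
    state: str = "UNASSIGNED"
    rot_deg: float | None = None
    tilt_flipped: bool = False
    hemichannel_index: int | None = None
    position_index: int | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.position_index is not None and self.rot_deg is not None:
            expect = position_from_rot(self.rot_deg)
            if self.position_index != expect:
                raise ValueError(
                    f"position_index {self.position_index} inconsistent with "
                    f"rot_deg {self.rot_deg} (expected {expect})"
                )


def position_from_rot(rot_deg: float) -> int:
    """Position index on the hexameric ring implied by the expansion rotation."""
    return int(round((rot_deg % 360.0) / 60.0)) % 6


@dataclass
class ParticleTable:
    """Ordered collection of protomer records backed by a DataFrame.

    Columns: ``particle_id`` (str), ``class_id`` (int), ``state`` (str),
    ``rot_deg``/``tilt_deg``/``psi_deg`` (float, NaN = unset), ``tilt_flipped``
    (bool), ``hemichannel_index``/``position_index`` (nullable Int64).
    Extra STAR columns survive round trips in ``extra``.
    """

    df: pd.DataFrame
    symmetry_group: str = "C1"
    provenance: str = ""
    optics: pd.DataFrame | None = None
    extra: pd.DataFrame | None = None

    CORE_COLUMNS = (
        "particle_id",
        "class_id",
        "state",
        "rot_deg",
        "tilt_deg",
        "psi_deg",
        "tilt_flipped",
        "hemichannel_index",
        "position_index",
    )

    def __post_init__(self) -> None:
        if self.symmetry_group not in _GROUP_ORDER:
            raise ValueError(f"unknown symmetry group {self.symmetry_group!r}")
        df = self.df.copy()
        for col in self.CORE_COLUMNS:
            if col not in df.columns:
                if col in ("rot_deg", "tilt_deg", "psi_deg"):
                    df[col] = np.nan
                elif col == "tilt_flipped":
                    df[col] = False
                elif col in ("hemichannel_index", "position_index"):
                    df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
                elif col == "state":
                    df[col] = "UNASSIGNED"
                else:
                    raise ValueError(f"missing mandatory column {col!r}")
        df["particle_id"] = df["particle_id"].astype(str)
        df["class_id"] = df["class_id"].astype(int)
        df["hemichannel_index"] = df["hemichannel_index"].astype("Int64")
        df["position_index"] = df["position_index"].astype("Int64")
        bad = ~df["state"].isin(STATES)
        if bad.any():
            raise ValueError(f"unknown state labels: {sorted(df.loc[bad, 'state'].unique())}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def group_order(self) -> int:
        return _GROUP_ORDER[self.symmetry_group]

    def records(self) -> Iterable[ProtomerRecord]:
        for row in self.df.itertuples(index=False):
            yield ProtomerRecord(
                particle_id=row.particle_id,
                class_id=int(row.class_id),
                state=row.state,
                rot_deg=None if pd.isna(row.rot_deg) else float(row.rot_deg),
                tilt_flipped=bool(row.tilt_flipped),
                hemichannel_index=None
                if pd.isna(row.hemichannel_index)
                else int(row.hemichannel_index),
                position_index=None
                if pd.isna(row.position_index)
                else int(row.position_index),
            )

    def state_counts(self) -> dict[str, int]:
        vc = self.df["state"].value_counts()
        return {s: int(vc.get(s, 0)) for s in STATES}

    def particle_multiplicity(self) -> pd.Series:
        """Record count per particle_id (12 for a clean D6 expansion)."""
        return self.df.groupby("particle_id", sort=False).size()


@dataclass(frozen=True)
class ClassStateMap:
    """Mapping from 3D-classification class numbers to conformational states.

    The default reflects a protomer-focused classification into eight classes
    where classes 5, 6 and 8 show the flexible N-terminal helix (FN) and the
    remaining five the pore-lining conformation (PLN).
    """

    mapping: Mapping[int, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("class->state map must contain at least one class")
        for cls, state in self.mapping.items():
            if state not in STATES:
                raise ValueError(f"class {cls} maps to unknown state {state!r}")

    @classmethod
    def from_groups(cls, **groups: Sequence[int]) -> "ClassStateMap":
        """Build from keyword groups, e.g. ``from_groups(FN=[5,6,8], PLN=[1,2,3,4,7])``."""
        mapping: dict[int, str] = {}
        for state, ids in groups.items():
            for cid in ids:
                mapping[int(cid)] = state
        return cls(mapping)

    @classmethod
    def default_protomer_map(cls) -> "ClassStateMap":
        return cls.from_groups(FN=[5, 6, 8], PLN=[1, 2, 3, 4, 7])

    def state_of(self, class_id: int) -> str:
        return self.mapping.get(int(class_id), "UNASSIGNED")


@dataclass
class ParticleComposition:
    """Per-dodecamer state census: counts plus the two positional ring strings.

    ``rings`` holds one length-6 string per hemichannel ordered by
    ``position_index`` using one-letter state codes (P/F/O/U); entries may be
    empty strings when positions were unavailable.
    """

    particle_id: str
    n_pln: int
    n_fn: int
    n_other: int
    n_unassigned: int
    rings: tuple[str, ...]
    complete: bool = True

    @property
    def n_total(self) -> int:
        return self.n_pln + self.n_fn + self.n_other + self.n_unassigned

    @property
    def k_pln(self) -> int:
        return self.n_pln


# ---------------------------------------------------------------------------
# STAR I/O (RELION-3.1 dialect)
# ---------------------------------------------------------------------------

_DEFAULT_OPTICS = pd.DataFrame(
    {
        "rlnOpticsGroupName": ["opticsGroup1"],
        "rlnOpticsGroup": [1],
        "rlnVoltage": [300.0],
        "rlnSphericalAberration": [2.7],
        "rlnAmplitudeContrast": [0.1],
        "rlnImagePixelSize": [1.0],
    }
)

_COL_TO_STAR = {
    "particle_id": "rlnImageName",
    "class_id": "rlnClassNumber",
    "rot_deg": "rlnAngleRot",
    "tilt_deg": "rlnAngleTilt",
    "psi_deg": "rlnAnglePsi",
}


def _block_to_df(block: cif.Block) -> pd.DataFrame:
    data: dict[str, list[str]] = {}
    for item in block:
        if item.loop is not None:
            for tag in item.loop.tags:
                data[tag.lstrip("_")] = list(block.find_loop(tag))
        elif item.pair is not None:
            tag, value = item.pair
            data[tag.lstrip("_")] = [value]
    return pd.DataFrame(data)


def read_star(path: str | Path, block_names: Sequence[str] | None = None) -> ParticleTable:
    """Read a RELION-3.1 particle STAR file into a :class:`ParticleTable`.

    Parameters
    ----------
    path:
        STAR file with at least a particles block containing ``rlnImageName``
        and ``rlnClassNumber``. A ``data_optics`` block is kept if present.
    block_names:
        Optional explicit (optics, particles) block names; by default the
        blocks named ``optics`` and ``particles`` are used, falling back to the
        first block containing ``rlnImageName``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = cif.read_file(str(path))
    except (ValueError, RuntimeError) as exc:  # gemmi reports the line number
        raise StarFormatError(f"malformed STAR file {path}: {exc}") from exc

    optics_block = None
    particles_block = None
    if block_names:
        wanted = set(block_names)
        for block in doc:
            if block.name in wanted:
                if block.find_loop("_rlnImageName"):
                    particles_block = block
                else:
                    optics_block = block
    else:
        for block in doc:
            if block.name == "optics":
                optics_block = block
            elif block.name == "particles" or (
                particles_block is None and block.find_loop("_rlnImageName")
            ):
                particles_block = block
    if particles_block is None:
        raise StarFormatError(f"{path}: no particles block with an rlnImageName column")

    raw = _block_to_df(particles_block)
    for mandatory in ("rlnImageName", "rlnClassNumber"):
        if mandatory not in raw.columns:
            raise StarFormatError(f"{path}: missing mandatory column {mandatory}")

    df = pd.DataFrame({"particle_id": raw["rlnImageName"].astype(str)})
    df["class_id"] = raw["rlnClassNumber"].astype(int)
    for col, tag in (("rot_deg", "rlnAngleRot"), ("tilt_deg", "rlnAngleTilt"),
                     ("psi_deg", "rlnAnglePsi")):
        df[col] = pd.to_numeric(raw[tag], errors="coerce") if tag in raw.columns else np.nan
    df["tilt_flipped"] = df["tilt_deg"].gt(90.0).fillna(False).astype(bool)
    pos = pd.Series(pd.array([pd.NA] * len(df), dtype="Int64"))
    has_rot = df["rot_deg"].notna()
    if has_rot.any():
        pos[has_rot] = (
            (np.round(np.mod(df.loc[has_rot, "rot_deg"], 360.0) / 60.0).astype(int)) % 6
        )
    df["position_index"] = pos.astype("Int64")
    df["hemichannel_index"] = pd.array(df["tilt_flipped"].astype(int), dtype="Int64")

    known = {"rlnImageName", "rlnClassNumber", "rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"}
    extra_cols = [c for c in raw.columns if c not in known]
    extra = raw[extra_cols].copy() if extra_cols else None

    optics = _block_to_df(optics_block) if optics_block is not None else None
    return ParticleTable(
        df=df,
        symmetry_group="C1",
        provenance=f"read_star:{path.name}",
        optics=optics,
        extra=extra,
    )


def _format_value(v: object) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.6f}"
    return str(v)


def write_star(table: ParticleTable, path: str | Path) -> Path:
    """Write a :class:`ParticleTable` as RELION-3.1 STAR (optics + particles)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty particle table")
    path = Path(path)

    optics = table.optics if table.optics is not None else _DEFAULT_OPTICS

    out_cols: dict[str, list[str]] = {}
    for col, tag in _COL_TO_STAR.items():
        series = table.df[col]
        if col in ("rot_deg", "tilt_deg", "psi_deg") and series.isna().all():
            continue
        if col in ("rot_deg", "tilt_deg", "psi_deg"):
            out_cols[tag] = [_format_value(v) for v in series.fillna(0.0)]
        else:
            out_cols[tag] = [_format_value(v) for v in series]
    if table.extra is not None:
        for col in table.extra.columns:
            out_cols["rln" + col if not col.startswith("rln") else col] = [
                str(v) for v in table.extra[col]
            ]

    buf = io.StringIO()
    buf.write("\n# version 30001\n\ndata_optics\n\nloop_\n")
    for i, col in enumerate(optics.columns, start=1):
        buf.write(f"_{col if col.startswith('rln') else 'rln' + col} #{i}\n")
    for row in optics.itertuples(index=False):
        buf.write(" ".join(_format_value(v) for v in row) + "\n")
    buf.write("\n\ndata_particles\n\nloop_\n")
    tags = list(out_cols)
    for i, tag in enumerate(tags, start=1):
        buf.write(f"_{tag} #{i}\n")
    n = len(table)
    cols = [out_cols[t] for t in tags]
    for i in range(n):
        buf.write(" ".join(col[i] for col in cols) + "\n")
    try:
        path.write_text(buf.getvalue())
    except OSError as exc:
        raise OSError(f"cannot write STAR file {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Symmetry expansion and state assignment
# ---------------------------------------------------------------------------

def expand_symmetry(table: ParticleTable, group: str) -> ParticleTable:
    """Replicate each particle under every rotation of its point group.

    D6 produces 12 copies per particle — in-plane rotations {0, 60, ..., 300}
    degrees crossed with the two hemichannel views (``tilt_flipped``); C6
    produces the 6 rotations of a single hemichannel view. The expansion
    rotation is stored in ``rot_deg`` and determines ``position_index``.
    """
    if group not in ("C6", "D6"):
        raise ValueError(f"symmetry group must be C6 or D6, got {group!r}")
    mult = table.particle_multiplicity()
    if (mult > 1).any():
        dup = mult[mult > 1].index[0]
        raise ValueError(
            f"input already expanded: particle {dup!r} appears {mult[dup]} times"
        )

    n = len(table)
    offsets = np.arange(6) * 60.0
    flips = [False, True] if group == "D6" else [False]
    order = len(flips) * 6

    base = table.df
    reps = []
    for flip in flips:
        for off in offsets:
            rep = base.copy()
            rep["rot_deg"] = off
            rep["tilt_flipped"] = flip
            rep["tilt_deg"] = 180.0 if flip else 0.0
            rep["position_index"] = pd.array([int(off // 60)] * n, dtype="Int64")
            rep["hemichannel_index"] = pd.array([int(flip)] * n, dtype="Int64")
            reps.append(rep)
    expanded = pd.concat(reps, ignore_index=True)
    # keep copies of the same particle adjacent, like RELION's expanded tables
    expanded = expanded.sort_values(
        ["particle_id", "hemichannel_index", "position_index"], kind="stable"
    ).reset_index(drop=True)
    assert len(expanded) == order * n
    return ParticleTable(
        df=expanded,
        symmetry_group=group,
        provenance=table.provenance + f"|expand:{group}",
        optics=table.optics,
    )


def assign_states(table: ParticleTable, class_map: ClassStateMap) -> ParticleTable:
    """Set each record's conformational state from its class number.

    Classes absent from the map become ``UNASSIGNED``. Returns a new table;
    per-state counts are available via :meth:`ParticleTable.state_counts`.
    """
    df = table.df.copy()
    mapping = {int(k): v for k, v in class_map.mapping.items()}
    df["state"] = df["class_id"].map(mapping).fillna("UNASSIGNED")
    return ParticleTable(
        df=df,
        symmetry_group=table.symmetry_group,
        provenance=table.provenance + "|states",
        optics=table.optics,
        extra=table.extra,
    )


def group_by_particle(
    table: ParticleTable, on_incomplete: str = "exclude"
) -> tuple[list[ParticleComposition], dict[str, int]]:
    """Fold expanded, state-assigned records into per-particle compositions.

    Duplicate records sharing ``(particle_id, hemichannel_index,
    position_index)`` are removed before counting (their number is reported).
    Particles whose record multiplicity after deduplication differs from the
    symmetry-group order are flagged incomplete and, by default, excluded.

    Returns
    -------
    (compositions, report):
        ``report`` has keys ``n_duplicates_removed``, ``n_incomplete``,
        ``n_complete``.
    """
    if table.symmetry_group not in ("C6", "D6"):
        raise ValueError("group_by_particle requires an expanded (C6/D6) table")
    order = table.group_order
    n_hemi = 2 if table.symmetry_group == "D6" else 1

    df = table.df
    if df["position_index"].isna().any() or df["hemichannel_index"].isna().any():
        raise ValueError(
            "records lack position/hemichannel indices; run expand_symmetry first"
        )

    before = len(df)
    dedup = df.drop_duplicates(
        subset=["particle_id", "hemichannel_index", "position_index"], keep="first"
    )
    n_dup = before - len(dedup)

    mult = dedup.groupby("particle_id", sort=False).size()
    complete_ids = mult.index[mult == order]
    incomplete_ids = mult.index[mult != order]

    sub = dedup[dedup["particle_id"].isin(complete_ids)].sort_values(
        ["particle_id", "hemichannel_index", "position_index"], kind="stable"
    )
    chars = sub["state"].map(_STATE_CHAR).to_numpy()
    ids = sub["particle_id"].to_numpy()[::order]
    grid = chars.reshape(-1, order)

    compositions: list[ParticleComposition] = []
    for pid, row in zip(ids, grid):
        s = "".join(row)
        rings = tuple(s[h * 6 : (h + 1) * 6] for h in range(n_hemi))
        compositions.append(
            ParticleComposition(
                particle_id=str(pid),
                n_pln=s.count("P"),
                n_fn=s.count("F"),
                n_other=s.count("O"),
                n_unassigned=s.count("U"),
                rings=rings,
                complete=True,
            )
        )
    report = {
        "n_duplicates_removed": int(n_dup),
        "n_incomplete": int(len(incomplete_ids)),
        "n_complete": len(compositions),
    }
    if on_incomplete not in ("exclude",):
        raise ValueError("only on_incomplete='exclude' is supported")
    return compositions, report


def _ring_group(ring: str, threshold: int) -> str | None:
    if ring.count("P") >= threshold:
        return "PLN"
    if ring.count("F") >= threshold:
        return "FN"
    return None


def select_hetero_junctional(
    compositions: Iterable[ParticleComposition], threshold: int = 6
) -> list[str]:
    """Particle ids whose two hemichannels belong to different state groups.

    A hemichannel ring is PLN-group (FN-group) when at least ``threshold`` of
    its six protomers are in that state; with the default ``threshold=6`` both
    rings must be uniform. Selection is symmetric under hemichannel swap.
    """
    if not 1 <= threshold <= 6:
        raise ValueError("threshold must be in 1..6")
    if threshold <= 3:
        raise ValueError("threshold <= 3 makes group labels ambiguous")
    selected = []
    for comp in compositions:
        if len(comp.rings) != 2:
            continue
        groups = {_ring_group(r, threshold) for r in comp.rings}
        if groups == {"PLN", "FN"}:
            selected.append(comp.particle_id)
    return selected
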