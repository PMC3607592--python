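"""Structure and trajectory I/O, residue selection, superposition, RMSD/RMSF.

All coordinates are stored in nm.  PDB records (Angstrom, 3 decimals) are
converted on read/write, so a round trip preserves positions to 1e-4 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ANGSTROM_PER_NM

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

# Standard atomic masses (u) by element symbol.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "MG": 24.305,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "FE": 55.845,
    "ZN": 65.38,
    "BR": 79.904,
    "SE": 78.971,
    "I": 126.904,
}

DEFAULT_MASS = 12.011


class PDBParseError(ValueError):
    """Raised for malformed PDB input; message names the offending line."""


def guess_element(atom_name: str, element_field: str = "") -> str:
    """Element symbol from the PDB element column, else from the atom name.

    Without an element column the first alphabetic character of the atom
    name is used, so "CA" (C-alpha) resolves to carbon, not calcium.
    """
    element_field = element_field.strip().upper()
    if element_field and element_field in ATOMIC_MASSES:
        return element_field
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    return ""


@dataclass(frozen=True)
class Atom:
    """A single atom record with residue bookkeeping; position in nm."""

    serial: int
    name: str
    residue_number: int
    residue_name: str
    chain: str
    position: np.ndarray
    element: str = ""
    insertion_code: str = ""
    is_hetatm: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.residue_number < 1:
            raise ValueError(
                f"atom {self.serial}: residue_number must be >= 1, got {self.residue_number}"
            )

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def mass(self) -> float:
        el = self.element or guess_element(self.name)
        return ATOMIC_MASSES.get(el, DEFAULT_MASS)


@dataclass
class Structure:
    """An ordered collection of atoms."""

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("Structure needs at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in nm (a fresh copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match atom count {len(self.atoms)}"
            )
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, label if label is not None else self.label)


@dataclass(frozen=True)
class Selection:
    """An ordered set of indices into ``Structure.atoms``."""

    atom_indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.asarray(self.atom_indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("atom_indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"selection {self.label!r}: duplicate atom indices")
        if idx.size and idx.min() < 0:
            raise ValueError(f"selection {self.label!r}: negative index")
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self) -> int:
        return len(self.atom_indices)

    def validate(self, structure: Structure) -> None:
        if self.atom_indices.size and self.atom_indices.max() >= len(structure):
            raise IndexError(
                f"selection {self.label!r} indexes beyond structure size {len(structure)}"
            )


@dataclass
class Trajectory:
    """Frames of coordinates sharing one topology; times in ps."""

    topology: Structure
    frames: np.ndarray  # (F, N, 3) nm
    times: np.ndarray  # (F,) ps

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (F, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, topology has {len(self.topology)}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times must have one entry per frame")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        res_name = line[17:20].strip()
        chain = line[21:22].strip()
        res_num = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if altloc not in ("", "A"):
        return None  # type: ignore[return-value]  # non-first conformer, skipped by caller
    return Atom(
        serial=serial,
        name=name,
        residue_number=res_num,
        residue_name=res_name,
        chain=chain,
        position=np.array([x, y, z]) / ANGSTROM_PER_NM,
        element=guess_element(name, element),
        insertion_code=icode,
        is_hetatm=line.startswith("HETATM"),
    )


def read_pdb(text: str, label: str = "") -> Structure:
    """Parse PDB text into a Structure (first model only; Angstrom -> nm).

    HETATM records are retained and flagged via ``is_hetatm``; for atoms with
    alternate locations only the blank/'A' conformer is kept.
    """
    if not text.strip():
        raise PDBParseError("empty PDB input")
    atoms: list[Atom] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            if atom is not None:
                atoms.append(atom)
        elif rec == "ENDMDL" and atoms:
            break  # first model only
    if not atoms:
        raise PDBParseError("no ATOM/HETATM records found")
    return Structure(atoms, label=label)


def read_pdb_trajectory(text: str, label: str = "", dt_ps: float = 1.0) -> Trajectory:
    """Parse a multi-model PDB into a Trajectory (one frame per MODEL).

    Timestamps are synthesized as ``i * dt_ps`` since PDB carries none.
    """
    if not text.strip():
        raise PDBParseError("empty PDB input")
    models: list[list[Atom]] = []
    current: list[Atom] = []
    saw_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            current = []
        elif rec == "ENDMDL":
            if current:
                models.append(current)
            current = []
        elif rec in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            if atom is not None:
                current.append(atom)
    if current and (not saw_model or not models):
        models.append(current)
    if not models:
        raise PDBParseError("no models with ATOM records found")
    n = len(models[0])
    for i, m in enumerate(models):
        if len(m) != n:
            raise PDBParseError(f"model {i + 1} has {len(m)} atoms, expected {n}")
    topology = Structure(models[0], label=label)
    frames = np.array([[a.position for a in m] for m in models])
    times = np.arange(len(models), dtype=float) * dt_ps
    return Trajectory(topology, frames, times)


def _format_atom_line(atom: Atom, serial: int, coords_nm: np.ndarray) -> str:
    record = "HETATM" if atom.is_hetatm else "ATOM  "
    name = atom.name
    # conventional PDB name justification: <4 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    x, y, z = coords_nm * ANGSTROM_PER_NM
    return (
        f"{record}{serial:5d} {name_field} {atom.residue_name:<3s} {atom.chain or 'A':1s}"
        f"{atom.residue_number:4d}{atom.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}"
    )


def write_pdb(structure: Structure, coords: np.ndarray | None = None) -> str:
    """Serialize a Structure to PDB text (nm -> Angstrom, 3 decimals)."""
    coords = structure.coords if coords is None else np.asarray(coords, dtype=float)
    lines = [
        _format_atom_line(a, i + 1, coords[i]) for i, a in enumerate(structure.atoms)
    ]
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb_trajectory(traj: Trajectory) -> str:
    """Serialize a Trajectory as a multi-model PDB."""
    blocks = []
    for f in range(traj.n_frames):
        blocks.append(f"MODEL     {f + 1:4d}")
        for i, a in enumerate(traj.topology.atoms):
            blocks.append(_format_atom_line(a, i + 1, traj.frames[f, i]))
        blocks.append("ENDMDL")
    blocks.append("END")
    return "\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# Plain-text XYZ-per-frame trajectory dialect
# ---------------------------------------------------------------------------


def write_xyz_trajectory(traj: Trajectory) -> str:
    """Write frames in the plain-text dialect: per frame a ``natoms time_ps``
    header line followed by one ``x y z`` line per atom (nm)."""
    out = []
    n = len(traj.topology)
    for f in range(traj.n_frames):
        out.append(f"{n} {traj.times[f]:.6f}")
        for i in range(n):
            x, y, z = traj.frames[f, i]
            out.append(f"{x:.9f} {y:.9f} {z:.9f}")
    return "\n".join(out) + "\n"


def read_xyz_trajectory(text: str, topology: Structure) -> Trajectory:
    """Read the plain-text XYZ-per-frame dialect against a known topology."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    frames = []
    times = []
    i = 0
    while i < len(lines):
        header = lines[i].split()
        if len(header) != 2:
            raise ValueError(f"bad frame header at line {i + 1}: {lines[i]!r}")
        natoms = int(header[0])
        if natoms != len(topology):
            raise ValueError(
                f"frame at line {i + 1} has {natoms} atoms, topology has {len(topology)}"
            )
        times.append(float(header[1]))
        block = lines[i + 1 : i + 1 + natoms]
        if len(block) < natoms:
            raise ValueError(f"truncated frame starting at line {i + 1}")
        frames.append([[float(v) for v in ln.split()[:3]] for ln in block])
        i += 1 + natoms
    return Trajectory(topology, np.array(frames), np.array(times))


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------


def select_residues(
    structure: Structure,
    ranges: list[tuple[int, int]],
    backbone_only: bool = False,
    chain: str | None = None,
    label: str = "",
) -> Selection:
    """Select atoms whose residue number falls in any inclusive interval.

    Raises ValueError if any interval selects nothing (guards against
    residue-numbering drift between structures).
    """
    indices: list[int] = []
    taken = set()
    for lo, hi in ranges:
        if hi < lo:
            raise ValueError(f"invalid residue interval ({lo}, {hi})")
        hit = False
        for i, a in enumerate(structure.atoms):
            if chain is not None and a.chain != chain:
                continue
            if lo <= a.residue_number <= hi:
                hit = True
                if backbone_only and not a.is_backbone:
                    continue
                if i not in taken:
                    taken.add(i)
                    indices.append(i)
        if not hit:
            raise ValueError(
                f"residue interval ({lo}, {hi}) selects no atoms"
                + (f" on chain {chain!r}" if chain else "")
            )
    indices.sort()  # preserve file order even with overlapping ranges
    return Selection(np.array(indices, dtype=int), label=label)


# ---------------------------------------------------------------------------
# Geometry: COM, Kabsch, RMSD, RMSF
# ---------------------------------------------------------------------------


def _resolve_frame(frame, topology: Structure | None):
    if isinstance(frame, Structure):
        return frame.coords, frame
    coords = np.asarray(frame, dtype=float)
    return coords, topology


def center_of_mass(
    frame,
    sel: Selection,
    mass_weighted: bool = True,
    topology: Structure | None = None,
) -> np.ndarray:
    """Center of mass (or geometric center) of the selected atoms, nm.

    ``frame`` may be a Structure or an (N, 3) array; arrays need ``topology``
    for mass lookup when ``mass_weighted``.
    """
    coords, topo = _resolve_frame(frame, topology)
    if len(sel) == 0:
        raise ValueError("empty selection")
    pts = coords[sel.atom_indices]
    if not mass_weighted:
        return pts.mean(axis=0)
    if topo is None:
        raise ValueError("mass-weighted COM of a bare coordinate array needs a topology")
    m = topo.masses[sel.atom_indices]
    return (pts * m[:, None]).sum(axis=0) / m.sum()


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Selection | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, transformed)`` where
    ``transformed = mobile @ rotation.T + translation`` minimizes the RMSD
    over the fit atoms.  The rotation is always proper (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        idx = np.arange(len(mobile))
    elif isinstance(fit_indices, Selection):
        idx = fit_indices.atom_indices
    else:
        idx = np.asarray(fit_indices, dtype=int)
    a = mobile[idx]
    b = reference[idx]
    if a.shape != b.shape:
        raise ValueError(f"fit sets differ in shape: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 fit atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(1.0, s[0]):
        raise ValueError("degenerate (collinear) fit set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cb - rot @ ca
    return rot, trans, mobile @ rot.T + trans


def rmsd(
    a: np.ndarray,
    b: np.ndarray,
    sel: Selection | None = None,
    superpose: bool = False,
) -> float:
    """Root-mean-square deviation (nm) over selected atoms, with optional
    Kabsch superposition of ``a`` onto ``b`` over the same selection."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    idx = sel.atom_indices if sel is not None else np.arange(len(a))
    if a[idx].shape != b[idx].shape:
        raise ValueError("coordinate sets differ in shape over the selection")
    if superpose:
        _, _, a = kabsch_superpose(a, b, idx)
    diff = a[idx] - b[idx]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsf(traj: Trajectory, sel: Selection | None = None) -> np.ndarray:
    """Per-atom RMS fluctuation about the time-mean position (nm).

    Frames are assumed pre-aligned; the caller superposes first if needed.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = sel.atom_indices if sel is not None else np.arange(len(traj.topology))
    x = traj.frames[:, idx, :]
    mean = x.mean(axis=0)
    return np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
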