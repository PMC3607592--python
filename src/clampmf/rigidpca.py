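"""Rigid-body principal component analysis of two-domain trajectories.

Internal domain motion is stripped by substituting a Kabsch-fitted rigid
reference for each domain in every frame; the covariance of the remaining
coordinates then isolates interdomain motion, whose leading modes (clamshell,
twisting, rocking) serve as collective variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colvars import ColvarSeries, interdomain_angle
from .structio import (
    Selection,
    Structure,
    Trajectory,
    kabsch_superpose,
    write_pdb_trajectory,
)

MODE_LABELS = ("clamshell", "twisting", "rocking")


@dataclass
class RigidBodyModel:
    """Two rigid domains plus a flexible hinge, with an optional rigid
    reference structure per domain (defaults to the trajectory average)."""

    dom1: Selection
    dom2: Selection
    hinge: Selection
    reference: Structure | None = None

    def __post_init__(self):
        s1 = set(self.dom1.atom_indices.tolist())
        s2 = set(self.dom2.atom_indices.tolist())
        sh = set(self.hinge.atom_indices.tolist())
        if s1 & s2 or s1 & sh or s2 & sh:
            raise ValueError("domain and hinge selections must be disjoint")

    @property
    def all_indices(self) -> np.ndarray:
        return np.sort(
            np.concatenate(
                [self.dom1.atom_indices, self.dom2.atom_indices, self.hinge.atom_indices]
            )
        )


@dataclass
class PCAResult:
    """Eigenmodes of the (stripped, aligned) coordinate covariance.

    Eigenvectors are unit vectors in the 3N-space of the analyzed atoms,
    sorted by descending eigenvalue (nm^2).
    """

    mean_coordinates: np.ndarray  # (n_used, 3)
    eigenvectors: np.ndarray  # (n_modes, 3 * n_used)
    eigenvalues: np.ndarray  # (n_modes,) descending
    mode_labels: list[str]
    atom_indices: np.ndarray  # indices into the topology
    align_indices: np.ndarray  # indices into the used-atom arrays
    align_reference: np.ndarray  # (n_used, 3) coords frames are fitted onto

    def __post_init__(self):
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(lam) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(lam < -1e-10):
            raise ValueError("eigenvalues must be non-negative")

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def total_variance(self) -> float:
        return float(np.sum(self.eigenvalues))


def make_average_reference(traj: Trajectory, model: RigidBodyModel) -> Structure:
    """Per-domain time-averaged rigid reference.

    Each frame's domain is superposed onto the first frame's before
    averaging, so the average reflects internal structure only.
    """
    coords = traj.frames[0].copy()
    for sel in (model.dom1, model.dom2):
        idx = sel.atom_indices
        anchor = traj.frames[0][idx]
        acc = np.zeros_like(anchor)
        for f in range(traj.n_frames):
            _, _, fitted = kabsch_superpose(traj.frames[f][idx], anchor)
            acc += fitted
        coords[idx] = acc / traj.n_frames
    hinge_idx = model.hinge.atom_indices
    coords[hinge_idx] = traj.frames[:, hinge_idx, :].mean(axis=0)
    return traj.topology.with_coords(coords, label="average_reference")


def strip_internal_motion(traj: Trajectory, model: RigidBodyModel) -> Trajectory:
    """Replace each domain in every frame by its Kabsch-fitted rigid
    reference; hinge atoms pass through unchanged."""
    ref = model.reference if model.reference is not None else make_average_reference(traj, model)
    ref_coords = ref.coords
    out = traj.frames.copy()
    for dom_name, sel in (("domain1", model.dom1), ("domain2", model.dom2)):
        idx = sel.atom_indices
        if idx.max() >= ref_coords.shape[0]:
            raise ValueError(f"reference does not contain all atoms of {dom_name}")
        ref_dom = ref_coords[idx]
        for f in range(traj.n_frames):
            try:
                _, _, fitted = kabsch_superpose(ref_dom, traj.frames[f][idx])
            except ValueError as exc:
                raise ValueError(f"frame {f}, {dom_name}: {exc}") from exc
            out[f][idx] = fitted
    return Trajectory(traj.topology, out, traj.times.copy())


def _align_frames(
    frames: np.ndarray, reference: np.ndarray, align_idx: np.ndarray
) -> np.ndarray:
    aligned = np.empty_like(frames)
    for f in range(frames.shape[0]):
        _, _, aligned[f] = kabsch_superpose(frames[f], reference, align_idx)
    return aligned


def rigid_pca(
    traj: Trajectory,
    model: RigidBodyModel,
    align_sel: Selection | None = None,
    backbone_only: bool = True,
    strip_internal: bool = False,
    angle_sign_convention: bool = True,
) -> PCAResult:
    """Diagonalize the covariance of the globally aligned coordinates.

    Frames are superposed on ``align_sel`` (default: domain 1) to remove
    overall rotation/translation.  The analysis runs on backbone atoms of
    dom1 + dom2 + hinge unless ``backbone_only`` is False.  Set
    ``strip_internal`` to compose ``strip_internal_motion`` first.

    Sign convention: mode 1 is oriented so its projection increases with the
    interdomain angle; other modes are positive on their largest-magnitude
    component.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if strip_internal:
        traj = strip_internal_motion(traj, model)
    used = model.all_indices
    if backbone_only:
        bb = np.array([traj.topology.atoms[i].is_backbone for i in used])
        used = used[bb]
    if used.size == 0:
        raise ValueError("no atoms to analyze (backbone filter removed everything?)")
    align_src = align_sel.atom_indices if align_sel is not None else model.dom1.atom_indices
    pos = {int(a): i for i, a in enumerate(used)}
    align_idx = np.array([pos[int(a)] for a in align_src if int(a) in pos], dtype=int)
    if align_idx.size < 3:
        raise ValueError("alignment selection covers fewer than 3 analyzed atoms")

    frames = traj.frames[:, used, :]
    # two-pass alignment: first onto frame 0, then onto the resulting mean
    aligned = _align_frames(frames, frames[0], align_idx)
    mean = aligned.mean(axis=0)
    aligned = _align_frames(frames, mean, align_idx)
    mean = aligned.mean(axis=0)

    x = (aligned - mean).reshape(traj.n_frames, -1)
    cov = (x.T @ x) / traj.n_frames
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order].T  # (n_modes, 3N)

    # deterministic sign: positive largest-magnitude component
    for m in range(vec.shape[0]):
        i = int(np.argmax(np.abs(vec[m])))
        if vec[m, i] < 0:
            vec[m] = -vec[m]

    labels = [
        MODE_LABELS[m] if m < len(MODE_LABELS) else f"mode{m + 1}" for m in range(len(lam))
    ]
    result = PCAResult(
        mean_coordinates=mean,
        eigenvectors=vec,
        eigenvalues=lam,
        mode_labels=labels,
        atom_indices=used,
        align_indices=align_idx,
        align_reference=mean.copy(),
    )
    if angle_sign_convention and lam[0] > 0:
        try:
            angles = np.array(
                [
                    interdomain_angle(
                        traj.frames[f], model.dom1, model.dom2, model.hinge,
                        topology=traj.topology,
                    )
                    for f in range(traj.n_frames)
                ]
            )
            proj = x @ vec[0]
            if np.std(angles) > 0 and np.corrcoef(proj, angles)[0, 1] < 0:
                result.eigenvectors[0] = -result.eigenvectors[0]
        except ValueError:
            pass  # degenerate geometry; keep component convention
    return result


def project_onto_modes(
    traj: Trajectory, pca: PCAResult, n_modes: int
) -> list[ColvarSeries]:
    """Per-frame projections (nm along the unit 3N-modes) after the same
    global alignment used when the PCA was computed."""
    if n_modes > pca.n_modes:
        raise ValueError(f"requested {n_modes} modes, only {pca.n_modes} available")
    if pca.atom_indices.max() >= traj.frames.shape[1]:
        raise ValueError("trajectory topology does not match the PCA result")
    frames = traj.frames[:, pca.atom_indices, :]
    aligned = _align_frames(frames, pca.align_reference, pca.align_indices)
    x = (aligned - pca.mean_coordinates).reshape(traj.n_frames, -1)
    out = []
    for m in range(n_modes):
        out.append(
            ColvarSeries(pca.mode_labels[m], traj.times.copy(), x @ pca.eigenvectors[m])
        )
    return out


def export_mode_arrows(
    pca: PCAResult, topology: Structure, mode: int, scale: float
) -> tuple[Structure, Structure]:
    """Structures displaced +-scale (nm) along a unit mode, for visualization
    as a 2-model PDB."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not 0 <= mode < pca.n_modes:
        raise ValueError(f"mode index {mode} out of range")
    disp = scale * pca.eigenvectors[mode].reshape(-1, 3)
    atoms = [topology.atoms[i] for i in pca.atom_indices]
    sub = Structure(list(atoms), label=f"mode{mode + 1}")
    plus = sub.with_coords(pca.mean_coordinates + disp, label=f"mode{mode + 1}+")
    minus = sub.with_coords(pca.mean_coordinates - disp, label=f"mode{mode + 1}-")
    return plus, minus


def write_mode_arrows_pdb(pca: PCAResult, topology: Structure, mode: int, scale: float) -> str:
    plus, minus = export_mode_arrows(pca, topology, mode, scale)
    traj = Trajectory(
        plus,
        np.stack([plus.coords, minus.coords]),
        np.array([0.0, 1.0]),
    )
    return write_pdb_trajectory(traj)


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------


def write_pca(pca: PCAResult) -> str:
    """Eigenvalues block, then one eigenvector block per mode (3 columns per
    atom row), then mean coordinates and bookkeeping indices."""
    lines = ["# rigid-body PCA result"]
    lines.append("# eigenvalues (nm^2)")
    lines.append(" ".join(f"{v:.10g}" for v in pca.eigenvalues))
    lines.append("# atom_indices")
    lines.append(" ".join(str(int(i)) for i in pca.atom_indices))
    lines.append("# align_indices")
    lines.append(" ".join(str(int(i)) for i in pca.align_indices))
    lines.append("# mean_coordinates")
    for row in pca.mean_coordinates:
        lines.append(" ".join(f"{v:.10g}" for v in row))
    for m in range(pca.n_modes):
        lines.append(f"# eigenvector {m + 1} label={pca.mode_labels[m]}")
        for row in pca.eigenvectors[m].reshape(-1, 3):
            lines.append(" ".join(f"{v:.10g}" for v in row))
    return "\n".join(lines) + "\n"


def read_pca(text: str) -> PCAResult:
    sections: dict[str, list[str]] = {}
    labels = []
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            tag = line.lstrip("#").strip()
            if tag.startswith("eigenvector"):
                parts = tag.split()
                labels.append(parts[2].split("=", 1)[1] if len(parts) > 2 else parts[1])
                current = f"vec{len(labels)}"
            elif tag.split()[0] in ("eigenvalues", "atom_indices", "align_indices", "mean_coordinates"):
                current = tag.split()[0]
            else:
                current = None
            if current is not None:
                sections[current] = []
            continue
        if current is not None:
            sections[current].append(line)
    lam = np.array([float(v) for v in sections["eigenvalues"][0].split()])
    atom_idx = np.array([int(v) for v in sections["atom_indices"][0].split()])
    align_idx = np.array([int(v) for v in sections["align_indices"][0].split()])
    mean = np.array([[float(v) for v in ln.split()] for ln in sections["mean_coordinates"]])
    vecs = []
    for m in range(len(lam)):
        rows = sections[f"vec{m + 1}"]
        vecs.append(np.array([[float(v) for v in ln.split()] for ln in rows]).ravel())
    return PCAResult(
        mean_coordinates=mean,
        eigenvectors=np.array(vecs),
        eigenvalues=lam,
        mode_labels=labels,
        atom_indices=atom_idx,
        align_indices=align_idx,
        align_reference=mean.copy(),
    )
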