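"""Reaction coordinates and interdomain geometry descriptors.

Five collective-variable kinds are supported: pairwise COM distance, a
plane-projected site--ligand distance, the interdomain angle measured at the
hinge center of mass, the signed interdomain torsion, and projections onto
rigid-body PCA modes.  Angles are reported in degrees, distances in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import Selection, Structure, Trajectory, center_of_mass, kabsch_superpose

CV_KINDS = (
    "pair_com_distance",
    "projected_site_distance",
    "interdomain_angle",
    "interdomain_torsion",
    "pca_projection",
)


@dataclass
class ColvarSeries:
    """A named time series of one collective variable."""

    name: str
    times: np.ndarray  # ps
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"series {self.name!r} contains non-finite values")

    def __len__(self) -> int:
        return len(self.times)


def write_series(series: ColvarSeries) -> str:
    """Two-column plain text (time_ps, value) with a '#' header naming the CV."""
    lines = [f"# {series.name}"]
    for t, v in zip(series.times, series.values):
        lines.append(f"{t:.6f} {v:.10g}")
    return "\n".join(lines) + "\n"


def read_series(text: str, name: str | None = None) -> ColvarSeries:
    times, values = [], []
    header = name or "cv"
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped and name is None:
                header = stripped
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"line {lineno}: expected two columns, got {line!r}")
        times.append(float(parts[0]))
        values.append(float(parts[1]))
    if not times:
        raise ValueError("no data rows in series text")
    return ColvarSeries(header, np.array(times), np.array(values))


@dataclass
class ColvarSpec:
    """Declarative CV description: a kind plus the selections/parameters it needs.

    selections keys by kind:
      pair_com_distance        -- "a", "b"
      projected_site_distance  -- "ligand", "site"
      interdomain_angle        -- "dom1", "dom2", "hinge"
      interdomain_torsion      -- "dom1", "hinge_top", "hinge_bottom", "dom2"
      pca_projection           -- none (params carry "pca" and "mode")
    """

    kind: str
    selections: dict[str, Selection] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if self.kind not in CV_KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}; expected one of {CV_KINDS}")
        for key, sel in self.selections.items():
            if len(sel) == 0:
                raise ValueError(f"selection {key!r} of CV {self.kind} is empty")
        if not self.name:
            self.name = self.kind


# ---------------------------------------------------------------------------
# Per-frame evaluators
# ---------------------------------------------------------------------------


def pair_com_distance(
    frame,
    sel_a: Selection,
    sel_b: Selection,
    mass_weighted: bool = True,
    topology: Structure | None = None,
) -> float:
    """Euclidean distance between the two selection COMs, nm."""
    ca = center_of_mass(frame, sel_a, mass_weighted, topology)
    cb = center_of_mass(frame, sel_b, mass_weighted, topology)
    return float(np.linalg.norm(ca - cb))


def projected_site_distance(
    frame,
    ligand_sel: Selection,
    site_sel: Selection,
    plane_normal=(0.0, 0.0, 1.0),
    mass_weighted: bool = True,
    topology: Structure | None = None,
    reference: np.ndarray | None = None,
) -> float:
    """Ligand-COM to site-COM distance after projecting onto the plane
    orthogonal to ``plane_normal`` (default z: domains stacked along z).

    If ``reference`` coordinates are given, the frame is first superposed onto
    them over the site selection, emulating removal of receptor rotation and
    translation before the projection is taken.
    """
    n = np.asarray(plane_normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValueError("plane normal must be non-zero")
    n = n / nn
    if isinstance(frame, Structure):
        topology = frame
        coords = frame.coords
    else:
        coords = np.asarray(frame, dtype=float)
    if reference is not None:
        _, _, coords = kabsch_superpose(coords, np.asarray(reference, float), site_sel)
    cl = center_of_mass(coords, ligand_sel, mass_weighted, topology)
    cs = center_of_mass(coords, site_sel, mass_weighted, topology)
    d = cl - cs
    d_in_plane = d - np.dot(d, n) * n
    return float(np.linalg.norm(d_in_plane))


def interdomain_angle(
    frame,
    dom1: Selection,
    dom2: Selection,
    hinge: Selection,
    mass_weighted: bool = True,
    topology: Structure | None = None,
) -> float:
    """Angle (degrees, in [0, 180]) at the hinge COM between the rays to the
    two domain COMs."""
    c1 = center_of_mass(frame, dom1, mass_weighted, topology)
    c2 = center_of_mass(frame, dom2, mass_weighted, topology)
    ch = center_of_mass(frame, hinge, mass_weighted, topology)
    v1 = c1 - ch
    v2 = c2 - ch
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("hinge COM coincides with a domain COM")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, (-180, 180], right-hand rule
    about the p2->p3 axis; cis = 0."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise ValueError("degenerate torsion axis (coincident middle points)")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate torsion (collinear points)")
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def interdomain_torsion(
    frame,
    dom1: Selection,
    hinge_top: Selection,
    hinge_bottom: Selection,
    dom2: Selection,
    mass_weighted: bool = True,
    topology: Structure | None = None,
) -> float:
    """Signed dihedral dom1COM - hingeTopCOM - hingeBottomCOM - dom2COM,
    degrees in (-180, 180]."""
    pts = [
        center_of_mass(frame, s, mass_weighted, topology)
        for s in (dom1, hinge_top, hinge_bottom, dom2)
    ]
    return dihedral(*pts)


# ---------------------------------------------------------------------------
# Trajectory evaluation
# ---------------------------------------------------------------------------


def evaluate_frame(frame, spec: ColvarSpec, topology: Structure | None = None) -> float:
    s = spec.selections
    p = spec.params
    mw = p.get("mass_weighted", True)
    if spec.kind == "pair_com_distance":
        return pair_com_distance(frame, s["a"], s["b"], mw, topology)
    if spec.kind == "projected_site_distance":
        return projected_site_distance(
            frame,
            s["ligand"],
            s["site"],
            p.get("plane_normal", (0.0, 0.0, 1.0)),
            mw,
            topology,
            p.get("reference"),
        )
    if spec.kind == "interdomain_angle":
        return interdomain_angle(frame, s["dom1"], s["dom2"], s["hinge"], mw, topology)
    if spec.kind == "interdomain_torsion":
        return interdomain_torsion(
            frame, s["dom1"], s["hinge_top"], s["hinge_bottom"], s["dom2"], mw, topology
        )
    raise ValueError(f"kind {spec.kind!r} is not a per-frame CV")


def colvar_timeseries(traj: Trajectory, spec: ColvarSpec) -> ColvarSeries:
    """Evaluate a CV on every frame; times are copied from the trajectory."""
    if spec.kind == "pca_projection":
        from .rigidpca import project_onto_modes

        pca = spec.params["pca"]
        mode = spec.params.get("mode", 0)
        series = project_onto_modes(traj, pca, n_modes=mode + 1)[mode]
        return ColvarSeries(spec.name, series.times, series.values)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        try:
            values[f] = evaluate_frame(traj.frames[f], spec, traj.topology)
        except ValueError as exc:
            raise ValueError(f"frame {f}: {exc}") from exc
    return ColvarSeries(spec.name, traj.times.copy(), values)
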