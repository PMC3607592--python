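"""Interpretive layer: PMF features, three-state assignment, and the
two-substep binding free-energy combination.

Sign convention, stated explicitly in every report: substep free energies
are positive costs of the unbinding-direction steps (receptor opening,
ligand dissociation); binding free energies are their negated sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .structio import Selection, Structure, rmsd
from .wham import PMFCurve, pmf_value_at

STATE_LABELS = ("closed", "half_closed", "open")


@dataclass
class StateReference:
    """A labelled reference structure for RMSD-based state assignment."""

    label: str
    reference: Structure
    source: str = ""

    def __post_init__(self):
        if self.label not in STATE_LABELS:
            raise ValueError(f"label must be one of {STATE_LABELS}, got {self.label!r}")


@dataclass
class PMFMinimum:
    position: float  # nm
    delta_g: float  # kcal/mol relative to the global minimum


@dataclass
class PMFBarrier:
    position: float
    height: float  # kcal/mol relative to the global minimum


@dataclass
class Plateau:
    interval: tuple[float, float]
    mean_delta_g: float


@dataclass
class PMFFeatureSet:
    """Minima, the barriers between adjacent minima, and flat plateaus."""

    minima: list[PMFMinimum]
    barriers: list[PMFBarrier]
    plateaus: list[Plateau]

    def __post_init__(self):
        pos = [m.position for m in self.minima]
        if pos != sorted(pos):
            raise ValueError("minima must be sorted by position")
        for b, (m1, m2) in zip(self.barriers, zip(self.minima, self.minima[1:])):
            if not m1.position <= b.position <= m2.position:
                raise ValueError("each barrier must lie between its flanking minima")


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    sm = np.convolve(padded, kernel, mode="same")
    return sm[pad : pad + len(y)] if pad else sm


def find_pmf_features(
    pmf: PMFCurve,
    smoothing_window: int = 1,
    min_prominence: float = 0.5,
    plateau_slope: float = 2.0,
    min_plateau_bins: int = 3,
) -> PMFFeatureSet:
    """Locate local minima (prominence-filtered, after moving-average
    smoothing), the maxima between adjacent minima, and plateau intervals
    where |dG/dx| stays below ``plateau_slope`` kcal/mol/nm.

    Boundary minima (monotone edges) are detected as well.
    """
    mask = pmf.mask
    x = pmf.bin_centers[mask]
    g = pmf.free_energy[mask]
    if len(g) < 5:
        raise ValueError("PMF needs at least 5 populated bins")
    gs = _moving_average(g, smoothing_window)
    peaks, _ = find_peaks(-gs, prominence=min_prominence)
    found = set(int(p) for p in peaks)
    # boundary minima: monotone edges with a prominent rise away from them
    if gs[0] < gs[1] and gs.max() - gs[0] >= min_prominence:
        found.add(0)
    if gs[-1] < gs[-2] and gs.max() - gs[-1] >= min_prominence:
        found.add(len(gs) - 1)
    idx = np.array(sorted(found), dtype=int)
    if idx.size == 0:
        raise ValueError(
            "no minima found; lower min_prominence or check the PMF range"
        )
    minima = [PMFMinimum(float(x[i]), float(gs[i] - gs.min())) for i in idx]
    barriers = []
    for a, b in zip(idx[:-1], idx[1:]):
        j = a + int(np.argmax(gs[a : b + 1]))
        barriers.append(PMFBarrier(float(x[j]), float(gs[j] - gs.min())))
    # plateaus: maximal runs of small |slope|
    slope = np.gradient(gs, x)
    flat = np.abs(slope) < plateau_slope
    plateaus = []
    start = None
    for i in range(len(flat) + 1):
        if i < len(flat) and flat[i]:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_plateau_bins:
                seg = slice(start, i)
                plateaus.append(
                    Plateau(
                        (float(x[seg][0]), float(x[seg][-1])),
                        float(np.mean(gs[seg]) - gs.min()),
                    )
                )
            start = None
    return PMFFeatureSet(minima=minima, barriers=barriers, plateaus=plateaus)


# ---------------------------------------------------------------------------
# State assignment
# ---------------------------------------------------------------------------


def label_from_rmsd_table(table: dict[str, float], tie_tol: float = 1e-6) -> str:
    """Label of the minimal-RMSD reference; exact ties raise rather than
    being broken arbitrarily."""
    if len(table) < 2:
        raise ValueError("need at least 2 reference RMSDs")
    items = sorted(table.items(), key=lambda kv: kv[1])
    if items[1][1] - items[0][1] < tie_tol:
        raise ValueError(
            f"RMSD tie between {items[0][0]!r} and {items[1][0]!r} "
            f"({items[0][1]:.6f} vs {items[1][1]:.6f} nm); use a finer selection"
        )
    return items[0][0]


def assign_state_by_rmsd(
    frame: np.ndarray,
    references: list[StateReference],
    sel: Selection,
) -> tuple[str, dict[str, float]]:
    """Kabsch-fit RMSD of the frame to every reference over a common
    selection; returns the argmin label and the full RMSD table."""
    if len(references) < 2:
        raise ValueError("need at least 2 state references")
    frame = np.asarray(frame, dtype=float)
    table = {}
    for ref in references:
        table[ref.label] = rmsd(frame, ref.reference.coords, sel, superpose=True)
    return label_from_rmsd_table(table), table


# ---------------------------------------------------------------------------
# Endpoint read-off and two-step combination
# ---------------------------------------------------------------------------


def endpoint_delta_g(pmf: PMFCurve, state_a, state_b) -> float:
    """Free-energy difference (b minus a); each state is a position (nearest
    bin) or a declared (lo, hi) plateau interval whose mean is used."""
    return pmf_value_at(pmf, state_b) - pmf_value_at(pmf, state_a)


@dataclass
class BindingFreeEnergyReport:
    """Two-substep binding free-energy combination for one ligand.

    All substep values are positive unbinding-direction costs in kcal/mol;
    ``dg_bind_*`` are the negated totals.  ``dg_combined`` averages the US
    and metadynamics step-I estimates when the latter is available.
    """

    ligand: str
    dg_open_us: float
    dg_dissociate_us: float
    dg_open_metad: float | None = None
    uncertainty_note: str = ""

    @property
    def dg_total_us(self) -> float:
        return self.dg_open_us + self.dg_dissociate_us

    @property
    def dg_bind_us(self) -> float:
        return -self.dg_total_us

    @property
    def dg_combined(self) -> float | None:
        if self.dg_open_metad is None:
            return None
        return 0.5 * (self.dg_open_us + self.dg_open_metad) + self.dg_dissociate_us

    @property
    def dg_bind_combined(self) -> float | None:
        c = self.dg_combined
        return None if c is None else -c

    def rounded(self, decimals: int = 1) -> dict[str, float | None]:
        def r(v):
            return None if v is None else round(v, decimals)

        return {
            "dg_open_us": r(self.dg_open_us),
            "dg_dissociate_us": r(self.dg_dissociate_us),
            "dg_total_us": r(self.dg_total_us),
            "dg_bind_us": r(self.dg_bind_us),
            "dg_open_metad": r(self.dg_open_metad),
            "dg_combined": r(self.dg_combined),
            "dg_bind_combined": r(self.dg_bind_combined),
        }


def combine_two_step(
    dg_open_us: float,
    dg_dissociate_us: float,
    dg_open_metad: float | None = None,
    ligand: str = "",
    uncertainty_note: str = "",
) -> BindingFreeEnergyReport:
    """Combine the two substeps: receptor opening (step I) and ligand
    dissociation from the open receptor (step II).

    dg_total_us = step I (US) + step II (US); dg_combined = mean(step I US,
    step I metadynamics) + step II (US); binding free energies are the
    negations.
    """
    for name, v in (("dg_open_us", dg_open_us), ("dg_dissociate_us", dg_dissociate_us)):
        if v is None:
            raise ValueError(f"{name} is required")
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    return BindingFreeEnergyReport(
        ligand=ligand,
        dg_open_us=float(dg_open_us),
        dg_dissociate_us=float(dg_dissociate_us),
        dg_open_metad=None if dg_open_metad is None else float(dg_open_metad),
        uncertainty_note=uncertainty_note,
    )


def format_report_table(reports: list[BindingFreeEnergyReport]) -> str:
    """Machine-readable table: rows US Step1 / US Step2 / US sum /
    Metadynamics / Combined; one column per ligand.  Values in kcal/mol;
    substeps are positive costs, the binding free energy rows are signed."""
    ligands = [r.ligand or f"ligand{i + 1}" for i, r in enumerate(reports)]
    rows = [
        ("US Step1", [r.dg_open_us for r in reports]),
        ("US Step2", [r.dg_dissociate_us for r in reports]),
        ("US Sum", [r.dg_total_us for r in reports]),
        ("Metadynamics", [r.dg_open_metad for r in reports]),
        ("Combined", [r.dg_combined for r in reports]),
        ("dG_bind (US)", [r.dg_bind_us for r in reports]),
        ("dG_bind (combined)", [r.dg_bind_combined for r in reports]),
    ]
    width = max(len(n) for n, _ in rows) + 2
    head = " " * width + "  ".join(f"{l:>10s}" for l in ligands)
    lines = [head]
    for name, vals in rows:
        cells = "  ".join(
            f"{v:10.2f}" if v is not None else f"{'--':>10s}" for v in vals
        )
        lines.append(f"{name:<{width}s}{cells}")
    lines.append(
        "# convention: substeps are positive unbinding costs; dG_bind rows are negated totals"
    )
    return "\n".join(lines) + "\n"
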