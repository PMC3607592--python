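"""Umbrella-sampling estimator: histograms, WHAM, PMF, convergence checks.

The self-consistent weighted-histogram equations are solved in log space for
numerical stability.  Units throughout: nm, ps, kcal/mol, kcal/mol/nm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import KT_300


@dataclass
class UmbrellaWindow:
    """One biased sampling window: harmonic restraint and its CV samples."""

    center: float  # nm
    force_constant: float  # kcal/mol/nm^2; 0 means an unbiased window
    times: np.ndarray  # ps
    samples: np.ndarray  # nm
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force_constant must be non-negative")
        if self.samples.size < 1:
            raise ValueError(f"window {self.label!r} has no samples")
        if self.times.shape != self.samples.shape:
            raise ValueError("times and samples must have the same length")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def bias(self, x: np.ndarray) -> np.ndarray:
        """Harmonic bias energy w(x) = 1/2 k (x - c)^2, kcal/mol."""
        return 0.5 * self.force_constant * (np.asarray(x) - self.center) ** 2


@dataclass
class Histograms:
    """Per-window counts on a shared half-open bin grid [lo+i*w, lo+(i+1)*w)."""

    edges: np.ndarray  # (B+1,)
    counts: np.ndarray  # (W, B) float
    n_out_of_range: np.ndarray  # (W,)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]


@dataclass
class WhamSolution:
    """Converged per-window free-energy offsets (gauge: f[0] = 0)."""

    offsets: np.ndarray  # (W,) kcal/mol
    log_p: np.ndarray  # (B,) unnormalized log probability; -inf for empty bins
    iterations: int
    residual: float


@dataclass
class PMFCurve:
    """Potential of mean force on the shared bin grid.

    Bins with zero total counts carry NaN free energy and are flagged in
    ``mask`` rather than silently interpolated.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray  # kcal/mol; NaN on empty bins
    bin_width: float
    sample_counts: np.ndarray
    zero_convention: str = "global minimum = 0"

    @property
    def mask(self) -> np.ndarray:
        """True where the PMF is defined."""
        return np.isfinite(self.free_energy)


@dataclass
class ConvergenceReport:
    """Sequential-batch WHAM curves plus overlap diagnostics."""

    batch_pmfs: list[PMFCurve]
    batch_endpoint_dg: np.ndarray | None  # (n_batches,) or None
    max_last_two_deviation: float
    overlap_matrix: np.ndarray
    low_overlap_pairs: list[tuple[int, int, float]]
    monotone_endpoint_drift: bool


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------


def build_histograms(
    windows: list[UmbrellaWindow],
    bin_width: float,
    range_: tuple[float, float],
) -> Histograms:
    """Bin every window's samples on one shared grid.

    Half-open bins: a sample exactly on an interior edge goes to the bin on
    its right; samples outside [lo, hi) are counted per window, not dropped
    silently.
    """
    lo, hi = range_
    if hi <= lo:
        raise ValueError("range upper bound must exceed lower bound")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((len(windows), n_bins))
    oor = np.zeros(len(windows), dtype=int)
    for w, win in enumerate(windows):
        idx = np.floor((win.samples - lo) / bin_width).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        oor[w] = int(np.sum(~ok))
        np.add.at(counts[w], idx[ok], 1.0)
    if counts.sum() == 0:
        raise ValueError("all samples fall outside the requested range")
    return Histograms(edges=edges, counts=counts, n_out_of_range=oor)


def histogram_overlap(hist: Histograms) -> np.ndarray:
    """Pairwise overlap matrix in [0, 1]: sum_j min(p_ij, p_kj) of normalized
    histograms.  Empty histograms overlap 0 with everything."""
    w = hist.n_windows
    totals = hist.counts.sum(axis=1)
    p = np.zeros_like(hist.counts)
    nz = totals > 0
    p[nz] = hist.counts[nz] / totals[nz, None]
    out = np.zeros((w, w))
    for i in range(w):
        for k in range(i, w):
            ov = float(np.minimum(p[i], p[k]).sum())
            out[i, k] = out[k, i] = ov
    return out


def low_overlap_pairs(
    overlap: np.ndarray, windows: list[UmbrellaWindow], threshold: float = 0.05
) -> list[tuple[int, int, float]]:
    """Adjacent window pairs (by center order) whose overlap is below threshold."""
    order = np.argsort([w.center for w in windows])
    flagged = []
    for a, b in zip(order[:-1], order[1:]):
        ov = float(overlap[a, b])
        if ov < threshold:
            flagged.append((int(a), int(b), ov))
    return flagged


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------


def _check_connected(hist: Histograms, windows: list[UmbrellaWindow]) -> None:
    supports = [np.nonzero(hist.counts[w] > 0)[0] for w in range(hist.n_windows)]
    order = np.argsort([w.center for w in windows])
    component = {int(order[0])}
    grew = True
    while grew:
        grew = False
        for w in range(hist.n_windows):
            if w in component:
                continue
            sw = set(supports[w].tolist())
            for c in list(component):
                if sw & set(supports[c].tolist()):
                    component.add(w)
                    grew = True
                    break
    missing = [w for w in range(hist.n_windows) if w not in component]
    if missing:
        centers = sorted(windows[w].center for w in missing)
        raise ValueError(
            "umbrella windows are disconnected: no histogram overlap reaching "
            f"windows centered at {centers}"
        )


def solve_wham(
    hist: Histograms,
    windows: list[UmbrellaWindow],
    kT: float = KT_300,
    tol: float = 1e-7,
    max_iter: int = 100000,
) -> WhamSolution:
    """Iterate the WHAM self-consistency equations to convergence.

    p_j  propto  (sum_i n_ij) / (sum_i N_i exp[(f_i - w_i(x_j)) / kT])
    f_i  =  -kT ln sum_j p_j exp(-w_i(x_j) / kT)

    Offsets are gauge-fixed to f[0] = 0; convergence is max |delta f| < tol.
    """
    if not windows:
        raise ValueError("need at least one window")
    if len(windows) != hist.n_windows:
        raise ValueError("window list and histogram set disagree in size")
    if tol <= 0:
        raise ValueError("tol must be positive")
    _check_connected(hist, windows)
    x = hist.centers
    n_tot = hist.counts.sum(axis=0)  # (B,)
    log_n_tot = np.where(n_tot > 0, np.log(np.maximum(n_tot, 1e-300)), -np.inf)
    n_i = hist.counts.sum(axis=1)  # (W,)
    log_n_i = np.log(np.maximum(n_i, 1e-300))
    w_mat = np.array([w.bias(x) for w in windows])  # (W, B)
    beta_w = w_mat / kT
    f = np.zeros(len(windows))
    residual = np.inf
    for it in range(1, max_iter + 1):
        # log denominator per bin
        log_den = logsumexp(log_n_i[:, None] + (f[:, None] - w_mat) / kT, axis=0)
        log_p = log_n_tot - log_den
        f_new = -kT * logsumexp(log_p[None, :] - beta_w, axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            return WhamSolution(offsets=f, log_p=log_p, iterations=it, residual=residual)
    raise RuntimeError(
        f"WHAM failed to converge after {max_iter} iterations "
        f"(residual {residual:.3e} kcal/mol > tol {tol:g})"
    )


def pmf_from_wham(
    solution: WhamSolution,
    hist: Histograms,
    kT: float = KT_300,
) -> PMFCurve:
    """PMF = -kT ln p on the shared grid, shifted so the global minimum is 0."""
    if hist.counts.sum() == 0:
        raise ValueError("empty histograms")
    g = -kT * solution.log_p
    finite = np.isfinite(g)
    if not finite.any():
        raise ValueError("no populated bins")
    g = g - g[finite].min()
    g[~finite] = np.nan
    return PMFCurve(
        bin_centers=hist.centers.copy(),
        free_energy=g,
        bin_width=hist.bin_width,
        sample_counts=hist.counts.sum(axis=0),
    )


def compute_pmf(
    windows: list[UmbrellaWindow],
    bin_width: float,
    range_: tuple[float, float],
    kT: float = KT_300,
    tol: float = 1e-7,
    max_iter: int = 100000,
) -> PMFCurve:
    """Convenience wrapper: histograms -> WHAM -> PMF."""
    hist = build_histograms(windows, bin_width, range_)
    sol = solve_wham(hist, windows, kT, tol, max_iter)
    return pmf_from_wham(sol, hist, kT)


# ---------------------------------------------------------------------------
# PMF read-off helpers (shared with the state model)
# ---------------------------------------------------------------------------


def pmf_value_at(pmf: PMFCurve, where) -> float:
    """PMF value at a position (nearest bin) or mean over an (lo, hi) interval.

    Intervals with only empty bins raise rather than guessing.
    """
    g = pmf.free_energy
    x = pmf.bin_centers
    if np.isscalar(where):
        i = int(np.argmin(np.abs(x - where)))
        if not np.isfinite(g[i]):
            raise ValueError(f"bin nearest {where} has no samples")
        return float(g[i])
    lo, hi = where
    sel = (x >= lo) & (x <= hi) & np.isfinite(g)
    if not sel.any():
        raise ValueError(f"interval ({lo}, {hi}) contains no populated bins")
    return float(g[sel].mean())


# ---------------------------------------------------------------------------
# Batch convergence
# ---------------------------------------------------------------------------


def _slice_window(win: UmbrellaWindow, b: int, n_batches: int) -> UmbrellaWindow:
    n = win.n_samples
    lo = (b * n) // n_batches
    hi = ((b + 1) * n) // n_batches
    if hi <= lo:
        raise ValueError(f"window {win.label!r}: batch {b} is empty")
    return UmbrellaWindow(
        center=win.center,
        force_constant=win.force_constant,
        times=win.times[lo:hi],
        samples=win.samples[lo:hi],
        label=f"{win.label}/batch{b}",
    )


def batch_convergence(
    windows: list[UmbrellaWindow],
    n_batches: int,
    bin_width: float,
    range_: tuple[float, float],
    kT: float = KT_300,
    endpoints: tuple | None = None,
    overlap_threshold: float = 0.05,
    tol: float = 1e-7,
    max_iter: int = 100000,
    dev_min_counts: int = 50,
) -> ConvergenceReport:
    """Solve WHAM on sequential time slices of every window.

    ``endpoints``, if given, is a pair (state_a, state_b) of positions or
    (lo, hi) plateau intervals; the per-batch endpoint free-energy difference
    b - a is then reported, and a monotone drift across batches is flagged.
    The last-two-batch deviation is measured over bins holding at least
    ``dev_min_counts`` samples in both batches (edge bins are pure noise).
    """
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    full_hist = build_histograms(windows, bin_width, range_)
    overlap = histogram_overlap(full_hist)
    flagged = low_overlap_pairs(overlap, windows, overlap_threshold)
    pmfs = []
    dgs = [] if endpoints is not None else None
    for b in range(n_batches):
        sliced = [_slice_window(w, b, n_batches) for w in windows]
        pmf = compute_pmf(sliced, bin_width, range_, kT, tol, max_iter)
        pmfs.append(pmf)
        if endpoints is not None:
            a, bb = endpoints
            dgs.append(pmf_value_at(pmf, bb) - pmf_value_at(pmf, a))
    g_prev, g_last = pmfs[-2].free_energy, pmfs[-1].free_energy
    both = (
        np.isfinite(g_prev)
        & np.isfinite(g_last)
        & (pmfs[-2].sample_counts >= dev_min_counts)
        & (pmfs[-1].sample_counts >= dev_min_counts)
    )
    max_dev = float(np.max(np.abs(g_prev[both] - g_last[both]))) if both.any() else np.nan
    drift = False
    if dgs is not None and len(dgs) >= 3:
        d = np.diff(dgs)
        drift = bool(np.all(d > 0) or np.all(d < 0))
    return ConvergenceReport(
        batch_pmfs=pmfs,
        batch_endpoint_dg=np.array(dgs) if dgs is not None else None,
        max_last_two_deviation=max_dev,
        overlap_matrix=overlap,
        low_overlap_pairs=flagged,
        monotone_endpoint_drift=drift,
    )


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------


def write_pmf(pmf: PMFCurve) -> str:
    """Three columns: bin center (nm), free energy (kcal/mol), total count."""
    lines = [f"# bin_center_nm dG_kcal_mol count  ({pmf.zero_convention})"]
    for x, g, c in zip(pmf.bin_centers, pmf.free_energy, pmf.sample_counts):
        gtxt = f"{g:.6f}" if np.isfinite(g) else "nan"
        lines.append(f"{x:.6f} {gtxt} {c:.0f}")
    return "\n".join(lines) + "\n"


def read_pmf(text: str) -> PMFCurve:
    xs, gs, cs = [], [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected 3 columns")
        xs.append(float(parts[0]))
        gs.append(float(parts[1]))
        cs.append(float(parts[2]))
    if len(xs) < 2:
        raise ValueError("PMF file needs at least 2 bins")
    xs = np.array(xs)
    return PMFCurve(
        bin_centers=xs,
        free_energy=np.array(gs),
        bin_width=float(xs[1] - xs[0]),
        sample_counts=np.array(cs),
    )


def write_window_series(win: UmbrellaWindow) -> str:
    """Two-column sample series in the colvars dialect, with window metadata
    in the header."""
    lines = [f"# {win.label or 'window'} center={win.center:.6f} k={win.force_constant:.6f}"]
    for t, v in zip(win.times, win.samples):
        lines.append(f"{t:.6f} {v:.10g}")
    return "\n".join(lines) + "\n"


def read_window_series(text: str, center: float, force_constant: float, label: str = "") -> UmbrellaWindow:
    times, samples = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        times.append(float(parts[0]))
        samples.append(float(parts[1]))
    return UmbrellaWindow(center, force_constant, np.array(times), np.array(samples), label)
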