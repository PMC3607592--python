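"""Metadynamics engine and free-energy-surface estimator.

Plain (non-well-tempered) metadynamics with a staged hill schedule: phases of
decreasing hill height mimic protocols that first explore coarsely and then
refine.  The accumulated bias approaches the negative free-energy surface;
the estimator reports both the final-time surface and a trailing time average
to damp deposition ripple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KT_300
from .toysystems import (
    AnalyticPotential,
    BiasForce,
    LangevinParams,
    LangevinResult,
    DOMAIN_GUARD,
)

HILL_CUTOFF_SIGMAS = 5.0


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: h * exp(-sum_d (s_d - c_d)^2 / (2 sigma_d^2))."""

    center: np.ndarray
    height: float  # kcal/mol
    widths: np.ndarray  # per-CV sigma
    deposit_time: float  # ps

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.center, dtype=float))
        w = np.atleast_1d(np.asarray(self.widths, dtype=float))
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "widths", w)
        if self.height <= 0:
            raise ValueError("hill height must be positive")
        if np.any(w <= 0):
            raise ValueError("hill widths must be positive")
        if c.shape != w.shape:
            raise ValueError("center and widths must agree in dimension")


@dataclass(frozen=True)
class HillPhase:
    height: float  # kcal/mol
    stride: float  # ps between depositions
    duration: float | None  # ps; None = open-ended (last phase only)

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("phase hill height must be positive")
        if self.stride <= 0:
            raise ValueError("phase stride must be positive")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("phase duration must be positive")


@dataclass
class HillSchedule:
    """Ordered, non-overlapping deposition phases."""

    phases: list[HillPhase]

    def __post_init__(self):
        for p in self.phases[:-1]:
            if p.duration is None:
                raise ValueError("only the last phase may be open-ended")

    @property
    def is_empty(self) -> bool:
        return not self.phases

    def expected_hill_count(self, total_time: float) -> int:
        """Number of depositions in ``total_time`` ps (hills land at integer
        multiples of the phase stride, measured from the phase start)."""
        count = 0
        t0 = 0.0
        for p in self.phases:
            end = total_time if p.duration is None else min(t0 + p.duration, total_time)
            if end <= t0:
                break
            count += int(np.floor((end - t0) / p.stride + 1e-9))
            t0 = t0 + p.duration if p.duration is not None else total_time
            if t0 >= total_time:
                break
        return count


@dataclass
class HillLedger:
    """Ordered record of all deposited hills (deposition order is stable)."""

    hills: list[Hill] = field(default_factory=list)
    cv_names: list[str] = field(default_factory=lambda: ["cv1"])

    def __post_init__(self):
        times = [h.deposit_time for h in self.hills]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("deposit times must be non-decreasing")
        for h in self.hills:
            if h.center.shape != (self.dimension,):
                raise ValueError("hill dimensionality does not match cv_names")

    @property
    def dimension(self) -> int:
        return len(self.cv_names)

    def __len__(self) -> int:
        return len(self.hills)


def bias_at(ledger: HillLedger, s, t: float) -> float:
    """Accumulated bias V(s, t) in kcal/mol; hills beyond 5 sigma in any
    dimension contribute exactly zero."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if s.shape != (ledger.dimension,):
        raise ValueError(
            f"point has dimension {s.shape[0]}, ledger has {ledger.dimension}"
        )
    total = 0.0
    for h in ledger.hills:
        if h.deposit_time > t:
            break
        z = (s - h.center) / h.widths
        if np.any(np.abs(z) > HILL_CUTOFF_SIGMAS):
            continue
        total += h.height * np.exp(-0.5 * float(np.dot(z, z)))
    return total


def bias_on_grid(ledger: HillLedger, axes: list[np.ndarray], t: float) -> np.ndarray:
    """V(s, t) evaluated on a rectangular grid (vectorized over all hills)."""
    mesh = np.meshgrid(*axes, indexing="ij")
    v = np.zeros(mesh[0].shape)
    for h in ledger.hills:
        if h.deposit_time > t:
            break
        z2 = np.zeros(mesh[0].shape)
        clipped = np.zeros(mesh[0].shape, dtype=bool)
        for d in range(ledger.dimension):
            zd = (mesh[d] - h.center[d]) / h.widths[d]
            clipped |= np.abs(zd) > HILL_CUTOFF_SIGMAS
            z2 += zd * zd
        v += np.where(clipped, 0.0, h.height * np.exp(-0.5 * z2))
    return v


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


class _AccumulatedBias(BiasForce):
    """Live bias used by the integrator: exact hill sums, vectorized."""

    def __init__(self, dimension: int):
        self.dim = dimension
        self.centers = np.empty((0, dimension))
        self.heights = np.empty(0)
        self.inv_w2 = np.empty((0, dimension))

    def add(self, hill: Hill):
        self.centers = np.vstack([self.centers, hill.center])
        self.heights = np.append(self.heights, hill.height)
        self.inv_w2 = np.vstack([self.inv_w2, 1.0 / hill.widths**2])

    def bias_value(self, x, t):
        if not len(self.heights):
            return 0.0
        dx = np.atleast_1d(np.asarray(x, dtype=float)) - self.centers
        z2 = np.sum(dx * dx * self.inv_w2, axis=1)
        keep = z2 <= (HILL_CUTOFF_SIGMAS**2) * self.dim  # conservative prefilter
        e = self.heights[keep] * np.exp(-0.5 * z2[keep])
        return float(e.sum())

    def bias_gradient(self, x, t):
        if not len(self.heights):
            return 0.0 if self.dim == 1 else np.zeros(self.dim)
        xv = np.atleast_1d(np.asarray(x, dtype=float))
        dx = xv - self.centers
        z2 = np.sum(dx * dx * self.inv_w2, axis=1)
        e = self.heights * np.exp(-0.5 * z2)
        # dV/dx_d = -sum_h h e^{-z2/2} (x_d - c_d) / sigma_d^2
        g = -np.sum(e[:, None] * dx * self.inv_w2, axis=0)
        return float(g[0]) if self.dim == 1 else g


@dataclass
class MetadResult:
    trajectory: LangevinResult
    ledger: HillLedger


def run_metadynamics(
    pot: AnalyticPotential,
    schedule: HillSchedule,
    widths,
    params: LangevinParams,
    x0=None,
    cv_names: list[str] | None = None,
) -> MetadResult:
    """Langevin dynamics on U + V(s, t) with hills deposited per the schedule.

    The CV is the coordinate itself.  Hills are deposited at integer
    multiples of the active phase's stride (measured from the phase start),
    at the instantaneous position, with that phase's height.  With an empty
    schedule the run is bitwise identical to ``simulate_langevin`` at the
    same seed.
    """
    d = pot.dimension
    widths = np.atleast_1d(np.asarray(widths, dtype=float))
    if widths.shape == (1,) and d > 1:
        widths = np.full(d, widths[0])
    if widths.shape != (d,):
        raise ValueError("one hill width per CV dimension required")
    if np.any(widths <= 0):
        raise ValueError("hill widths must be positive")
    cv_names = cv_names or [f"cv{i + 1}" for i in range(d)]
    dt = params.timestep
    kT = params.kT
    D = kT / params.friction
    drift = dt / params.friction
    noise_scale = np.sqrt(2.0 * D * dt)
    rng = np.random.default_rng(params.seed)
    total = params.n_equil + params.n_steps
    xi = rng.standard_normal((total, d))
    x = np.zeros(d) if x0 is None else np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    if x.shape != (d,):
        raise ValueError(f"x0 has dimension {x.shape}, potential has {d}")

    # per-phase deposition step counts
    phase_bounds = []  # (start_step, end_step, stride_steps, height)
    t0 = 0.0
    for p in schedule.phases:
        start = int(round(t0 / dt))
        end = total if p.duration is None else min(int(round((t0 + p.duration) / dt)), total)
        stride_steps = max(1, int(round(p.stride / dt)))
        phase_bounds.append((start, end, stride_steps, p.height))
        if p.duration is None:
            t0 = total * dt
            break
        t0 += p.duration

    bias = _AccumulatedBias(d)
    hills: list[Hill] = []
    scalar = d == 1
    times, positions = [], []
    t = 0.0
    for step in range(total):
        if scalar:
            xs = float(x[0])
            g = pot.gradient(xs) + bias.bias_gradient(xs, t)
            x = x - drift * g + noise_scale * xi[step]
        else:
            g = np.asarray(pot.gradient(x), dtype=float) + bias.bias_gradient(x, t)
            x = x - drift * g + noise_scale * xi[step]
        t += dt
        if np.any(np.abs(x) > DOMAIN_GUARD):
            raise RuntimeError(
                f"metadynamics integration diverged at step {step}; use a smaller timestep"
            )
        for start, end, stride_steps, height in phase_bounds:
            if start < step + 1 <= end and (step + 1 - start) % stride_steps == 0:
                hill = Hill(center=x.copy(), height=height, widths=widths, deposit_time=t)
                hills.append(hill)
                bias.add(hill)
                break
        if step >= params.n_equil and (step - params.n_equil) % params.save_stride == 0:
            times.append(t)
            positions.append(x.copy())
    return MetadResult(
        trajectory=LangevinResult(np.array(times), np.array(positions)),
        ledger=HillLedger(hills, cv_names),
    )


# ---------------------------------------------------------------------------
# FES reconstruction and basin analysis
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergySurface:
    """Gridded free-energy estimate; minimum is 0 under the default convention."""

    axes: list[np.ndarray]
    values: np.ndarray  # kcal/mol
    zero_convention: str = "global minimum = 0"

    @property
    def dimension(self) -> int:
        return len(self.axes)


def reconstruct_fes(
    ledger: HillLedger,
    axes: list[np.ndarray] | np.ndarray,
    t_final: float | None = None,
    average_window: float | None = None,
) -> FreeEnergySurface:
    """F(s) = -V(s, t_final), shifted so min F = 0.

    With ``average_window`` (ps), -V is averaged over every deposition epoch
    in [t_final - window, t_final], damping the ripple of plain metadynamics.
    The grid must cover every hill center +- 3 sigma.
    """
    if isinstance(axes, np.ndarray) and axes.ndim == 1:
        axes = [axes]
    axes = [np.asarray(a, dtype=float) for a in axes]
    if len(axes) != ledger.dimension:
        raise ValueError("grid dimensionality does not match ledger")
    if not ledger.hills:
        raise ValueError("empty ledger")
    for d, ax in enumerate(axes):
        lo = min(h.center[d] - 3 * h.widths[d] for h in ledger.hills)
        hi = max(h.center[d] + 3 * h.widths[d] for h in ledger.hills)
        if ax.min() > lo or ax.max() < hi:
            raise ValueError(
                f"grid axis {d} [{ax.min():.3f}, {ax.max():.3f}] does not cover "
                f"hills +- 3 sigma [{lo:.3f}, {hi:.3f}]"
            )
    if t_final is None:
        t_final = ledger.hills[-1].deposit_time
    if average_window is None:
        v = bias_on_grid(ledger, axes, t_final)
        f = -v
    else:
        t_start = t_final - average_window
        base_hills = [h for h in ledger.hills if h.deposit_time <= t_start]
        tail_hills = [h for h in ledger.hills if t_start < h.deposit_time <= t_final]
        v = bias_on_grid(HillLedger(base_hills, ledger.cv_names), axes, t_final) if base_hills else 0.0
        mesh = np.meshgrid(*axes, indexing="ij")
        if np.isscalar(v):
            v = np.zeros(mesh[0].shape)
        acc = np.zeros_like(v)
        count = 0
        for h in tail_hills:
            z2 = np.zeros(v.shape)
            clipped = np.zeros(v.shape, dtype=bool)
            for d in range(ledger.dimension):
                zd = (mesh[d] - h.center[d]) / h.widths[d]
                clipped |= np.abs(zd) > HILL_CUTOFF_SIGMAS
                z2 += zd * zd
            v = v + np.where(clipped, 0.0, h.height * np.exp(-0.5 * z2))
            acc += v
            count += 1
        if count == 0:
            f = -v
        else:
            f = -acc / count
    f = f - f.min()
    return FreeEnergySurface(axes=axes, values=f)


@dataclass
class BasinDeltaG:
    """Basin-integrated and minimum-to-minimum free-energy differences (a - b)."""

    integrated: float
    min_to_min: float


def _basin_mask(fes: FreeEnergySurface, spec) -> np.ndarray:
    """Basin spec: one (lo, hi) pair per dimension."""
    spec = np.atleast_2d(np.asarray(spec, dtype=float))
    if spec.shape != (fes.dimension, 2):
        raise ValueError("basin spec needs one (lo, hi) range per CV dimension")
    mesh = np.meshgrid(*fes.axes, indexing="ij")
    mask = np.ones(mesh[0].shape, dtype=bool)
    for d in range(fes.dimension):
        mask &= (mesh[d] >= spec[d, 0]) & (mesh[d] <= spec[d, 1])
    return mask


def basin_delta_g(
    fes: FreeEnergySurface, basin_a, basin_b, kT: float = KT_300
) -> BasinDeltaG:
    """Free energy of basin A relative to basin B.

    integrated: -kT ln sum_A exp(-F/kT) + kT ln sum_B exp(-F/kT)
    min_to_min: min_A F - min_B F
    """
    ma = _basin_mask(fes, basin_a)
    mb = _basin_mask(fes, basin_b)
    if not ma.any() or not mb.any():
        raise ValueError("basin region contains no grid points")
    fa = fes.values[ma]
    fb = fes.values[mb]
    ga = -kT * np.log(np.sum(np.exp(-fa / kT)))
    gb = -kT * np.log(np.sum(np.exp(-fb / kT)))
    return BasinDeltaG(
        integrated=float(ga - gb),
        min_to_min=float(fa.min() - fb.min()),
    )


def count_transitions(series: np.ndarray, boundary: float, margin: float = 0.0) -> int:
    """Crossings between the regions below boundary-margin and above
    boundary+margin (hysteresis suppresses barrier-top jitter)."""
    series = np.asarray(series, dtype=float)
    state = 0  # -1 low, +1 high
    crossings = 0
    for v in series:
        if v < boundary - margin:
            if state == 1:
                crossings += 1
            state = -1
        elif v > boundary + margin:
            if state == -1:
                crossings += 1
            state = 1
    return crossings


# ---------------------------------------------------------------------------
# HILLS-like plain-text ledger I/O
# ---------------------------------------------------------------------------


def write_hills(ledger: HillLedger) -> str:
    """Columns: time, centers..., sigmas..., height (PLUMED-style ordering)."""
    names = ledger.cv_names
    header = "#! FIELDS time " + " ".join(names) + " " + " ".join(
        f"sigma_{n}" for n in names
    ) + " height"
    lines = [header]
    for h in ledger.hills:
        cols = [f"{h.deposit_time:.6f}"]
        cols += [f"{c:.10g}" for c in h.center]
        cols += [f"{w:.10g}" for w in h.widths]
        cols.append(f"{h.height:.10g}")
        lines.append(" ".join(cols))
    return "\n".join(lines) + "\n"


def read_hills(text: str) -> HillLedger:
    """Parse a HILLS-like file; ragged rows raise with their line number."""
    cv_names: list[str] = []
    hills: list[Hill] = []
    dim = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "FIELDS" in stripped:
                fields = stripped.split()
                fields = fields[fields.index("FIELDS") + 1 :]
                if "time" in fields:
                    fields.remove("time")
                cv_names = [f for f in fields if not f.startswith("sigma") and f != "height"]
                dim = len(cv_names)
            continue
        parts = stripped.split()
        if dim is None:
            # infer: time + d centers + d sigmas + height -> odd count >= 4
            if len(parts) < 4 or len(parts) % 2 != 0:
                raise ValueError(f"line {lineno}: cannot infer column layout")
            dim = (len(parts) - 2) // 2
            cv_names = [f"cv{i + 1}" for i in range(dim)]
        if len(parts) != 2 + 2 * dim:
            raise ValueError(
                f"line {lineno}: expected {2 + 2 * dim} columns, got {len(parts)}"
            )
        try:
            vals = [float(v) for v in parts]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        hills.append(
            Hill(
                center=np.array(vals[1 : 1 + dim]),
                widths=np.array(vals[1 + dim : 1 + 2 * dim]),
                height=vals[-1],
                deposit_time=vals[0],
            )
        )
    if dim is None:
        raise ValueError("no hill rows found")
    return HillLedger(hills, cv_names)


def write_fes(fes: FreeEnergySurface) -> str:
    """Gridded text: axes header then one row per grid point (coords..., F)."""
    lines = [f"# dimension {fes.dimension}  ({fes.zero_convention})"]
    for d, ax in enumerate(fes.axes):
        lines.append(f"# axis {d}: {len(ax)} points from {ax[0]:.6f} to {ax[-1]:.6f}")
    mesh = np.meshgrid(*fes.axes, indexing="ij")
    flat = [m.ravel() for m in mesh]
    vals = fes.values.ravel()
    for i in range(vals.size):
        coords = " ".join(f"{m[i]:.6f}" for m in flat)
        lines.append(f"{coords} {vals[i]:.6f}")
    return "\n".join(lines) + "\n"
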