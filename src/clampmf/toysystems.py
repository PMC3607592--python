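"""Synthetic-data generators standing in for the MD engine.

Provides analytic potentials (harmonic, asymmetric double well, triple well
mimicking a clamshell opening PMF), an overdamped Langevin integrator with
pluggable bias forces, umbrella-sampling dataset generation, and a toy
two-rigid-domain clamshell trajectory generator with planted bend/twist/rock
modes.  Everything is a pure function of its seed.

Units: nm, ps, kcal/mol.  The friction coefficient is interpreted so that
the diffusion constant is D = kT/friction in nm^2/ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import brentq

from .constants import KB_KCAL, DEFAULT_TEMPERATURE
from .colvars import ColvarSeries
from .structio import Atom, Selection, Structure, Trajectory
from .wham import UmbrellaWindow


# ---------------------------------------------------------------------------
# Analytic potentials
# ---------------------------------------------------------------------------


def _horner(coeffs, x):
    """Evaluate a polynomial (descending coefficients) for scalars or arrays."""
    r = coeffs[0] * (x * 0 + 1) if not np.isscalar(x) else coeffs[0]
    for c in coeffs[1:]:
        r = r * x + c
    return r


class AnalyticPotential:
    """Base class: value(x) in kcal/mol, gradient(x) in kcal/mol/nm."""

    dimension: int = 1

    def value(self, x) -> float:
        raise NotImplementedError

    def gradient(self, x) -> np.ndarray:
        raise NotImplementedError

    def gradient_array(self, xs: np.ndarray) -> np.ndarray:
        """Vectorized 1D gradient (used for batched window integration)."""
        return np.array([self.gradient(float(v)) for v in xs])

    def value_array(self, xs: np.ndarray) -> np.ndarray:
        return np.array([self.value(float(v)) for v in xs])

    def check_gradient(self, points, h: float = 1e-6, rtol: float = 1e-5) -> bool:
        """Central-finite-difference consistency check of the gradient."""
        for p in points:
            p = np.atleast_1d(np.asarray(p, dtype=float))
            g = np.atleast_1d(self.gradient(p if self.dimension > 1 else float(p[0])))
            for d in range(self.dimension):
                e = np.zeros(self.dimension)
                e[d] = h
                hi = p + e
                lo = p - e
                if self.dimension == 1:
                    num = (self.value(float(hi[0])) - self.value(float(lo[0]))) / (2 * h)
                else:
                    num = (self.value(hi) - self.value(lo)) / (2 * h)
                scale = max(1.0, abs(num))
                if abs(num - g[d]) > rtol * scale:
                    return False
        return True


class HarmonicPotential(AnalyticPotential):
    """U(x) = 1/2 k (x - x0)^2, isotropic in any dimension."""

    def __init__(self, k: float, x0=0.0, dimension: int = 1):
        if k < 0:
            raise ValueError("force constant must be non-negative")
        self.k = float(k)
        self.dimension = dimension
        self.x0 = np.full(dimension, x0, dtype=float) if np.isscalar(x0) else np.asarray(
            x0, dtype=float
        )

    def value(self, x) -> float:
        if self.dimension == 1 and np.isscalar(x):
            d = x - self.x0[0]
            return 0.5 * self.k * d * d
        d = np.atleast_1d(np.asarray(x, dtype=float)) - self.x0
        return float(0.5 * self.k * np.dot(d, d))

    def gradient(self, x):
        if self.dimension == 1 and np.isscalar(x):
            return self.k * (x - self.x0[0])
        d = np.atleast_1d(np.asarray(x, dtype=float)) - self.x0
        g = self.k * d
        return float(g[0]) if self.dimension == 1 else g

    def gradient_array(self, xs):
        return self.k * (np.asarray(xs, dtype=float) - self.x0[0])

    def value_array(self, xs):
        d = np.asarray(xs, dtype=float) - self.x0[0]
        return 0.5 * self.k * d * d


class PolynomialWellPotential(AnalyticPotential):
    """1D potential whose derivative is k * prod(x - r_i) over planted roots.

    Alternating minima/maxima at the ordered roots allow exact placement of
    well positions, relative depths and barrier heights.
    """

    dimension = 1

    def __init__(self, k: float, roots):
        self.k = float(k)
        self.roots = np.sort(np.asarray(roots, dtype=float))
        deriv = Polynomial([1.0])
        for r in self.roots:
            deriv = deriv * Polynomial([-r, 1.0])
        deriv = deriv * self.k
        self._poly = deriv.integ()
        self._poly = self._poly - self._poly(self.roots[0])  # zero at first minimum
        self._deriv = deriv
        # descending-order coefficient lists for fast Horner evaluation
        self._vc = [float(c) for c in self._poly.coef[::-1]]
        self._gc = [float(c) for c in self._deriv.coef[::-1]]

    def value(self, x) -> float:
        if np.isscalar(x):
            return _horner(self._vc, float(x))
        return float(_horner(self._vc, float(np.atleast_1d(x)[0])))

    def gradient(self, x):
        if np.isscalar(x):
            return _horner(self._gc, float(x))
        return float(_horner(self._gc, float(np.atleast_1d(x)[0])))

    def gradient_array(self, xs):
        return _horner(self._gc, np.asarray(xs, dtype=float))

    def value_array(self, xs):
        return _horner(self._vc, np.asarray(xs, dtype=float))

    @property
    def minima(self) -> np.ndarray:
        return self.roots[::2]

    @property
    def maxima(self) -> np.ndarray:
        return self.roots[1::2]


def double_well(
    x1: float = 0.4,
    x2: float = 1.0,
    barrier: float = 3.0,
    delta: float = 0.0,
) -> PolynomialWellPotential:
    """Quartic double well with minima exactly at x1 < x2, barrier height
    ``barrier`` above the x1 well, and U(x2) - U(x1) = ``delta`` exactly."""
    if not x1 < x2:
        raise ValueError("need x1 < x2")
    if barrier <= 0 or barrier <= delta:
        raise ValueError("barrier must be positive and exceed delta")

    def integ(m):
        p = Polynomial([1.0])
        for r in (x1, m, x2):
            p = p * Polynomial([-r, 1.0])
        q = p.integ()
        return q

    def depth_ratio(m):
        q = integ(m)
        return (q(x2) - q(x1)) / (q(m) - q(x1)) - delta / barrier

    mid = 0.5 * (x1 + x2)
    if abs(delta) < 1e-14:
        m = mid
    else:
        # at the midpoint the wells are degenerate (ratio 0); the barrier
        # shifts toward the shallower well as |delta| grows
        eps = 1e-6 * (x2 - x1)
        lo, hi = (mid, x2 - eps) if delta > 0 else (x1 + eps, mid)
        m = brentq(depth_ratio, lo, hi)
    q = integ(m)
    k = barrier / (q(m) - q(x1))
    return PolynomialWellPotential(k, [x1, m, x2])


class GaussianWellPotential(AnalyticPotential):
    """1D sum of attractive Gaussian wells: U(x) = sum_i -A_i N((x-c_i)/w_i).

    Gentle walls (forces stay modest) with flat plateaus outside the wells,
    mimicking a clamshell-opening PMF whose open state is a plateau rather
    than a steep-walled minimum.
    """

    dimension = 1

    def __init__(self, centers, amplitudes, widths):
        self.centers = np.asarray(centers, dtype=float)
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        self.widths = np.asarray(widths, dtype=float)
        if not (len(self.centers) == len(self.amplitudes) == len(self.widths)):
            raise ValueError("centers, amplitudes and widths must align")
        if np.any(self.amplitudes <= 0) or np.any(self.widths <= 0):
            raise ValueError("well amplitudes and widths must be positive")

    def value(self, x) -> float:
        z = (float(np.atleast_1d(x)[0]) - self.centers) / self.widths
        return float(-np.sum(self.amplitudes * np.exp(-0.5 * z * z)))

    def gradient(self, x):
        xs = float(np.atleast_1d(x)[0])
        z = (xs - self.centers) / self.widths
        e = self.amplitudes * np.exp(-0.5 * z * z)
        return float(np.sum(e * (xs - self.centers) / self.widths**2))

    def gradient_array(self, xs):
        xs = np.asarray(xs, dtype=float)
        z = (xs[:, None] - self.centers) / self.widths
        e = self.amplitudes * np.exp(-0.5 * z * z)
        return np.sum(e * (xs[:, None] - self.centers) / self.widths**2, axis=1)

    def value_array(self, xs):
        xs = np.asarray(xs, dtype=float)
        z = (xs[:, None] - self.centers) / self.widths
        return -np.sum(self.amplitudes * np.exp(-0.5 * z * z), axis=1)

    def _stationary_points(self):
        from scipy.optimize import minimize_scalar

        minima = []
        for c, w in zip(self.centers, self.widths):
            res = minimize_scalar(
                self.value, bounds=(c - w, c + w), method="bounded",
                options={"xatol": 1e-12},
            )
            minima.append(float(res.x))
        maxima = []
        for a, b in zip(minima[:-1], minima[1:]):
            res = minimize_scalar(
                lambda x: -self.value(x), bounds=(a, b), method="bounded",
                options={"xatol": 1e-12},
            )
            maxima.append(float(res.x))
        return np.array(minima), np.array(maxima)

    @property
    def minima(self) -> np.ndarray:
        return self._stationary_points()[0]

    @property
    def maxima(self) -> np.ndarray:
        return self._stationary_points()[1]


def clamshell_triple_well(
    minima=(0.53, 0.76, 1.12),
    depths=(0.0, 1.35, 3.0),
    width: float = 0.07,
    base_depth: float = 6.0,
) -> GaussianWellPotential:
    """Three Gaussian wells calibrated so the potential's actual local minima
    sit exactly at ``minima`` with the requested relative ``depths``.

    ``base_depth`` sets the absolute depth of the first well below the outer
    plateau, which fixes the barrier toward dissociation.  Defaults mimic a
    clamshell PMF with closed/half-closed/open minima near 0.53/0.76/1.12 nm
    and depth spacings of a few kcal/mol.
    """
    m = np.asarray(minima, dtype=float)
    d = np.asarray(depths, dtype=float)
    if np.any(np.diff(m) <= 0):
        raise ValueError("minima must be strictly increasing")
    if d[0] != 0.0:
        raise ValueError("first depth is the reference and must be 0")
    if np.any(d[1:] >= base_depth):
        raise ValueError("base_depth must exceed all relative depths")
    targets = -base_depth + d  # absolute well values
    widths = np.full(len(m), float(width))
    centers = m.copy()
    amps = base_depth - d  # cross-talk-free starting guess
    pot = GaussianWellPotential(centers, amps, widths)
    # fixed point: shift centers so actual minima land on target positions,
    # re-solve amplitudes so values at those minima match the target depths
    for _ in range(60):
        actual = pot.minima
        centers = centers + (m - actual)
        z = (m[:, None] - centers) / widths
        g = np.exp(-0.5 * z * z)  # G[i, j] = well j evaluated at minimum i
        amps = np.linalg.solve(g, -targets)
        if np.any(amps <= 0):
            raise ValueError("triple-well calibration failed; widen the wells")
        pot = GaussianWellPotential(centers, amps, widths)
        if np.max(np.abs(pot.minima - m)) < 1e-10:
            break
    residual = np.abs(pot.value_array(pot.minima) - targets).max()
    if np.max(np.abs(pot.minima - m)) > 1e-8 or residual > 1e-8:
        raise ValueError("triple-well calibration did not converge; adjust parameters")
    return pot


def build_potential(config: dict) -> AnalyticPotential:
    """Construct a potential from a config mapping (CLI/YAML entry point)."""
    cfg = dict(config)
    kind = cfg.pop("kind", None)
    if kind == "harmonic":
        return HarmonicPotential(**cfg)
    if kind == "double_well":
        return double_well(**cfg)
    if kind == "clamshell_triple_well":
        return clamshell_triple_well(**cfg)
    raise ValueError(f"unknown potential kind {kind!r}")


# ---------------------------------------------------------------------------
# Bias forces
# ---------------------------------------------------------------------------


class BiasForce:
    """Contract: bias_value(x, t) kcal/mol and bias_gradient(x, t) kcal/mol/nm."""

    def bias_value(self, x, t: float) -> float:
        raise NotImplementedError

    def bias_gradient(self, x, t: float):
        raise NotImplementedError


class NoBias(BiasForce):
    def bias_value(self, x, t):
        return 0.0

    def bias_gradient(self, x, t):
        return 0.0 if np.isscalar(x) else np.zeros_like(np.asarray(x, dtype=float))


class HarmonicUmbrella(BiasForce):
    """V(x) = 1/2 k (x - center)^2 on a 1D coordinate."""

    def __init__(self, center: float, k: float):
        if k < 0:
            raise ValueError("umbrella force constant must be non-negative")
        self.center = float(center)
        self.k = float(k)

    def bias_value(self, x, t):
        d = (x if np.isscalar(x) else float(np.atleast_1d(x)[0])) - self.center
        return 0.5 * self.k * d * d

    def bias_gradient(self, x, t):
        d = (x if np.isscalar(x) else float(np.atleast_1d(x)[0])) - self.center
        return self.k * d


# ---------------------------------------------------------------------------
# Overdamped Langevin integrator
# ---------------------------------------------------------------------------


@dataclass
class LangevinParams:
    """Parameters for the overdamped (Brownian) integrator.

    ``friction`` sets the diffusion constant D = kT/friction.  The seed is
    mandatory: every run is a pure function of it.
    """

    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0
    timestep: float = 0.002
    n_steps: int = 10000
    seed: int = 0
    save_stride: int = 1
    n_equil: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")
        if self.seed is None:
            raise ValueError("seed must be explicit")

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature


@dataclass
class LangevinResult:
    """Saved positions over time from one Langevin run."""

    times: np.ndarray  # (n_saved,) ps
    positions: np.ndarray  # (n_saved, d)

    @property
    def dimension(self) -> int:
        return self.positions.shape[1]

    def as_series(self, name: str = "x", component: int = 0) -> ColvarSeries:
        return ColvarSeries(name, self.times, self.positions[:, component])


DOMAIN_GUARD = 1e3  # nm; beyond this the integration has diverged


def simulate_langevin(
    pot: AnalyticPotential,
    params: LangevinParams,
    bias: BiasForce | None = None,
    x0=None,
) -> LangevinResult:
    """Overdamped Langevin dynamics on U + V_bias.

    Update: x <- x - (D/kT) grad(U+V) dt + sqrt(2 D dt) xi, D = kT/friction.
    Bit-reproducible for a fixed seed; positions are recorded every
    ``save_stride`` steps starting from the initial point, after discarding
    ``n_equil`` equilibration steps.
    """
    bias = bias or NoBias()
    d = pot.dimension
    kT = params.kT
    D = kT / params.friction
    dt = params.timestep
    drift = dt / params.friction  # = (D/kT) dt
    noise_scale = np.sqrt(2.0 * D * dt)
    rng = np.random.default_rng(params.seed)
    total = params.n_equil + params.n_steps
    stride = params.save_stride
    times, positions = [], []
    if d == 1:
        x = 0.0 if x0 is None else float(np.atleast_1d(x0)[0])
        xi = noise_scale * rng.standard_normal(total)
        t = 0.0
        for step in range(total):
            g = pot.gradient(x) + bias.bias_gradient(x, t)
            x = x - drift * g + xi[step]
            t += dt
            if x > DOMAIN_GUARD or x < -DOMAIN_GUARD:
                raise RuntimeError(
                    f"integration diverged at step {step} (|x| > {DOMAIN_GUARD} nm); "
                    "use a smaller timestep"
                )
            if step >= params.n_equil and (step - params.n_equil) % stride == 0:
                times.append(t)
                positions.append(x)
        return LangevinResult(np.array(times), np.array(positions)[:, None])
    x = np.zeros(d) if x0 is None else np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    if x.shape != (d,):
        raise ValueError(f"x0 has dimension {x.shape}, potential has {d}")
    xi = noise_scale * rng.standard_normal((total, d))
    t = 0.0
    for step in range(total):
        g = np.asarray(pot.gradient(x), dtype=float) + bias.bias_gradient(x, t)
        x = x - drift * g + xi[step]
        t += dt
        if np.any(np.abs(x) > DOMAIN_GUARD):
            raise RuntimeError(
                f"integration diverged at step {step} (|x| > {DOMAIN_GUARD} nm); "
                "use a smaller timestep"
            )
        if step >= params.n_equil and (step - params.n_equil) % stride == 0:
            times.append(t)
            positions.append(x.copy())
    return LangevinResult(np.array(times), np.array(positions))


def window_seed(base_seed: int, index: int) -> int:
    """Deterministic per-window seed stream derived from the base seed."""
    return int(np.random.SeedSequence((base_seed, index)).generate_state(1)[0])


def generate_umbrella_dataset(
    pot: AnalyticPotential,
    centers,
    k: float,
    params: LangevinParams,
) -> list[UmbrellaWindow]:
    """One harmonically biased Langevin run per window center.

    Each window starts at its center with a seed derived deterministically
    from the base seed and the window index.
    """
    centers = np.asarray(centers, dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centers must be sorted and distinct")
    if k <= 0:
        raise ValueError("umbrella force constant must be positive")
    if pot.dimension != 1:
        raise ValueError("umbrella datasets are generated on 1D potentials")
    n_win = len(centers)
    kT = params.kT
    D = kT / params.friction
    dt = params.timestep
    drift = dt / params.friction
    noise_scale = np.sqrt(2.0 * D * dt)
    total = params.n_equil + params.n_steps
    # per-window noise streams, derived deterministically from the base seed
    noise = np.empty((n_win, total))
    for i in range(n_win):
        noise[i] = noise_scale * np.random.default_rng(
            window_seed(params.seed, i)
        ).standard_normal(total)
    x = centers.astype(float).copy()
    t = 0.0
    saved_t, saved_x = [], []
    for step in range(total):
        g = pot.gradient_array(x) + k * (x - centers)
        x = x - drift * g + noise[:, step]
        t += dt
        if np.any(np.abs(x) > DOMAIN_GUARD):
            i = int(np.argmax(np.abs(x)))
            raise RuntimeError(
                f"window {i} (center {centers[i]}): integration diverged at step {step}; "
                "use a smaller timestep"
            )
        if step >= params.n_equil and (step - params.n_equil) % params.save_stride == 0:
            saved_t.append(t)
            saved_x.append(x.copy())
    times = np.array(saved_t)
    samples = np.array(saved_x)  # (n_saved, n_win)
    return [
        UmbrellaWindow(
            center=float(centers[i]),
            force_constant=float(k),
            times=times.copy(),
            samples=samples[:, i].copy(),
            label=f"window_{i}",
        )
        for i in range(n_win)
    ]


# ---------------------------------------------------------------------------
# Toy clamshell structure generator
# ---------------------------------------------------------------------------


@dataclass
class ClamshellToyParams:
    """Geometry and planted-mode parameters for the toy two-domain clamshell.

    The hinge sits at the origin; domain 1 is fixed along +x at distance
    ``arm_length``; domain 2 swings in the xy-plane at the commanded
    interdomain angle.  Bend modulates that angle, twist rotates domain 2
    about its own arm axis, rock tilts it out of plane.  Each planted mode is
    a sinusoid in frame index with a configurable integer cycle count so that
    distinct modes are exactly orthogonal in time.
    """

    atoms_per_domain: int = 20
    hinge_atoms: int = 4
    arm_length: float = 1.5  # nm, hinge -> domain COM
    domain_radius: float = 0.4  # nm, spread of each rigid cloud
    base_angle: float = 112.0  # degrees
    bend_amplitude: float = 0.0  # degrees
    twist_amplitude: float = 0.0  # degrees
    rock_amplitude: float = 0.0  # degrees
    bend_cycles: int = 3
    twist_cycles: int = 5
    rock_cycles: int = 7
    jitter_sigma: float = 0.0  # nm
    angle_schedule: np.ndarray | None = None  # explicit per-frame angles, degrees
    seed: int = 0

    def __post_init__(self):
        for amp in (self.bend_amplitude, self.twist_amplitude, self.rock_amplitude):
            if amp < 0:
                raise ValueError("mode amplitudes must be non-negative")
        if not 0.0 < self.base_angle < 180.0:
            raise ValueError("base angle must lie in (0, 180) degrees")


@dataclass
class ClamshellTrajectory:
    """A generated trajectory plus the ground-truth planted mode time courses."""

    trajectory: Trajectory
    truth: dict[str, np.ndarray]
    dom1_ranges: list[tuple[int, int]]
    dom2_ranges: list[tuple[int, int]]
    hinge_ranges: list[tuple[int, int]]


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer(axis, axis)


def make_clamshell_structure(p: ClamshellToyParams) -> Structure:
    """Reference toy structure at the base angle; one CA pseudo-atom per residue.

    Residue numbering: domain 1 = 1..n, hinge = n+1..n+h, domain 2 follows.
    """
    rng = np.random.default_rng(np.random.SeedSequence((p.seed, 0xC1A)))
    n, h = p.atoms_per_domain, p.hinge_atoms

    def cloud(center, count, radius):
        pts = rng.normal(scale=radius, size=(count, 3))
        pts -= pts.mean(axis=0)  # COM exactly at center
        return pts + center

    theta = np.radians(p.base_angle)
    com1 = np.array([p.arm_length, 0.0, 0.0])
    com2 = p.arm_length * np.array([np.cos(theta), np.sin(theta), 0.0])
    dom1 = cloud(com1, n, p.domain_radius)
    hinge = cloud(np.zeros(3), h, 0.1)
    dom2 = cloud(com2, n, p.domain_radius)
    atoms = []
    resnum = 1
    for block, resname in ((dom1, "DM1"), (hinge, "HNG"), (dom2, "DM2")):
        for pos in block:
            atoms.append(
                Atom(
                    serial=resnum,
                    name="CA",
                    residue_number=resnum,
                    residue_name=resname,
                    chain="A",
                    position=pos,
                    element="C",
                )
            )
            resnum += 1
    return Structure(atoms, label="toy_clamshell")


def clamshell_residue_ranges(p: ClamshellToyParams):
    n, h = p.atoms_per_domain, p.hinge_atoms
    dom1 = [(1, n)]
    hinge = [(n + 1, n + h)]
    dom2 = [(n + h + 1, n + h + n)]
    return dom1, dom2, hinge


def clamshell_frame(
    p: ClamshellToyParams,
    ref_coords: np.ndarray,
    bend: float,
    twist: float,
    rock: float,
) -> np.ndarray:
    """Noise-free toy frame at the given mode displacements (degrees).

    Bend rotates domain 2 about z through the hinge (changing the
    interdomain angle by exactly ``bend``), twist spins it about its own
    hinge->COM arm, rock tilts it about the in-plane axis perpendicular to
    the arm.
    """
    n, h = p.atoms_per_domain, p.hinge_atoms
    idx2 = np.arange(n + h, n + h + n)
    theta0 = np.radians(p.base_angle)
    arm2 = np.array([np.cos(theta0), np.sin(theta0), 0.0])
    rock_axis = np.cross(arm2, np.array([0.0, 0.0, 1.0]))
    coords = ref_coords.copy()
    d2 = coords[idx2]
    com2 = d2.mean(axis=0)
    d2 = (d2 - com2) @ _rotation_about(arm2, twist).T + com2
    r = _rotation_about(np.array([0.0, 0.0, 1.0]), bend) @ _rotation_about(rock_axis, rock)
    coords[idx2] = d2 @ r.T  # rotations about the hinge at the origin
    return coords


def planted_mode_directions(
    p: ClamshellToyParams, delta: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth mode directions and gains at the base geometry.

    Returns ``(directions, gains)``: unit vectors in the 3N-space of all toy
    atoms (rows: bend, twist, rock) and the Cartesian displacement norm per
    degree of each mode, from central finite differences.
    """
    ref = make_clamshell_structure(p).coords
    dirs, gains = [], []
    for mode in range(3):
        args = [0.0, 0.0, 0.0]
        args[mode] = delta
        hi = clamshell_frame(p, ref, *args)
        args[mode] = -delta
        lo = clamshell_frame(p, ref, *args)
        d = (hi - lo).ravel() / (2 * delta)
        norm = np.linalg.norm(d)
        dirs.append(d / norm)
        gains.append(norm)
    return np.array(dirs), np.array(gains)


def generate_clamshell_trajectory(
    p: ClamshellToyParams, n_frames: int, dt_ps: float = 1.0
) -> ClamshellTrajectory:
    """Generate a toy trajectory with planted bend/twist/rock motion.

    Domain 2 is rotated rigidly about the hinge: bend about z (changing the
    interdomain angle exactly), twist about the hinge->domain-2 axis, rock
    about the in-plane axis perpendicular to it.  Internal Gaussian jitter is
    added per atom afterwards.  Ground-truth series are returned in ``truth``
    under keys "angle", "bend", "twist", "rock".
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    ref = make_clamshell_structure(p)
    coords0 = ref.coords
    i = np.arange(n_frames)
    if p.angle_schedule is not None:
        angles = np.asarray(p.angle_schedule, dtype=float)
        if angles.shape != (n_frames,):
            raise ValueError("angle_schedule must have one angle per frame")
        bend = angles - p.base_angle
    else:
        bend = p.bend_amplitude * np.sin(2 * np.pi * p.bend_cycles * i / n_frames)
        angles = p.base_angle + bend
    if np.any(angles <= 0.0) or np.any(angles >= 180.0):
        raise ValueError("commanded angles must stay within (0, 180) degrees")
    twist = p.twist_amplitude * np.sin(2 * np.pi * p.twist_cycles * i / n_frames)
    rock = p.rock_amplitude * np.sin(2 * np.pi * p.rock_cycles * i / n_frames)

    rng = np.random.default_rng(np.random.SeedSequence((p.seed, 0xF0A)))
    frames = np.empty((n_frames, len(ref), 3))
    for f in range(n_frames):
        coords = clamshell_frame(p, coords0, bend[f], twist[f], rock[f])
        if p.jitter_sigma > 0:
            coords = coords + rng.normal(scale=p.jitter_sigma, size=coords.shape)
        frames[f] = coords
    times = np.arange(n_frames, dtype=float) * dt_ps
    dom1_r, dom2_r, hinge_r = clamshell_residue_ranges(p)
    return ClamshellTrajectory(
        trajectory=Trajectory(ref, frames, times),
        truth={"angle": angles, "bend": bend, "twist": twist, "rock": rock},
        dom1_ranges=dom1_r,
        dom2_ranges=dom2_r,
        hinge_ranges=hinge_r,
    )
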