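"""Synthetic trajectories and configurations with known statistics.

The *librator* emulates rigid water molecules reorienting by damped
harmonic angular oscillation (librational modes) superposed on exponential
orientational diffusion, so every pipeline stage can be verified against a
closed-form collective dipole autocorrelation without any external data.

Construction, per molecule (all molecules statistically independent unless
the correlated variant is requested):

* a base orientation performs isotropic rotational diffusion, realized as
  a composition of small random rotations whose per-step mean is tuned so
  the rank-1 orientational correlation is exactly ``exp(-t/tau_r)``;
* two small libration angles about the transverse body axes are stationary
  Gaussian processes with covariance ``sigma_k^2 exp(-gamma_k t)
  cos(omega_k t)`` per mode, realized exactly as
  ``x1(t) cos(omega t) + x2(t) sin(omega t)`` with x1, x2 independent
  Ornstein-Uhlenbeck processes (exact discretization, no integrator drift).

The resulting unit-dipole autocorrelation has the exact closed form

    C1(t) = exp(-t/tau_r) * [S + C(S + C)],
    S = e^{-s} sinh(s rho(t)),  C = e^{-s} cosh(s rho(t)),

with ``s`` the total angular variance per axis and ``rho`` the normalized
mixture of mode covariances.  To leading order in the mode amplitudes
``a_k = 2 sigma_k^2`` this is the familiar
``exp(-t/tau_r) [a_0 + sum_k a_k exp(-gamma_k t) cos(omega_k t)]``; the
exact form is what :class:`AnalyticLibratorACF` evaluates, making it a
sharp oracle at any amplitude.

The correlated variant shares the diffusing base rotation between all
molecules (fixed small per-molecule offsets), producing nonzero
distinct-molecule cross-correlations like a hydrogen-bond network does;
its cross ACF is realization-dependent and is not claimed in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .collective import CorrelationFunction, MolecularDipoleSeries
from .constants import omega_from_wavenumber
from .water_models import (
    MoleculeGeometry,
    RigidTransform,
    WaterModelSpec,
    build_reference_molecule,
    load_model,
    permanent_dipole,
)

__all__ = [
    "LibratorMode",
    "LibratorParams",
    "LibratorTrajectory",
    "AnalyticLibratorACF",
    "ClusterConfig",
    "generate_librator_trajectory",
    "generate_cluster",
    "build_dimer",
    "dipoles_from_positions",
]


@dataclass(frozen=True)
class LibratorMode:
    amplitude: float    # fraction of the t=0 correlation carried by the mode
    wavenumber: float   # mode center, cm^-1
    damping: float      # ps^-1

    @property
    def omega(self) -> float:
        return omega_from_wavenumber(self.wavenumber)


@dataclass(frozen=True)
class LibratorParams:
    n_molecules: int = 8
    box_edge: float = 18.0           # Angstrom
    model: str = "spce"
    modes: tuple[LibratorMode, ...] = (
        LibratorMode(0.10, 200.0, 2.0),
        LibratorMode(0.16, 650.0, 2.5),
    )
    tau_r: float = 8.0               # ps, orientational diffusion time
    dt: float = 0.004                # ps
    n_frames: int = 16384
    seed: int = 0
    correlated: bool = False
    offset_spread: float = 0.35      # rad, correlated variant only

    def validate(self) -> None:
        if sum(m.amplitude for m in self.modes) > 1.0 + 1e-12:
            raise ValueError("mode amplitude fractions must sum to <= 1")
        if any(m.damping <= 0 for m in self.modes) or self.tau_r <= 0 or self.dt <= 0:
            raise ValueError("all rates must be > 0")
        worst = max((m.omega * self.dt for m in self.modes), default=0.0)
        if worst > 0.5:
            raise ValueError(
                f"dt too coarse: max omega*dt = {worst:.3f} > 0.5 (aliasing)"
            )
        if 3.0 * np.exp(-self.dt / self.tau_r) - 1.0 <= 0:
            raise ValueError("dt too coarse for the requested tau_r")


@dataclass
class AnalyticLibratorACF:
    """Exact parametric collective-dipole ACF of the librator process."""

    m2: float                        # <M_D^2> = N mu0^2, D^2
    mu0: float                       # molecular dipole magnitude, D
    tau_r: float
    sigma2: np.ndarray               # per-mode angular variance per axis
    omega: np.ndarray                # rad/ps
    gamma: np.ndarray                # ps^-1

    def unit_acf(self, t: np.ndarray) -> np.ndarray:
        """Normalized single-molecule orientational correlation C1(t)."""
        t = np.asarray(t, float)
        s = float(self.sigma2.sum())
        diff = np.exp(-t / self.tau_r)
        if s == 0.0:
            return diff
        rho = (
            self.sigma2[:, None]
            * np.exp(-np.outer(self.gamma, t))
            * np.cos(np.outer(self.omega, t))
        ).sum(axis=0) / s
        S = np.exp(-s) * np.sinh(s * rho)
        C = np.exp(-s) * np.cosh(s * rho)
        return diff * (S + C * (S + C))

    def collective_acf(self, t: np.ndarray) -> np.ndarray:
        return self.m2 * self.unit_acf(t)

    def correlation(self, dt: float, n_lags: int) -> CorrelationFunction:
        """The exact Phi_D sampled like an estimated correlation function."""
        lags = dt * np.arange(n_lags + 1)
        return CorrelationFunction(
            lags=lags,
            values=self.collective_acf(lags),
            counts=np.ones(n_lags + 1),
            kind="analytic",
        )


@dataclass
class LibratorTrajectory:
    params: LibratorParams
    spec: WaterModelSpec
    times: np.ndarray                  # ps
    dipoles: np.ndarray                # (n_frames, n_molecules, 3), D
    rotations: np.ndarray              # (n_frames, n_molecules, 3, 3)
    centers: np.ndarray                # (n_molecules, 3), A
    descriptor: AnalyticLibratorACF
    site_labels: list[str] = field(default_factory=list)

    def positions(self) -> np.ndarray:
        """Atomic coordinates, shape (n_frames, n_molecules, n_sites, 3) A."""
        ref = build_reference_molecule(self.spec)
        xyz = np.einsum("fmij,sj->fmsi", self.rotations, ref.coords)
        return xyz + self.centers[None, :, None, :]

    def dipole_series(self) -> MolecularDipoleSeries:
        return MolecularDipoleSeries(dt=self.params.dt, permanent=self.dipoles)


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x**2 + z**2), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x**2 + y**2)], -1),
        ],
        axis=-2,
    )


def _axis_angle_rotations(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rodrigues formula, batched; axes (n,3) unit, angles (n,)."""
    c = np.cos(angles)[:, None, None]
    s = np.sin(angles)[:, None, None]
    k = axes
    K = np.zeros((len(axes), 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -k[:, 2], k[:, 1]
    K[:, 1, 0], K[:, 1, 2] = k[:, 2], -k[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -k[:, 1], k[:, 0]
    kk = np.einsum("ni,nj->nij", k, k)
    return c * np.eye(3) + s * K + (1 - c) * kk


def _ou_processes(rng, shape, n_frames, sigma, gamma, dt):
    """Exact stationary OU paths; shape = trailing dims, output (n_frames, *shape)."""
    a = np.exp(-gamma * dt)
    innov = rng.normal(size=(n_frames, *shape))
    innov[0] *= sigma
    innov[1:] *= sigma * np.sqrt(1.0 - a * a)
    return lfilter([1.0], [1.0, -a], innov, axis=0)


def _place_centers(rng, n, box, min_dist, max_attempts=20000):
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"packing failure: placed {len(centers)} of {n} molecules at "
                f"minimum distance {min_dist} A in a {box} A box"
            )
        cand = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
    return np.asarray(centers)


def generate_librator_trajectory(params: LibratorParams) -> LibratorTrajectory:
    """Generate a librator trajectory plus its exact analytic ACF descriptor."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, nf, dt = params.n_molecules, params.n_frames, params.dt
    spec = load_model(params.model)
    mu0 = float(np.linalg.norm(permanent_dipole(build_reference_molecule(spec), spec)))

    # libration angles about the two transverse body axes
    modes = params.modes
    sigma2 = np.array([m.amplitude / 2.0 for m in modes])
    omegas = np.array([m.omega for m in modes])
    gammas = np.array([m.damping for m in modes])
    t = dt * np.arange(nf)
    alpha = np.zeros((nf, n))
    beta = np.zeros((nf, n))
    for s2, om, ga in zip(sigma2, omegas, gammas):
        # x1 cos + x2 sin per axis: stationary Gaussian, ACF s2 e^{-g t} cos(om t)
        x = _ou_processes(rng, (4, n), nf, np.sqrt(s2), ga, dt)
        cos_t, sin_t = np.cos(om * t)[:, None], np.sin(om * t)[:, None]
        alpha += x[:, 0] * cos_t + x[:, 1] * sin_t
        beta += x[:, 2] * cos_t + x[:, 3] * sin_t

    # diffusive base rotation: per-step random rotations tuned so the
    # rank-1 orientational correlation decays exactly as exp(-t/tau_r)
    mean_cos = (3.0 * np.exp(-dt / params.tau_r) - 1.0) / 2.0
    step_var = -2.0 * np.log(mean_cos)
    n_chains = 1 if params.correlated else n
    base = np.empty((nf, n_chains, 3, 3))
    base[0] = _random_rotations(rng, n_chains)
    for f in range(1, nf):
        axes = rng.normal(size=(n_chains, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = rng.normal(scale=np.sqrt(step_var), size=n_chains)
        base[f] = _axis_angle_rotations(axes, angles) @ base[f - 1]
    if params.correlated:
        axes = rng.normal(size=(n, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        offs = _axis_angle_rotations(
            axes, rng.normal(scale=params.offset_spread, size=n)
        )
        base = np.einsum("fcij,njk->fnik", base, offs)

    # R = R_base . R_x(alpha) . R_y(beta); dipole direction u = R z_hat
    ca, sa, cb, sb = np.cos(alpha), np.sin(alpha), np.cos(beta), np.sin(beta)
    zeros, ones = np.zeros_like(ca), np.ones_like(ca)
    r_lib = np.stack(
        [
            np.stack([cb, zeros, sb], -1),
            np.stack([sa * sb, ca, -sa * cb], -1),
            np.stack([-ca * sb, sa, ca * cb], -1),
        ],
        axis=-2,
    )
    rotations = np.einsum("fnij,fnjk->fnik", base, r_lib)
    u = rotations[..., :, 2]  # lab image of the body z axis (bisector)
    dipoles = mu0 * u

    centers = _place_centers(rng, n, params.box_edge, min_dist=2.6)
    descriptor = AnalyticLibratorACF(
        m2=n * mu0**2, mu0=mu0, tau_r=params.tau_r,
        sigma2=sigma2, omega=omegas, gamma=gammas,
    )
    ref = build_reference_molecule(spec)
    return LibratorTrajectory(
        params=params, spec=spec, times=t, dipoles=dipoles,
        rotations=rotations, centers=centers, descriptor=descriptor,
        site_labels=list(ref.labels),
    )


def dipoles_from_positions(positions: np.ndarray, spec: WaterModelSpec,
                           labels: list[str]) -> np.ndarray:
    """Point-charge molecular dipoles (D) from coordinates, vectorized.

    ``positions`` shaped (..., n_sites, 3) with sites ordered as ``labels``.
    Valid for charge-only models (atomic-dipole terms need local frames and
    go through :func:`thzwater.water_models.permanent_dipole`).
    """
    from .constants import EA_TO_DEBYE

    q = np.array([spec.site_charges[lab] for lab in labels])
    if abs(q.sum()) > 1e-10:
        raise ValueError("non-neutral site set gives an origin-dependent dipole")
    return EA_TO_DEBYE * np.einsum("s,...si->...i", q, positions)


# ---------------------------------------------------------------------------
# static configurations

@dataclass(frozen=True)
class ClusterConfig:
    n_molecules: int
    box_edge: float            # Angstrom
    min_oo_distance: float = 2.7
    seed: int = 0
    max_attempts: int = 20000


def generate_cluster(
    config: ClusterConfig, spec: WaterModelSpec
) -> list[MoleculeGeometry]:
    """Random non-overlapping rigid-water placements (open cluster)."""
    rng = np.random.default_rng(config.seed)
    centers = _place_centers(
        rng, config.n_molecules, config.box_edge,
        config.min_oo_distance, config.max_attempts,
    )
    rots = _random_rotations(rng, config.n_molecules)
    return [
        build_reference_molecule(
            spec, RigidTransform(rots[i], centers[i]), molecule_index=i
        )
        for i in range(config.n_molecules)
    ]


def build_dimer(
    r_oo: float,
    spec: WaterModelSpec,
    acceptor_tilt: float = 52.0,
    nonplanar: bool = True,
) -> list[MoleculeGeometry]:
    """Linear hydrogen-bonded water dimer (donor O-H aimed at acceptor O).

    The donor sits at the origin with its H1 on the O-O axis, so the donor
    H1 to acceptor O distance is exactly ``r_oo - r_oh``.  The acceptor
    bisector is tilted by ``acceptor_tilt`` degrees from the axis;
    ``nonplanar`` rotates the acceptor plane 90 degrees out of the donor
    plane (the global-minimum-like geometry class).
    """
    if r_oo <= 2.0:
        raise ValueError("r_oo must exceed 2 A")
    half = np.deg2rad(spec.hoh_angle) / 2.0

    def roty(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    def rotz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

    # donor: R_y(-half) maps the reference H1 = r(sin h, 0, cos h) onto +z
    donor = build_reference_molecule(
        spec, RigidTransform(roty(-half), np.zeros(3)), molecule_index=0
    )
    # acceptor: bisector tilted away from the axis
    tilt = np.deg2rad(180.0 - acceptor_tilt)
    rot = roty(tilt)
    if nonplanar:
        rot = rotz(np.pi / 2.0) @ rot
    acceptor = build_reference_molecule(
        spec, RigidTransform(rot, np.array([0.0, 0.0, r_oo])), molecule_index=1
    )
    return [donor, acceptor]
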