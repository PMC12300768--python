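"""Induced dipoles: Drude displacements and self-consistent point dipoles.

Two routes produce induced dipoles:

* Drude models carry a physical charge pair; the induced dipole is simply
  the Drude charge times the displacement vector (:func:`drude_induced`).
* Point-polarizability models (and post-trajectory polarization of
  non-polarizable trajectories) solve the mutual-induction equations

      mu_i = alpha_i * (E0_i + sum_{j != i} T(r_ij) mu_j)

  self-consistently (:func:`scf_induced_dipoles`), either by damped
  fixed-point iteration or by a direct linear solve of
  ``(I - alpha T) mu = alpha E0``.

Internally fields are in e/A^2 and dipoles in e*A (so ``mu = alpha E`` with
alpha in A^3); results are converted to Debye at the interface.

Same-molecule permanent-field and mutual-induction contributions are
excluded: for a rigid three/four-site water this is the only choice that
leaves an isolated molecule field-free.  The bare dipole tensor diverges at
short range (polarization catastrophe); Thole exponential damping is
available and recommended for dense-liquid configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import EA_TO_DEBYE
from .water_models import (
    MoleculeGeometry,
    WaterModelSpec,
    local_frames,
    molecule_from_coords,
    quadrupole_lab,
)
from .water_models import scale_polarizability  # re-export  # noqa: F401

__all__ = [
    "PolarizationOptions",
    "InducedDipoleSet",
    "PolarizableSystem",
    "PolarizationCatastropheError",
    "drude_induced",
    "dipole_tensor",
    "permanent_field",
    "build_system",
    "scf_induced_dipoles",
    "post_trajectory_polarization",
    "scale_polarizability",
]


class PolarizationCatastropheError(RuntimeError):
    """Mutual induction diverged (alpha*T eigenvalue >= 1 somewhere)."""


@dataclass(frozen=True)
class PolarizationOptions:
    interaction: str = "bare_tensor"      # "bare_tensor" | "thole_damped"
    thole_a: float = 0.39
    solver: str = "fixed_point"           # "fixed_point" | "direct_linear"
    max_iter: int = 200
    mixing: float = 0.7                   # fixed-point damping in (0, 1]
    tol: float = 1e-6                     # convergence tolerance in Debye
    boundary: str = "open_cluster"        # "open_cluster" | "minimum_image"
    box: float | None = None              # cubic box edge, Angstrom
    cutoff: float = 9.0                   # Angstrom (minimum_image only)
    switch_width: float = 1.0             # Angstrom, smooth switch-off width
    field_charges: bool = True
    field_atomic_dipoles: bool = False
    field_atomic_quadrupoles: bool = False

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not (0 < self.mixing <= 1):
            raise ValueError("mixing must be in (0, 1]")
        if self.boundary == "minimum_image":
            if self.box is None:
                raise ValueError("minimum_image boundary requires a box edge")
            if self.cutoff >= self.box / 2 + 1e-9:
                raise ValueError("cutoff must be below half the box edge")


@dataclass
class InducedDipoleSet:
    """Per-site induced dipoles (Debye) with the convergence record."""

    dipoles: np.ndarray          # (n_pol, 3), Debye
    site_molecule: np.ndarray    # (n_pol,) molecule index per polarizable site
    iterations: int
    residual: float              # Debye
    converged: bool

    def per_molecule(self, n_molecules: int) -> np.ndarray:
        out = np.zeros((n_molecules, 3))
        np.add.at(out, self.site_molecule, self.dipoles)
        return out


def drude_induced(host_position, drude_position, q_d: float) -> np.ndarray:
    """Induced dipole of a Drude pair, in Debye.

    ``mu = q_d * d`` with ``d`` the displacement from the fixed particle
    (charge -q_d, at the host position) to the mobile particle (charge
    +q_d).  Zero displacement gives a zero dipole.
    """
    if q_d == 0:
        raise ValueError("Drude charge must be nonzero")
    d = np.asarray(drude_position, float) - np.asarray(host_position, float)
    return EA_TO_DEBYE * q_d * d


def dipole_tensor(
    r_vec: np.ndarray,
    interaction: str = "bare_tensor",
    thole_a: float = 0.39,
    alpha_i: float | None = None,
    alpha_j: float | None = None,
) -> np.ndarray:
    """Dipole-dipole interaction tensor T(r) in A^-3.

    Bare form: ``(3 rr^T / r^2 - I) / r^3`` (symmetric, traceless).  The
    Thole-damped form multiplies the r^-3 and r^-5 terms by the standard
    exponential damping factors with u = a * r / (alpha_i alpha_j)^(1/6).
    """
    r_vec = np.asarray(r_vec, float)
    r = np.linalg.norm(r_vec)
    if r < 1e-6:
        raise ValueError("coincident sites: |r| below 1e-6 A")
    n = r_vec / r
    lam3 = lam5 = 1.0
    if interaction == "thole_damped":
        if alpha_i is None or alpha_j is None:
            raise ValueError("thole damping needs both site polarizabilities")
        au3 = thole_a * (r / (alpha_i * alpha_j) ** (1.0 / 6.0)) ** 3
        lam3 = 1.0 - np.exp(-au3)
        lam5 = 1.0 - (1.0 + au3) * np.exp(-au3)
    elif interaction != "bare_tensor":
        raise ValueError(f"unknown interaction {interaction!r}")
    return (3.0 * lam5 * np.outer(n, n) - lam3 * np.eye(3)) / r**3


# ---------------------------------------------------------------------------
# system assembly

@dataclass
class PolarizableSystem:
    """Flat site arrays of a multi-molecule configuration.

    ``positions`` (n, 3) A; ``charges`` (n,) e; ``molecule`` (n,) int;
    ``alphas`` (n,) A^3 with zero on non-polarizable sites.  Optional
    lab-frame atomic dipoles (e*A) and quadrupoles (e*A^2) act as extra
    permanent field sources.
    """

    positions: np.ndarray
    charges: np.ndarray
    molecule: np.ndarray
    alphas: np.ndarray
    labels: list[str] = field(default_factory=list)
    atomic_dipoles: np.ndarray | None = None      # (n, 3)
    atomic_quadrupoles: np.ndarray | None = None  # (n, 3, 3)

    @property
    def n_sites(self) -> int:
        return len(self.charges)

    @property
    def polarizable(self) -> np.ndarray:
        return self.alphas > 0

    @property
    def n_molecules(self) -> int:
        return int(self.molecule.max()) + 1 if self.n_sites else 0


def build_system(
    molecules: list[MoleculeGeometry],
    spec: WaterModelSpec,
    include_multipoles: bool = True,
) -> PolarizableSystem:
    """Flatten molecule geometries plus a model spec into site arrays."""
    pos, q, mol, alpha, labels = [], [], [], [], []
    dip, quad = [], []
    has_dip = bool(spec.atomic_dipoles)
    has_quad = bool(spec.atomic_quadrupoles)
    for geom in molecules:
        frames = local_frames(geom, spec) if (has_dip or has_quad) else None
        quads = (
            quadrupole_lab(geom, spec) if (has_quad and include_multipoles) else None
        )
        for i, lab in enumerate(geom.labels):
            pos.append(geom.coords[i])
            q.append(spec.site_charges[lab])
            mol.append(geom.molecule_index)
            labels.append(lab)
            alpha.append(spec.polarizable_alpha(lab) or 0.0)
            if has_dip and include_multipoles and lab in spec.atomic_dipoles:
                dip.append(frames[lab].to_lab(spec.atomic_dipoles[lab]) / EA_TO_DEBYE)
            else:
                dip.append(np.zeros(3))
            if quads is not None and lab in quads:
                quad.append(quads[lab] / EA_TO_DEBYE)
            else:
                quad.append(np.zeros((3, 3)))
    return PolarizableSystem(
        positions=np.asarray(pos, float),
        charges=np.asarray(q, float),
        molecule=np.asarray(mol, int),
        alphas=np.asarray(alpha, float),
        labels=labels,
        atomic_dipoles=np.asarray(dip) if (has_dip and include_multipoles) else None,
        atomic_quadrupoles=np.asarray(quad) if quads is not None else None,
    )


def _pair_geometry(targets, sources, options):
    """Displacements target-source with boundary rule; returns (d, r, weight)."""
    d = targets[:, None, :] - sources[None, :, :]
    if options.boundary == "minimum_image":
        d -= options.box * np.round(d / options.box)
    r = np.linalg.norm(d, axis=-1)
    w = np.ones_like(r)
    if options.boundary == "minimum_image":
        rc, width = options.cutoff, options.switch_width
        w = np.where(r >= rc, 0.0, w)
        ramp = (r > rc - width) & (r < rc)
        w = np.where(ramp, 0.5 * (1.0 + np.cos(np.pi * (r - rc + width) / width)), w)
    return d, r, w


def permanent_field(
    system: PolarizableSystem,
    options: PolarizationOptions | None = None,
    target_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Electric field (e/A^2) of permanent sources at the target sites.

    Sums Coulomb fields of all *other* molecules' charges and, when enabled
    in ``options`` and present on the system, point-dipole and traceless
    point-quadrupole fields.  Intramolecular sources are always excluded.
    """
    options = options or PolarizationOptions()
    if target_indices is None:
        target_indices = np.nonzero(system.polarizable)[0]
    targets = system.positions[target_indices]
    d, r, w = _pair_geometry(targets, system.positions, options)
    inter = system.molecule[target_indices][:, None] != system.molecule[None, :]
    active = inter & (w > 0)
    if np.any(r[active] < 1e-6):
        raise ValueError("singular field: overlapping intermolecular sites")
    r_safe = np.where(r < 1e-6, 1.0, r)
    E = np.zeros((len(target_indices), 3))
    mask = (w * active)  # zero for excluded/cut pairs
    if options.field_charges:
        E += np.einsum("tm,tmk->tk", mask * system.charges / r_safe**3, d)
    if options.field_atomic_dipoles and system.atomic_dipoles is not None:
        n = d / r_safe[..., None]
        mu = system.atomic_dipoles
        mu_dot_n = np.einsum("mk,tmk->tm", mu, n)
        term = 3.0 * mu_dot_n[..., None] * n - mu[None, :, :]
        E += np.einsum("tm,tmk->tk", mask / r_safe**3, term)
    if options.field_atomic_quadrupoles and system.atomic_quadrupoles is not None:
        n = d / r_safe[..., None]
        th = system.atomic_quadrupoles
        th_n = np.einsum("mkl,tml->tmk", th, n)
        n_th_n = np.einsum("tmk,tmk->tm", n, th_n)
        term = 7.5 * n_th_n[..., None] * n - 3.0 * th_n
        E += np.einsum("tm,tmk->tk", mask / r_safe**4, term)
    return E


def _interaction_matrix(system, options, pol_idx):
    """(3p, 3p) tensor block matrix between polarizable sites."""
    pos = system.positions[pol_idx]
    alph = system.alphas[pol_idx]
    d, r, w = _pair_geometry(pos, pos, options)
    p = len(pol_idx)
    same_mol = system.molecule[pol_idx][:, None] == system.molecule[pol_idx][None, :]
    T = np.zeros((p, 3, p, 3))
    for i in range(p):
        for j in range(p):
            if i == j or same_mol[i, j] or w[i, j] == 0:
                continue
            T[i, :, j, :] = w[i, j] * dipole_tensor(
                d[i, j], options.interaction, options.thole_a, alph[i], alph[j]
            )
    return T.reshape(3 * p, 3 * p)


def _closest_pair(system, pol_idx):
    pos = system.positions[pol_idx]
    r = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(r, np.inf)
    i, j = np.unravel_index(np.argmin(r), r.shape)
    return int(pol_idx[i]), int(pol_idx[j]), float(r[i, j])


def scf_induced_dipoles(
    system: PolarizableSystem,
    options: PolarizationOptions | None = None,
    external_field: np.ndarray | None = None,
    warm_start: np.ndarray | None = None,
) -> InducedDipoleSet:
    """Solve the mutual-induction equations for all polarizable sites.

    ``external_field`` (e/A^2, per polarizable site) replaces or augments the
    permanent field; pass it alone for isolated-site tests.  ``warm_start``
    (Debye) seeds the fixed-point iteration.
    """
    options = options or PolarizationOptions()
    pol_idx = np.nonzero(system.polarizable)[0]
    p = len(pol_idx)
    if p == 0:
        return InducedDipoleSet(np.zeros((0, 3)), np.zeros(0, int), 0, 0.0, True)
    alphas = system.alphas[pol_idx]
    E0 = np.zeros((p, 3))
    if system.charges.any() or options.field_atomic_dipoles or options.field_atomic_quadrupoles:
        E0 = permanent_field(system, options, pol_idx)
    if external_field is not None:
        E0 = E0 + np.asarray(external_field, float)
    T = _interaction_matrix(system, options, pol_idx)
    A = alphas[:, None] * np.ones((p, 3))  # per-component alpha
    a_flat = A.reshape(-1)
    E0_flat = E0.reshape(-1)

    if options.solver == "direct_linear":
        M = np.eye(3 * p) - a_flat[:, None] * T
        try:
            mu_flat = np.linalg.solve(M, a_flat * E0_flat)
        except np.linalg.LinAlgError as exc:
            i, j, r = _closest_pair(system, pol_idx)
            raise PolarizationCatastropheError(
                f"singular induction matrix; closest site pair ({i}, {j}) at {r:.3f} A"
            ) from exc
        mu = mu_flat.reshape(p, 3)
        res = np.abs(mu_flat - a_flat * (E0_flat + T @ mu_flat)).max() * EA_TO_DEBYE
        return InducedDipoleSet(
            mu * EA_TO_DEBYE, system.molecule[pol_idx], 1, float(res), True
        )

    if options.solver != "fixed_point":
        raise ValueError(f"unknown solver {options.solver!r}")
    mu = (
        np.asarray(warm_start, float).reshape(-1) / EA_TO_DEBYE
        if warm_start is not None
        else a_flat * E0_flat
    )
    prev_res, growth = np.inf, 0
    for it in range(1, options.max_iter + 1):
        target = a_flat * (E0_flat + T @ mu)
        res = np.abs(target - mu).max() * EA_TO_DEBYE
        mu = (1.0 - options.mixing) * mu + options.mixing * target
        if res <= options.tol:
            return InducedDipoleSet(
                mu.reshape(p, 3) * EA_TO_DEBYE,
                system.molecule[pol_idx],
                it,
                float(res),
                True,
            )
        growth = growth + 1 if res > prev_res else 0
        prev_res = res
        if growth >= 10 or not np.isfinite(res):
            i, j, r = _closest_pair(system, pol_idx)
            raise PolarizationCatastropheError(
                f"fixed-point iteration diverging (residual {res:.3g} D after "
                f"{it} iterations); closest site pair ({i}, {j}) at {r:.3f} A"
            )
    raise PolarizationCatastropheError(
        f"no convergence within {options.max_iter} iterations "
        f"(residual {prev_res:.3g} D)"
    )


def post_trajectory_polarization(
    frames: np.ndarray,
    spec: WaterModelSpec,
    options: PolarizationOptions | None = None,
    alpha_override: float | None = None,
    on_failure: str = "abort",
) -> np.ndarray:
    """Per-frame SCF induced dipoles for a non-polarizable trajectory.

    ``frames`` has shape (n_frames, n_molecules, 3, 3): O, H1, H2 positions
    per molecule in Angstrom.  Oxygen carries the polarizability (from the
    model's ``post_polarization`` entry unless ``alpha_override`` is given);
    hydrogens stay unpolarized.  Each frame is warm-started from the
    previous solution.  Returns molecular induced dipoles, shape
    (n_frames, n_molecules, 3), in Debye.

    ``on_failure="skip"`` records NaN for frames whose SCF fails instead of
    aborting.
    """
    frames = np.asarray(frames, float)
    n_frames, n_mol = frames.shape[:2]
    alpha = alpha_override
    if alpha is None:
        if spec.post_polarization:
            alpha = float(spec.post_polarization["alpha"])
        else:
            alpha = spec.polarizable_alpha("O")
    if alpha is None:
        raise ValueError(f"{spec.name}: no oxygen polarizability available")
    if alpha == 0.0:
        return np.zeros((n_frames, n_mol, 3))
    pol_spec = replace(spec, polarizability={**spec.polarizability, "O": alpha})
    out = np.zeros((n_frames, n_mol, 3))
    warm = None
    for f in range(n_frames):
        mols = [
            molecule_from_coords(pol_spec, *frames[f, i], molecule_index=i)
            for i in range(n_mol)
        ]
        system = build_system(mols, pol_spec)
        try:
            sol = scf_induced_dipoles(system, options, warm_start=warm)
        except PolarizationCatastropheError as exc:
            if on_failure == "skip":
                out[f] = np.nan
                warm = None
                continue
            raise PolarizationCatastropheError(f"frame {f}: {exc}") from exc
        warm = sol.dipoles
        out[f] = sol.per_molecule(n_mol)
    return out
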