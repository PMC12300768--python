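"""Electrostatic water-model definitions and molecular geometry machinery.

A :class:`WaterModelSpec` holds the electrostatic parameter set of one water
model: site charges, rigid reference geometry, virtual-site construction
rules, an optional Drude pair, and optional atomic permanent dipoles and
traceless quadrupoles expressed in atomic local frames.

Local-frame conventions (used by the multipole models):

* oxygen frame: ``z`` is the unit bisector from O toward the hydrogen
  midpoint; ``x`` lies in the molecular plane perpendicular to ``z``
  (signed toward H1); ``y = z × x`` completes a right-handed frame.
* hydrogen frame: ``z`` points from that hydrogen toward the oxygen;
  ``x`` lies in the molecular plane, perpendicular to ``z`` and pointing
  toward the molecular interior (positive projection on the other
  hydrogen); ``y`` completes a right-handed frame.

These sign choices are the unique set that reassembles the printed
AMOEBA14 monomer dipole of 1.71 D from its charges and atomic dipoles.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .constants import EA_TO_DEBYE

__all__ = [
    "WaterModelSpec",
    "LocalFrame",
    "MoleculeGeometry",
    "RigidTransform",
    "load_model",
    "available_models",
    "build_reference_molecule",
    "molecule_from_coords",
    "local_frames",
    "permanent_dipole",
    "quadrupole_lab",
]

_CHARGE_NEUTRALITY_TOL = 1e-12
_QUAD_TRACE_TOL = 1.5e-3  # D*A; printed values round-trip within this


class ModelError(ValueError):
    """Invalid or inconsistent water-model specification."""


@dataclass(frozen=True)
class DrudeSpec:
    host: str
    q_d: float | None
    alpha: float | None


@dataclass(frozen=True)
class VirtualSite:
    label: str
    rule: str            # currently only "bisector"
    displacement: float  # Angstrom from O toward the H midpoint


@dataclass(frozen=True)
class WaterModelSpec:
    """Electrostatic parameter set of one water model."""

    name: str
    site_charges: dict[str, float]
    r_oh: float | None = None
    hoh_angle: float | None = None   # degrees
    rigid: bool = True
    virtual_sites: tuple[VirtualSite, ...] = ()
    drude: DrudeSpec | None = None
    polarizability: dict[str, float] = field(default_factory=dict)
    atomic_dipoles: dict[str, np.ndarray] = field(default_factory=dict)
    atomic_quadrupoles: dict[str, np.ndarray] = field(default_factory=dict)
    quadrupole_scale_convention: str = "as_printed"
    fragments: dict[str, list[str]] | None = None
    post_polarization: dict | None = None

    @property
    def site_labels(self) -> list[str]:
        return list(self.site_charges)

    def polarizable_alpha(self, label: str) -> float | None:
        """Isotropic polarizability of a site in A^3 (Drude or point-dipole)."""
        if self.drude is not None and self.drude.host == label:
            return self.drude.alpha
        return self.polarizability.get(label)

    def validate(self) -> None:
        total = sum(self.site_charges.values())
        if abs(total) > 1e-6:
            raise ModelError(
                f"{self.name}: site charges sum to {total:+.6f} e, not neutral"
            )
        for label, theta in self.atomic_quadrupoles.items():
            theta = np.asarray(theta, dtype=float)
            if not np.allclose(theta, theta.T, atol=1e-12):
                raise ModelError(f"{self.name}: quadrupole on {label} not symmetric")
            if abs(np.trace(theta)) > _QUAD_TRACE_TOL:
                raise ModelError(
                    f"{self.name}: quadrupole on {label} has |trace| "
                    f"{abs(np.trace(theta)):.4f} > {_QUAD_TRACE_TOL} D*A"
                )
        if self.drude is not None and self.drude.alpha is not None:
            if self.drude.alpha <= 0:
                raise ModelError(f"{self.name}: Drude polarizability must be > 0")
            if not self.drude.q_d:
                raise ModelError(f"{self.name}: Drude charge must be nonzero")


@dataclass(frozen=True)
class LocalFrame:
    """Rotation from an atomic local frame into the laboratory frame.

    ``rotation`` columns are the lab-frame images of the local x, y, z axes,
    orthonormal with determinant +1.
    """

    origin_site: str
    rotation: np.ndarray  # (3, 3)

    def to_lab(self, v_local: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(v_local, dtype=float)


@dataclass
class MoleculeGeometry:
    """Laboratory-frame site coordinates of one molecule (Angstrom)."""

    labels: list[str]
    coords: np.ndarray  # (n_sites, 3)
    molecule_index: int = 0

    def position(self, label: str) -> np.ndarray:
        return self.coords[self.labels.index(label)]


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)


# ---------------------------------------------------------------------------
# model loading

def _quad_from_mapping(entry: dict) -> np.ndarray:
    theta = np.zeros((3, 3))
    idx = {"x": 0, "y": 1, "z": 2}
    for key, value in entry.items():
        i, j = idx[key[0]], idx[key[1]]
        theta[i, j] = value
        theta[j, i] = value
    # symmetrize exactly (printed tables are symmetric by construction)
    return 0.5 * (theta + theta.T)


def _spec_from_dict(raw: dict) -> WaterModelSpec:
    geom = raw.get("geometry", {}) or {}
    drude = None
    if "drude" in raw:
        drude = DrudeSpec(
            host=raw["drude"]["host"],
            q_d=raw["drude"].get("q_d"),
            alpha=raw["drude"].get("alpha"),
        )
    vsites = tuple(
        VirtualSite(v["label"], v["rule"], float(v["displacement"]))
        for v in raw.get("virtual_sites", [])
    )
    spec = WaterModelSpec(
        name=raw["name"],
        site_charges={k: float(v) for k, v in raw["site_charges"].items()},
        r_oh=geom.get("r_oh"),
        hoh_angle=geom.get("hoh_angle"),
        rigid=bool(geom.get("rigid", True)),
        virtual_sites=vsites,
        drude=drude,
        polarizability={k: float(v) for k, v in (raw.get("polarizability") or {}).items()},
        atomic_dipoles={
            k: np.asarray(v, dtype=float)
            for k, v in (raw.get("atomic_dipoles") or {}).items()
        },
        atomic_quadrupoles={
            k: _quad_from_mapping(v)
            for k, v in (raw.get("atomic_quadrupoles") or {}).items()
        },
        quadrupole_scale_convention=raw.get("quadrupole_scale_convention", "as_printed"),
        fragments=raw.get("fragments"),
        post_polarization=raw.get("post_polarization"),
    )
    spec.validate()
    return spec


_ALIASES = {
    "spce": "spce",
    "spc/e": "spce",
    "swm4": "swm4ndp",
    "swm4-ndp": "swm4ndp",
    "swm4ndp": "swm4ndp",
    "ipol-0.13": "ipol013",
    "ipol013": "ipol013",
    "opc3-pol": "opc3pol",
    "opc3pol": "opc3pol",
    "amoeba14": "amoeba14",
    "water-dimer": "water_dimer",
    "water_dimer": "water_dimer",
}


def available_models() -> list[str]:
    root = importlib.resources.files("thzwater") / "models"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_model(name_or_path: str | Path) -> WaterModelSpec:
    """Load a bundled model by name or any model parameter file by path."""
    path = Path(name_or_path)
    if path.suffix in {".yaml", ".yml"} and path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        key = _ALIASES.get(str(name_or_path).lower())
        if key is None:
            raise ModelError(
                f"unknown model {name_or_path!r}; available: {available_models()}"
            )
        resource = importlib.resources.files("thzwater") / "models" / f"{key}.yaml"
        raw = yaml.safe_load(resource.read_text())
    return _spec_from_dict(raw)


# ---------------------------------------------------------------------------
# geometry

def build_reference_molecule(
    spec: WaterModelSpec,
    placement: RigidTransform | None = None,
    molecule_index: int = 0,
) -> MoleculeGeometry:
    """Build one molecule at its (equilibrium) reference geometry.

    The canonical pose puts the oxygen at the transform origin with the
    H-O-H bisector along the transform z axis and the molecule in the
    transform xz plane.  Virtual sites are placed per their construction
    rule (e.g. the SWM4 OM site ``displacement`` Angstrom from O toward the
    hydrogen midpoint).
    """
    if spec.r_oh is None or spec.hoh_angle is None:
        raise ModelError(f"{spec.name}: geometry required (no reference bond/angle)")
    half = np.deg2rad(spec.hoh_angle) / 2.0
    s, c = np.sin(half), np.cos(half)
    coords = {
        "O": np.zeros(3),
        "H1": spec.r_oh * np.array([s, 0.0, c]),
        "H2": spec.r_oh * np.array([-s, 0.0, c]),
    }
    for vs in spec.virtual_sites:
        if vs.rule != "bisector":
            raise ModelError(f"unknown virtual-site rule {vs.rule!r}")
        coords[vs.label] = np.array([0.0, 0.0, vs.displacement])
    labels = [lab for lab in spec.site_labels if lab in coords]
    missing = set(spec.site_labels) - set(labels)
    if missing:
        raise ModelError(f"{spec.name}: cannot place sites {sorted(missing)}")
    xyz = np.stack([coords[lab] for lab in labels])
    if placement is not None:
        xyz = placement.apply(xyz)
    return MoleculeGeometry(labels=labels, coords=xyz, molecule_index=molecule_index)


def molecule_from_coords(
    spec: WaterModelSpec,
    o_pos: np.ndarray,
    h1_pos: np.ndarray,
    h2_pos: np.ndarray,
    molecule_index: int = 0,
) -> MoleculeGeometry:
    """Assemble a molecule from trajectory O/H coordinates, adding virtual sites."""
    coords = {"O": np.asarray(o_pos, float),
              "H1": np.asarray(h1_pos, float),
              "H2": np.asarray(h2_pos, float)}
    for vs in spec.virtual_sites:
        mid = 0.5 * (coords["H1"] + coords["H2"])
        b = mid - coords["O"]
        norm = np.linalg.norm(b)
        if norm < 1e-10:
            raise ModelError("degenerate geometry: hydrogens collapse onto oxygen")
        coords[vs.label] = coords["O"] + vs.displacement * b / norm
    labels = [lab for lab in spec.site_labels if lab in coords]
    return MoleculeGeometry(labels=labels,
                            coords=np.stack([coords[lab] for lab in labels]),
                            molecule_index=molecule_index)


def _orthonormal_frame(z: np.ndarray, x_hint: np.ndarray) -> np.ndarray:
    """Right-handed frame with given z and x along the in-plane hint."""
    z = z / np.linalg.norm(z)
    x = x_hint - np.dot(x_hint, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-10:
        raise ModelError("degenerate frame: collinear atoms")
    x /= nx
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def local_frames(geom: MoleculeGeometry, spec: WaterModelSpec) -> dict[str, LocalFrame]:
    """Atomic local frames for O, H1 and H2 (multipole conventions)."""
    o, h1, h2 = geom.position("O"), geom.position("H1"), geom.position("H2")
    mid = 0.5 * (h1 + h2)
    if np.linalg.norm(mid - o) < 1e-10 or np.linalg.norm(h1 - h2) < 1e-10:
        raise ModelError("degenerate frame: collinear or coincident atoms")
    frames: dict[str, LocalFrame] = {}
    # oxygen: z along the bisector, x in-plane toward H1
    frames["O"] = LocalFrame("O", _orthonormal_frame(mid - o, h1 - h2))
    # hydrogens: z toward O, x in-plane toward the other hydrogen (interior)
    frames["H1"] = LocalFrame("H1", _orthonormal_frame(o - h1, h2 - h1))
    frames["H2"] = LocalFrame("H2", _orthonormal_frame(o - h2, h1 - h2))
    return frames


def permanent_dipole(geom: MoleculeGeometry, spec: WaterModelSpec) -> np.ndarray:
    """Permanent molecular dipole in Debye.

    Sum of the point-charge dipole (site charges times lab coordinates,
    converted with 1 e*A = 4.80321 D) and, when the model carries atomic
    permanent dipoles, their lab-frame rotations.  Requires a neutral site
    set so the value is origin-independent.
    """
    q = np.array([spec.site_charges[lab] for lab in geom.labels])
    if abs(q.sum()) > 1e-10:
        raise ModelError(
            f"{spec.name}: non-neutral site set (sum {q.sum():+.4f} e) gives an "
            "origin-dependent dipole"
        )
    mu = EA_TO_DEBYE * (q[:, None] * geom.coords).sum(axis=0)
    if spec.atomic_dipoles:
        frames = local_frames(geom, spec)
        for label, mu_local in spec.atomic_dipoles.items():
            mu = mu + frames[label].to_lab(mu_local)
    return mu


def quadrupole_lab(
    geom: MoleculeGeometry,
    spec: WaterModelSpec,
    convention: str | None = None,
) -> dict[str, np.ndarray]:
    """Atomic quadrupoles rotated to the lab frame (R Theta R^T), in D*A.

    ``convention="one_third"`` scales the tabulated values by 1/3, the form
    consumed by simulation engines; the trace is preserved under rotation.
    """
    if not spec.atomic_quadrupoles:
        raise ModelError(f"{spec.name}: no atomic quadrupoles defined")
    convention = convention or spec.quadrupole_scale_convention
    if convention not in {"as_printed", "one_third"}:
        raise ModelError(f"unknown quadrupole convention {convention!r}")
    scale = 1.0 / 3.0 if convention == "one_third" else 1.0
    frames = local_frames(geom, spec)
    out = {}
    for label, theta in spec.atomic_quadrupoles.items():
        theta = np.asarray(theta, float)
        if not np.allclose(theta, theta.T, atol=1e-12):
            raise ModelError(f"non-symmetric quadrupole on {label}")
        r = frames[label].rotation
        out[label] = scale * (r @ theta @ r.T)
    return out


def scale_polarizability(spec: WaterModelSpec, factor: float) -> WaterModelSpec:
    """Return a copy of ``spec`` with every polarizability scaled by ``factor``.

    For Drude models this rescales the effective alpha = q_d^2/k_d directly;
    the analysis pipeline consumes alpha, not the force constant.
    """
    if factor <= 0:
        raise ModelError("polarizability scale factor must be > 0")
    drude = spec.drude
    if drude is not None and drude.alpha is not None:
        drude = DrudeSpec(drude.host, drude.q_d, drude.alpha * factor)
    pol = {k: v * factor for k, v in spec.polarizability.items()}
    return replace(spec, drude=drude, polarizability=pol)
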