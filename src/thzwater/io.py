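"""Trajectory and spectrum file handling.

Trajectory I/O goes through MDAnalysis, so the pipeline ingests synthetic
and real data identically (PDB/GRO topologies; DCD/XTC/TRR frame formats).
All coordinates are in Angstrom and times in ps.  Water molecules are
resolved from residues; Drude particles are detected by a configurable
name prefix and returned separately.

Spectra and correlation functions are exchanged as two-column text with a
``# key: value`` metadata header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .collective import CorrelationFunction
from .spectra import Spectrum

__all__ = [
    "WaterTrajectory",
    "write_water_trajectory",
    "load_trajectory",
    "write_spectrum",
    "read_spectrum",
    "write_correlation",
    "read_correlation",
]


@dataclass
class WaterTrajectory:
    """In-memory water trajectory: O/H1/H2 coordinates per molecule.

    ``positions`` has shape (n_frames, n_molecules, 3, 3) in Angstrom with
    the atom axis ordered O, H1, H2.  ``drude_positions`` (same shape minus
    the hydrogen slots: (n_frames, n_molecules, 3)) is present when Drude
    particles were found attached to the oxygens.
    """

    positions: np.ndarray
    dt: float
    box: float | None = None
    drude_positions: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[1]


def write_water_trajectory(
    prefix: str | Path,
    positions: np.ndarray,
    dt: float,
    box: float | None = None,
    site_labels: list[str] | None = None,
) -> tuple[Path, Path]:
    """Write (n_frames, n_molecules, n_sites, 3) coordinates as PDB + DCD."""
    prefix = Path(prefix)
    n_frames, n_mol, n_sites, _ = positions.shape
    labels = site_labels or ["O", "H1", "H2"][:n_sites]
    n_atoms = n_mol * n_sites
    u = mda.Universe.empty(
        n_atoms=n_atoms,
        n_residues=n_mol,
        atom_resindex=np.repeat(np.arange(n_mol), n_sites),
        residue_segindex=np.zeros(n_mol, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", labels * n_mol)
    u.add_TopologyAttr("resnames", ["SOL"] * n_mol)
    u.add_TopologyAttr("resids", np.arange(1, n_mol + 1))
    u.add_TopologyAttr("elements", [lab[0] for lab in labels] * n_mol)
    if box is not None:
        u.dimensions = [box, box, box, 90.0, 90.0, 90.0]
    u.atoms.positions = positions[0].reshape(n_atoms, 3)
    pdb_path = prefix.with_suffix(".pdb")
    dcd_path = prefix.with_suffix(".dcd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(pdb_path))
        with mda.Writer(str(dcd_path), n_atoms=n_atoms, dt=dt) as w:
            for f in range(n_frames):
                u.atoms.positions = positions[f].reshape(n_atoms, 3)
                w.write(u.atoms)
    return pdb_path, dcd_path


def load_trajectory(
    topology: str | Path,
    trajectory: str | Path | None = None,
    dt: float | None = None,
    stride: int = 1,
    drude_prefix: str = "D",
) -> WaterTrajectory:
    """Load a water trajectory, resolving molecules from residues.

    Frames are streamed (never more than one MDAnalysis timestep in memory
    beyond the output arrays).  ``dt`` overrides the file metadata and is
    required when the format carries none; ``stride`` subsamples frames and
    scales the effective dt accordingly.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory is None:
            u = mda.Universe(str(topology))
        else:
            try:
                u = mda.Universe(str(topology), str(trajectory))
            except ValueError as exc:
                top_u = mda.Universe(str(topology))
                raise ValueError(
                    f"atom-count mismatch between topology "
                    f"({top_u.atoms.n_atoms} atoms) and trajectory: {exc}"
                ) from exc
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        file_dt = getattr(u.trajectory, "dt", None)
    if any("no dt information" in str(w.message) for w in caught):
        file_dt = None  # MDAnalysis substitutes 1.0 ps when the format has none
    eff_dt = dt if dt is not None else file_dt
    if eff_dt is None or eff_dt <= 0:
        raise ValueError("trajectory carries no time step; pass dt explicitly")
    eff_dt *= stride

    o_idx, h_idx, d_idx = [], [], []
    for res in u.residues:
        names = [n.upper() for n in res.atoms.names]
        o_local = [i for i, n in enumerate(names) if n.startswith("O")]
        h_local = [i for i, n in enumerate(names) if n.startswith("H")]
        drude_local = [i for i, n in enumerate(names) if n.startswith(drude_prefix.upper())]
        if not o_local or len(h_local) < 2:
            raise ValueError(
                f"residue {res.resid} is not a water (names {list(res.atoms.names)})"
            )
        gids = res.atoms.indices
        o_idx.append(gids[o_local[0]])
        h_idx.append([gids[h_local[0]], gids[h_local[1]]])
        d_idx.append(gids[drude_local[0]] if drude_local else -1)
    o_idx = np.asarray(o_idx)
    h_idx = np.asarray(h_idx)
    d_idx = np.asarray(d_idx)
    has_drude = bool((d_idx >= 0).all()) and len(d_idx) > 0

    frames, drude_frames = [], []
    for ts in u.trajectory[::stride]:
        xyz = ts.positions
        frame = np.empty((len(o_idx), 3, 3))
        frame[:, 0] = xyz[o_idx]
        frame[:, 1] = xyz[h_idx[:, 0]]
        frame[:, 2] = xyz[h_idx[:, 1]]
        frames.append(frame)
        if has_drude:
            drude_frames.append(xyz[d_idx])
    box = None
    if u.dimensions is not None and u.dimensions[0] > 0:
        box = float(u.dimensions[0])
    return WaterTrajectory(
        positions=np.asarray(frames),
        dt=float(eff_dt),
        box=box,
        drude_positions=np.asarray(drude_frames) if has_drude else None,
    )


# ---------------------------------------------------------------------------
# two-column text formats

def _write_two_column(path, x, y, header: dict, columns: str) -> Path:
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in header.items()]
    lines.append(f"# columns: {columns}")
    body = "\n".join(f"{a:.10g} {b:.10g}" for a, b in zip(x, y))
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    return path


def _read_two_column(path) -> tuple[np.ndarray, np.ndarray, dict]:
    header: dict[str, str] = {}
    xs, ys = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
            continue
        a, b = line.split()[:2]
        xs.append(float(a))
        ys.append(float(b))
    return np.asarray(xs), np.asarray(ys), header


def write_spectrum(path: str | Path, spec: Spectrum) -> Path:
    header = {
        "channel": spec.channel,
        "volume_A3": spec.volume,
        "temperature_K": spec.temperature,
        "n_molecules": spec.n_molecules,
        **{f"smoothing_{k}": v for k, v in spec.smoothing.items()},
        **spec.meta,
    }
    return _write_two_column(
        path, spec.wavenumbers, spec.values,
        {k: v for k, v in header.items() if v is not None},
        "wavenumber_cm-1 alpha_n_cm-1",
    )


def read_spectrum(path: str | Path) -> Spectrum:
    nu, vals, header = _read_two_column(path)
    return Spectrum(
        wavenumbers=nu,
        values=vals,
        channel=header.get("channel", "total"),
        volume=float(header["volume_A3"]) if "volume_A3" in header else None,
        temperature=(
            float(header["temperature_K"]) if "temperature_K" in header else None
        ),
        meta={"source": str(path)},
    )


def write_correlation(path: str | Path, corr: CorrelationFunction) -> Path:
    header = {"kind": corr.kind}
    if corr.derivative_scheme:
        header["derivative_scheme"] = corr.derivative_scheme
    return _write_two_column(path, corr.lags, corr.values, header, "lag_ps value")


def read_correlation(path: str | Path) -> CorrelationFunction:
    lags, vals, header = _read_two_column(path)
    return CorrelationFunction(
        lags=lags,
        values=vals,
        counts=np.ones_like(lags),
        kind=header.get("kind", ""),
        derivative_scheme=header.get("derivative_scheme"),
    )
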