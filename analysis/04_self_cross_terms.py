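#!/usr/bin/env python
"""Self/cross decomposition: independent molecules vs a shared director.

Two librator ensembles with identical single-molecule dynamics:

* independent molecules -- distinct-molecule (cross) correlations vanish in
  expectation, so the collective spectrum is carried by the self terms;
* correlated variant (all molecules share the diffusing base orientation)
  -- cross terms become comparable to the self terms, the situation in
  hydrogen-bonded liquids where network motions shape the low-frequency
  spectrum.

Writes results/self_cross_summary.csv and the decomposed spectra as
results/self_cross_<variant>.dat (wavenumber, total, self, cross).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from thzwater.collective import MolecularDipoleSeries, self_cross_split
from thzwater.constants import C_CM_PER_PS
from thzwater.spectra import smooth_and_scale, spectrum_from_current
from thzwater.synthetic import LibratorParams, generate_librator_trajectory

out = Path("results")
out.mkdir(exist_ok=True)

N_RUNS, N_FRAMES, DT = 4, 16384, 0.004
LAG_N = 750  # 3 ps lag window

rows = []
for variant, correlated in (("independent", False), ("correlated", True)):
    csums = None
    for r in range(N_RUNS):
        params = LibratorParams(
            n_molecules=12, n_frames=N_FRAMES, dt=DT,
            seed=7000 + 17 * r, correlated=correlated,
        )
        traj = generate_librator_trajectory(params)
        series = MolecularDipoleSeries(dt=DT, permanent=traj.dipoles)
        c_self, c_cross, c_total = self_cross_split(
            series, via="currents", max_lag_fraction=LAG_N / (N_FRAMES - 2)
        )
        vals = np.stack([c_total.values, c_self.values, c_cross.values])
        csums = vals if csums is None else csums + vals
    csums /= N_RUNS
    volume = params.box_edge**3
    step = 1.0 / (2.0 * C_CM_PER_PS * c_total.lags[-1])
    grid = np.arange(0.0, 1200.0, step)
    spectra = []
    for channel_vals in csums:
        c_total.values = channel_vals
        spec = spectrum_from_current(c_total, volume, 300.0, wavenumbers=grid)
        spectra.append(smooth_and_scale(spec, 13, 3).values)
    total_s, self_s, cross_s = spectra
    np.savetxt(
        out / f"self_cross_{variant}.dat",
        np.column_stack([grid, total_s, self_s, cross_s]),
        header="wavenumber_cm-1 total self cross",
    )
    band = (grid >= 150) & (grid <= 750)
    rows.append({
        "variant": variant,
        "cross_to_self_acf0": round(float(csums[2][0] / csums[1][0]), 4),
        "max_|cross|/max_total_spectrum": round(
            float(np.abs(cross_s[band]).max() / total_s[band].max()), 4
        ),
    })

summary = pd.DataFrame(rows)
summary.to_csv(out / "self_cross_summary.csv", index=False)
print(summary.to_string(index=False))
print(
    "\nWith independent molecules the cross channel is statistical noise "
    "around zero; sharing the orientational director moves a finite "
    "fraction of the collective response into the cross terms while "
    "self + cross = total holds exactly in both cases."
)
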