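#!/usr/bin/env python
"""Validate the off-axis reconstruction against the interference forward model.

Builds noiseless synthetic holograms from known bandlimited speckle object
fields, demodulates the sideband, and measures how well the reconstructed
intensity tracks the injected |O|² on interior pixels.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bdiflow.holography import fourier_demodulate, guard_band_mask, locate_sideband
from bdiflow.synthetic import generate_hologram_stack, speckle_field

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rng = np.random.default_rng(11)
    rows = []
    for trial in range(5):
        obj = 0.4 * speckle_field((64, 64), 0.05, rng)
        stack = generate_hologram_stack(obj, (0.3, 0.3), reference_amplitude=2.0)
        est = locate_sideband(np.abs(np.fft.fft2(stack.frames[0])), 0.08)
        rec = fourier_demodulate(stack.frames[0], (0.3, 0.3), aperture_radius=0.1)
        m = guard_band_mask((64, 64), 8)
        intensity = rec.intensity()[m]
        truth = np.abs(obj[m]) ** 2
        corr = float(np.corrcoef(intensity, truth)[0, 1])
        scale = float(np.sum(intensity * truth) / np.sum(truth**2))
        rows.append(
            {
                "trial": trial,
                "roundtrip_correlation": round(corr, 6),
                "recovered_scale": round(scale, 4),
                "carrier_error_bins": round(
                    64 * max(abs(est[0] - 0.3), abs(est[1] - 0.3)), 2
                ),
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "holography_check.csv", index=False)
    print(table.to_string(index=False))
    print(
        f"\nmin round-trip correlation {table['roundtrip_correlation'].min():.4f} "
        f"(scale ~ |R|^2 = 4); wrote {RESULTS/'holography_check.csv'}"
    )


if __name__ == "__main__":
    main()
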