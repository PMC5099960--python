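#!/usr/bin/env python
"""Piecewise log-linear diameter regression.

Regenerates diameter-vs-generation series from the three published
log-linear segments (noise-free, and with log-normal measurement scatter),
refits them with the fixed-breakpoint piecewise OLS (breaks after
generations 11 and 20), and tabulates slopes, intercepts and 95% CIs.

The noise-free refit must return the printed coefficients to machine
precision; the noisy refit shows the CI widths the procedure produces at a
study-like sample size (6 subjects per generation).
"""

from pathlib import Path

import pandas as pd

from pigairway.generator import DEFAULT_SEGMENTS, generate_diameter_series
from pigairway.morphometry import fit_loglinear_segments

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for label, noise, n_per in [("noise_free", 0.0, 3), ("log_noise_0.02", 0.02, 6)]:
    series = generate_diameter_series(DEFAULT_SEGMENTS, noise_sd_log10=noise,
                                      n_per_generation=n_per, seed=1)
    for f in fit_loglinear_segments(series):
        rows.append({
            "series": label,
            "segment": f.segment_index,
            "generations": f"{f.generation_range[0]}-{f.generation_range[1]}",
            "slope_log10mm_per_gen": f.slope,
            "intercept_log10mm": f.intercept,
            "ci95_slope": f.ci_slope_halfwidth,
            "ci95_intercept": f.ci_intercept_halfwidth,
            "r2": f.r2,
            "n": f.n,
        })
df = pd.DataFrame(rows)
df.to_csv(OUT / "regression_fits.csv", index=False)

print("Piecewise log-linear fits of log10(diameter) on generation")
print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
nf = df[df.series == "noise_free"]
print("\nNoise-free refit returns the three generating equations exactly: "
      f"slopes {nf.slope_log10mm_per_gen.round(4).tolist()}, "
      f"intercepts {nf.intercept_log10mm.round(4).tolist()}.")
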