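"""Spectrometer noise level over an exposure x integration grid.

Simulates 20 repeated white-plate measurements per acquisition condition,
computes the apparent absorbance of repeats 2-20 against the first, takes
the second derivative, and reports the noise level NL (mean windowed SD,
834-872 nm).  Longer exposures and more integrations both lower NL; for a
read-noise-dominated detector NL falls as 1/sqrt(integrations).
"""

from strawspec import (AcquisitionCondition, DetectorModel, SGConfig,
                       generate_white_plate_series, grid_evaluate)
from strawspec.noise import (INTEGRATION_STEPS, VIS_NIR_EXPOSURES_MS,
                             VIS_NIR_NOISE_WINDOW_NM)

detector = DetectorModel(source_per_ms=200.0, read_noise=30.0, shot_factor=1.0)

series = []
seed = 0
for exposure in VIS_NIR_EXPOSURES_MS[::2]:       # 10, 120, 240 ms
    for integrations in INTEGRATION_STEPS[::2]:  # 8, 32, 128
        seed += 1
        series.append(generate_white_plate_series(
            AcquisitionCondition(exposure, integrations), n_repeats=20,
            detector=detector, seed=seed))

table = grid_evaluate(series, SGConfig(), VIS_NIR_NOISE_WINDOW_NM).to_frame()
table["NL_uabs"] = table["NL"] * 1e6
print(table[["exposure_ms", "integrations", "n_points", "NL_uabs"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
best = table.loc[table["NL"].idxmin()]
print(f"\nlowest NL: {best['NL_uabs']:.2f} uabs at "
      f"{best['exposure_ms']:.0f} ms x {best['integrations']:.0f} integrations")
# NL is reported in micro-absorbance; each condition uses 19 apparent
# spectra and the 20 grid points between 834 and 872 nm.
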