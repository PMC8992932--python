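"""Spatial resolution from periodic patterns: the MTF representative value.

Within a 7.5 cm^2 circular ROI over a periodic plate pattern, the std/mean
ratio maps to a single-number MTF via MTF = sqrt(2) * sigma/mu (for a
sinusoid of modulation M, sigma/mu = M/sqrt(2)). The calibrated threshold:
sigma/mu = 0.56 corresponds to MTF 0.8, the pass limit. Blur suppresses the
pattern modulation and the MTF falls.
"""

from phantomqa import SimConfig, get_layout, register_phantom, render_series
from phantomqa.resolution import evaluate_zone_resolution

layout = get_layout("INSIGHT")
print(f"{'blur FWHM (mm)':>15}{'MTF (FE)':>10}{'MTF (PE)':>10}  pass(>=0.8)")
for blur in (0.0, 1.0, 2.0, 3.0, 4.0):
    series, _ = render_series(SimConfig(layout="INSIGHT", blur_fwhm=blur))
    reg = register_phantom(series[0], layout)
    fe, pe = evaluate_zone_resolution(series, layout, reg, zone_id=1)
    print(f"{blur:>15.1f}{fe.mtf:>10.3f}{pe.mtf:>10.3f}  {fe.passed and pe.passed}")
# MTF decreases monotonically with blur; around FWHM ~2 mm the 6 mm-period
# pattern drops below the 0.8 threshold and the resolution test fails.
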