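"""Calibration against the published atmospheric/marine curves.

The package does not distribute IntCal20/Marine20. Download them once
(https://intcal.org: intcal20.14c and marine20.14c, the standard
three-column format) and pass their paths; this reproduces published
mixed-curve chronologies, e.g. roughly 1000-800 calBC for a 2800 +/- 30 BP
date with 21.4 +/- 12.6 % marine carbon and deltaR -138 +/- 23.

Usage: python calibrate_published.py intcal20.14c marine20.14c
"""

import sys

from paleoiso.calibration import CalConfig, RadiocarbonDate, calibrate, load_curve

if len(sys.argv) != 3:
    sys.exit(__doc__)

terr = load_curve(sys.argv[1])
marine = load_curve(sys.argv[2])
date = RadiocarbonDate(
    lab_code="Beta-581537", burial_id="B2", cra=2800, sigma=30,
    marine_frac=0.214, marine_frac_sd=0.126, deltaR=-138, deltaR_sd=23,
)
res = calibrate(date, terr, marine, CalConfig(seed=1))
print("95.4% range(s):", res.range_2sigma)
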