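"""Synthetic stand-in for a 90-tumour per-tumour AI-ratio distribution.

The real per-tumour ratio table this emulates is not redistributable, so
this module constructs a synthetic cohort of 90 AI ratios that reproduces
its known aggregate properties exactly:

* 70 ratios >= 0.2 and 20 below (78% / 22% at the CIN cut-off),
* overall range 0 to 0.78,
* 15 ratios inside [0.12, 0.22] whose median is 0.20.

It exists to exercise cut-off application and summary logic against a
realistically shaped cohort; it is NOT real data.
"""

import numpy as np


def synthetic_ai_ratio_cohort() -> np.ndarray:
    low = np.linspace(0.0, 0.11, 13)  # clearly CIN-L
    window_l = np.array([0.12, 0.13, 0.14, 0.15, 0.16, 0.17, 0.19])
    window_h = np.array([0.20, 0.20, 0.21, 0.21, 0.21, 0.22, 0.22, 0.22])
    high = np.linspace(0.23, 0.78, 62)  # clearly CIN-H, max 0.78
    ratios = np.concatenate([low, window_l, window_h, high])
    assert ratios.size == 90
    return ratios
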