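"""Jute-fiber breaking-strength data (two gauge lengths, 30 specimens each).

Breaking strength of jute fibre at gauge lengths 10 mm and 20 mm, a standard
pair of lifetime-type datasets for comparing two related populations.  The
analysis convention divides the raw strengths by 1000.
"""

from __future__ import annotations

import numpy as np

__all__ = ["JUTE_GAUGE_10MM", "JUTE_GAUGE_20MM", "load_jute"]

JUTE_GAUGE_10MM = np.array([
    43.93, 50.16, 101.15, 108.94, 123.06, 141.38,
    151.48, 163.40, 177.25, 183.16, 212.13, 257.44,
    262.90, 291.27, 303.90, 323.83, 353.24, 376.42,
    383.43, 422.11, 506.60, 530.55, 590.48, 637.66,
    671.49, 693.73, 700.74, 704.66, 727.23, 778.17,
])

JUTE_GAUGE_20MM = np.array([
    36.75, 45.58, 48.01, 71.46, 83.55, 99.72,
    113.85, 116.99, 119.86, 145.96, 166.49, 187.13,
    187.85, 200.16, 244.53, 284.64, 350.70, 375.81,
    419.02, 456.60, 547.44, 578.62, 581.60, 585.57,
    594.29, 662.66, 688.16, 707.36, 756.70, 765.14,
])


def load_jute(scaled: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Return the two datasets, divided by 1000 unless ``scaled=False``."""
    if scaled:
        return JUTE_GAUGE_10MM / 1000.0, JUTE_GAUGE_20MM / 1000.0
    return JUTE_GAUGE_10MM.copy(), JUTE_GAUGE_20MM.copy()
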