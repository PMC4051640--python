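"""Canonical double-gamma hemodynamic response function.

The kernel is the difference of two gamma densities: a positive response
peaking at 6 s and an undershoot peaking at 16 s with 1/6 the amplitude
(the shape used by the major SPM-style analysis packages). It is sampled
at the repetition time and normalized to unit peak so that convolving a
unit boxcar yields a response whose plateau amplitude is directly
interpretable as the effect size.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["double_gamma_hrf"]

PEAK_DELAY_S = 6.0
UNDERSHOOT_DELAY_S = 16.0
DISPERSION_S = 1.0
UNDERSHOOT_RATIO = 1.0 / 6.0
DURATION_S = 32.0


def double_gamma_hrf(tr: float, duration_s: float = DURATION_S) -> np.ndarray:
    """Sample the canonical HRF at ``tr`` seconds; unit peak amplitude."""
    if tr <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0, duration_s + tr / 2, tr)
    peak = gamma_dist.pdf(t, PEAK_DELAY_S / DISPERSION_S, scale=DISPERSION_S)
    under = gamma_dist.pdf(t, UNDERSHOOT_DELAY_S / DISPERSION_S, scale=DISPERSION_S)
    h = peak - UNDERSHOOT_RATIO * under
    m = np.max(np.abs(h))
    if m == 0:
        raise ValueError("degenerate HRF sampling (TR too long)")
    return h / m
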