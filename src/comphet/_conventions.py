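"""Numerical conventions shared across the package.

One percentile convention is used everywhere (contrast stretching,
reference thresholds, display statistics): linear interpolation between
order statistics, i.e. the quantile at level q/100 of the sorted sample
with fractional positions interpolated linearly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["percentile"]


def percentile(values, q):
    """Percentile with linear interpolation between order statistics.

    Parameters
    ----------
    values : array-like
        Finite sample values.
    q : float or sequence of floats
        Percentile level(s) in [0, 100].
    """
    return np.percentile(np.asarray(values, dtype=float), q, method="linear")
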