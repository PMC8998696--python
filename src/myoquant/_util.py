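"""Small shared helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd


def relative_histogram(values, bin_width: float, start: float = 0.0) -> pd.DataFrame:
    """Relative-frequency histogram with fixed-width bins starting at `start`.

    Returns a DataFrame with columns ``bin_left``, ``bin_right``,
    ``frequency``; frequencies sum to 1 (empty input gives an empty frame).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "frequency"])
    n_bins = max(1, int(np.ceil((values.max() - start) / bin_width)))
    if values.max() >= start + n_bins * bin_width:  # right-edge value
        n_bins += 1
    edges = start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    nz = np.flatnonzero(counts)
    lo, hi = nz[0], nz[-1] + 1  # trim empty bins at both ends
    return pd.DataFrame(
        {
            "bin_left": edges[lo:hi],
            "bin_right": edges[lo + 1 : hi + 1],
            "frequency": counts[lo:hi] / counts.sum(),
        }
    )


def modal_value(values: np.ndarray) -> float:
    """Mode of an integer-valued array (most frequent gray level)."""
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("cannot take mode of empty array")
    counts = np.bincount(values.astype(np.int64))
    return float(np.argmax(counts))
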