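"""Statistical helpers for weight-distribution classification."""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde


def kde_mode_count(
    weights: np.ndarray,
    w_max: float,
    grid_points: int = 256,
    prominence_frac: float = 0.05,
    bandwidth_frac: float = 0.04,
) -> int:
    """Number of prominent modes of a weight sample on [0, w_max].

    The sample is reflected at both boundaries before kernel density
    estimation so that probability mass piled against a bound shows up as a
    boundary mode rather than leaking outside the support.  A fixed
    bandwidth of ``bandwidth_frac * w_max`` is used (Silverman's rule badly
    over-smooths the wide, shallow-dipped U shapes these simulations
    produce).  Modes are local maxima of the density with prominence at
    least ``prominence_frac`` of the global maximum (the grid is
    zero-padded so boundary modes count).
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 3 or np.ptp(w) < 1e-12 * w_max:
        return 1
    reflected = np.concatenate([w, -w, 2.0 * w_max - w])
    try:
        kde = gaussian_kde(reflected)
        kde.set_bandwidth(bandwidth_frac * w_max / max(reflected.std(), 1e-12))
    except np.linalg.LinAlgError:
        return 1
    grid = np.linspace(0.0, w_max, grid_points)
    dens = kde(grid)
    peak = dens.max()
    if peak <= 0:
        return 1
    padded = np.concatenate([[0.0], dens, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_frac * peak)
    return max(len(peaks), 1)
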