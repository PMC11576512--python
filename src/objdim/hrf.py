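"""Library of candidate haemodynamic response functions.

Voxels differ in haemodynamic shape; rather than fitting a free-form HRF,
the modulation model selects per voxel from a fixed library of 20
double-gamma kernels spanning a grid of 10 times-to-peak (4-8 s) by 2
undershoot ratios, sampled on the microtime grid (TR / microtime_factor)
and normalized to unit peak amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from ._utils import check_positive

__all__ = ["HRFLibrary", "build_hrf_library"]

KERNEL_DURATION_S = 32.0
UNDERSHOOT_DELAY_S = 8.0


@dataclass(frozen=True)
class HRFLibrary:
    """Sampled HRF kernels plus their shape parameters.

    ``kernels`` has one row per candidate, sampled at ``dt`` seconds
    (the microtime resolution); ``params`` records time-to-peak and
    undershoot ratio per kernel. Rows are ordered by time-to-peak, then
    undershoot ratio.
    """

    kernels: np.ndarray
    params: pd.DataFrame
    dt: float
    tr: float
    microtime_factor: int

    def __post_init__(self) -> None:
        if len(self.kernels) != len(self.params):
            raise ValueError("one parameter row per kernel required")
        peaks = self.kernels.max(axis=1)
        if not np.allclose(peaks, 1.0, atol=1e-9):
            raise ValueError("kernels must be peak-normalized to 1")

    def __len__(self) -> int:
        return len(self.kernels)


def _double_gamma(t: np.ndarray, time_to_peak: float, undershoot_ratio: float) -> np.ndarray:
    # gamma pdf with scale 1 peaks at shape - 1
    main = gamma_dist.pdf(t, a=time_to_peak + 1.0)
    under = gamma_dist.pdf(t, a=time_to_peak + UNDERSHOOT_DELAY_S + 1.0)
    h = main - undershoot_ratio * under
    return h / h.max()


def build_hrf_library(
    tr: float,
    n: int = 20,
    *,
    microtime_factor: int = 10,
    peak_range: tuple[float, float] = (4.0, 8.0),
    undershoot_ratios: tuple[float, ...] = (0.15, 0.35),
) -> HRFLibrary:
    """Build the candidate-HRF library on the microtime grid.

    The default 10 x 2 grid of times-to-peak and undershoot ratios yields
    20 kernels. ``n`` must factor as (times-to-peak) x (undershoot ratios).
    """
    check_positive("tr", tr)
    n_peaks, rem = divmod(n, len(undershoot_ratios))
    if rem or n_peaks < 1:
        raise ValueError(
            f"n={n} does not factor over {len(undershoot_ratios)} undershoot ratios"
        )
    dt = tr / microtime_factor
    t = np.arange(0.0, KERNEL_DURATION_S, dt)
    peaks = np.linspace(*peak_range, n_peaks)
    kernels, rows = [], []
    for ttp in peaks:
        for ratio in undershoot_ratios:
            kernels.append(_double_gamma(t, ttp, ratio))
            rows.append((ttp, ratio))
    kernels = np.array(kernels)
    # order by the realized peak time (the undershoot can shift the maximum
    # by a sample), so library order == time-to-peak order exactly
    order = np.lexsort(([r[1] for r in rows], kernels.argmax(axis=1)))
    kernels = kernels[order]
    rows = [rows[i] for i in order]
    params = pd.DataFrame(rows, columns=["time_to_peak", "undershoot_ratio"])
    return HRFLibrary(kernels, params, dt=dt, tr=tr,
                      microtime_factor=microtime_factor)
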