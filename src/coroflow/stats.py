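"""Method-comparison statistics: Bland–Altman agreement, CoV, Pearson correlation.

These are the statistics used to compare a candidate flow measurement
(CFD-derived or Doppler-derived) against a reference, and to quantify
reproducibility of repeated measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "AgreementSummary",
    "bland_altman",
    "coefficient_of_variation",
    "pearson_r2",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class AgreementSummary:
    """Bland–Altman agreement between two paired measurement methods.

    ``bias`` is the mean of the paired differences a - b, ``sd_delta`` the
    sample standard deviation of the differences (n-1 denominator), and the
    limits of agreement are ``bias ± 1.96·sd_delta``, the interval expected
    to contain ~95% of differences under a Gaussian error model.
    ``r``/``r2`` are optionally attached by callers that also correlate the
    two methods (e.g. the virtual bench agreement report).
    """

    bias: float
    sd_delta: float
    loa_low: float
    loa_high: float
    n: int
    r: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("agreement summary requires n >= 2")
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


def bland_altman(a, b) -> AgreementSummary:
    """Bland–Altman comparison of paired measurements ``a`` and ``b``.

    Differences are taken as ``a - b``; swap the arguments to flip the sign
    of the bias and mirror the limits of agreement.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("bland_altman requires two 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("bland_altman requires at least 2 pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("bland_altman requires pairwise finite values")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementSummary(
        bias=bias,
        sd_delta=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(a.size),
    )


def coefficient_of_variation(repeats) -> float:
    """CoV of repeated samples: 100 × sd/mean (sample sd), in percent."""
    x = np.asarray(repeats, dtype=float)
    if x.size < 2:
        raise ValueError("CoV requires at least 2 repeats")
    m = x.mean()
    if m == 0:
        raise ValueError("CoV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / m)


def pearson_r2(x, y) -> tuple[float, float]:
    """Pearson correlation of two vectors; returns ``(r, r**2)``.

    The two-sided p-value is available via :func:`scipy.stats.pearsonr`
    directly; only r and R² are part of the reported surface here.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_r2 requires equal-length 1-D vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r2 undefined for zero-variance input")
    r = float(_sps.pearsonr(x, y).statistic)
    return r, r * r


def bland_altman_plot(a, b, ax=None, label_a="method A", label_b="method B"):
    """Standard Bland–Altman panel: (mean, difference) scatter with bias/LoA lines."""
    import matplotlib.pyplot as plt

    summ = bland_altman(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, a - b, s=18, color="k", zorder=3)
    ax.axhline(summ.bias, color="k")
    for y in (summ.loa_low, summ.loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} − {label_b}")
    return ax, summ
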