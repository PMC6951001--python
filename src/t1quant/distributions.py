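"""Zero-inflated log-normal distribution for skewed, often-absent lesions.

Several lesion burdens (microvascular-obstruction extent, haemorrhage area,
salvage index) are reported as median (IQR) with a substantial share of
exact zeros — the lesion simply is not present in many subjects. The
simulator models such quantities as a point mass at zero of size ``p_zero``
(one minus the lesion incidence) mixed with a log-normal positive part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ZeroInflatedLogNormal", "fit_zi_lognormal", "Z75"]

#: standard-normal upper quartile, the z-score of a log-normal's q3
Z75: float = float(stats.norm.ppf(0.75))


@dataclass(frozen=True)
class ZeroInflatedLogNormal:
    """Mixture of a point mass at zero and a log-normal positive part.

    Parameters
    ----------
    p_zero
        Probability of an exact zero (1 - incidence), in ``[0, 1)``.
    mu, sigma
        Log-scale location and scale of the positive part (``sigma >= 0``).
    """

    p_zero: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_zero < 1.0:
            raise ValueError("p_zero must be in [0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_overall_quantiles(
        cls, p_zero: float, median: float, q1: float, q3: float
    ) -> "ZeroInflatedLogNormal":
        """Fit from quantiles of the *overall* distribution (zeros included).

        Printed cohort summaries quote the median and IQR of the whole
        group, zeros and all. Each printed quantile at overall level ``l``
        with a positive value corresponds to the positive part's quantile at
        level ``(l - p_zero) / (1 - p_zero)`` (valid when ``l > p_zero``).
        ``(mu, sigma)`` are fitted by least squares of the log-values on the
        matching standard-normal scores. With a single usable quantile the
        fit is underdetermined and ``sigma`` defaults to 1.0.
        """
        if not 0.0 <= p_zero < 1.0:
            raise ValueError("p_zero must be in [0, 1)")
        if not q1 <= median <= q3:
            raise ValueError("quantiles must satisfy q1 <= median <= q3")
        pts = []
        for level, value in ((0.25, q1), (0.5, median), (0.75, q3)):
            if value > 0 and level > p_zero:
                pos_level = (level - p_zero) / (1.0 - p_zero)
                pts.append((float(stats.norm.ppf(pos_level)), np.log(value)))
        if not pts:
            raise ValueError(
                "no usable positive quantile: printed quantiles are all zero "
                "or all below the zero mass"
            )
        if len(pts) == 1:
            z, logv = pts[0]
            sigma = 1.0
            mu = logv - sigma * z
        else:
            z = np.array([p[0] for p in pts])
            logv = np.array([p[1] for p in pts])
            sigma, mu = np.polyfit(z, logv, 1)
            sigma = max(float(sigma), 0.0)
            mu = float(np.mean(logv - sigma * z)) if sigma == 0.0 else float(mu)
        return cls(p_zero=p_zero, mu=float(mu), sigma=float(sigma))

    # -- sampling and summaries -------------------------------------------

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values; exact zeros appear with probability ``p_zero``.

        The zero indicator is drawn first, then the log-normal deviates, so
        a fixed generator state yields identical samples.
        """
        zeros = rng.random(n) < self.p_zero
        x = rng.lognormal(self.mu, self.sigma, size=n)
        x[zeros] = 0.0
        return x

    def positive_median(self) -> float:
        return float(np.exp(self.mu))

    def positive_quantile(self, q) -> np.ndarray:
        return np.exp(self.mu + self.sigma * stats.norm.ppf(q))

    def overall_quantile(self, q) -> np.ndarray:
        """Quantile of the mixture (zeros included)."""
        q = np.asarray(q, dtype=float)
        pos_level = (q - self.p_zero) / (1.0 - self.p_zero)
        out = np.where(q <= self.p_zero, 0.0,
                       np.exp(self.mu + self.sigma * stats.norm.ppf(np.clip(pos_level, 1e-12, 1 - 1e-12))))
        return out


def fit_zi_lognormal(
    p_zero: float, median: float, q1: float, q3: float
) -> ZeroInflatedLogNormal:
    """Fit the positive part to a stated median and IQR.

    The stated quantiles describe the log-normal positive part:
    ``mu = ln(median)`` exactly, and ``sigma`` minimises the squared error
    to ``(q1, q3)`` on the log scale, which has the closed form
    ``sigma = ln(q3 / q1) / (2 * Z75)``.

    Raises
    ------
    ValueError
        If ``q1 <= 0`` while ``p_zero == 0`` (zeros in the quantiles require
        mass at zero), or the quantile ordering / domains are violated.
    """
    if not 0.0 <= p_zero < 1.0:
        raise ValueError("p_zero must be in [0, 1)")
    if q1 <= 0.0 and p_zero == 0.0:
        raise ValueError("q1 <= 0 with p_zero = 0: mass at zero required")
    if q1 <= 0.0 or median <= 0.0:
        # printed quantiles reach into the zero mass; delegate to the
        # overall-quantile construction
        return ZeroInflatedLogNormal.from_overall_quantiles(p_zero, median, q1, q3)
    if not q1 <= median <= q3:
        raise ValueError("quantiles must satisfy q1 <= median <= q3")
    mu = float(np.log(median))
    sigma = float(np.log(q3 / q1) / (2.0 * Z75))
    return ZeroInflatedLogNormal(p_zero=p_zero, mu=mu, sigma=sigma)
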