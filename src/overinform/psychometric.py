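"""Maximum-likelihood psychometric (logistic) fits with bootstrap intervals.

Categorisation data from the staircases are modelled with the same
lapse-rate logistic family the simulated observer uses:

    P(far-category | x) = gamma/2 + (1 - gamma) * logistic((x - b) / sigma)

where ``b`` is the category boundary, ``sigma`` the slope scale and
``gamma`` an optional lapse rate (fixed, or profiled out).  Confidence
intervals are percentile bootstrap over trials; display points can be
binned (e.g. five trials per bin for the 50-step colour continuum) with
per-bin bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

__all__ = ["PsychometricModel", "PsychometricResults", "bootstrap_proportion_ci"]


def _nll(params, x, y, lapse):
    b, log_sigma = params
    p = lapse / 2.0 + (1.0 - lapse) * expit((x - b) / np.exp(log_sigma))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))


@dataclass
class PsychometricResults:
    """Fitted psychometric parameters, optionally with bootstrap intervals."""

    boundary: float
    slope: float
    lapse: float
    degenerate: bool
    nll: float
    boot_boundaries: Optional[np.ndarray] = None
    boot_slopes: Optional[np.ndarray] = None

    def conf_int(self, param: str = "boundary", alpha: float = 0.05) -> tuple[float, float]:
        draws = {"boundary": self.boot_boundaries, "slope": self.boot_slopes}[param]
        if draws is None:
            raise ValueError("fit was run without bootstrap=True")
        return (float(np.percentile(draws, 100 * alpha / 2)),
                float(np.percentile(draws, 100 * (1 - alpha / 2))))

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.lapse / 2.0 + (1.0 - self.lapse) * expit((x - self.boundary) / self.slope)

    def plot(self, ax=None, points: Optional[pd.DataFrame] = None, label: str = None):
        """Diagnostic plot: fitted curve, optionally with binned points + CIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo = points["position"].min() if points is not None else self.boundary - 4 * self.slope
        hi = points["position"].max() if points is not None else self.boundary + 4 * self.slope
        grid = np.linspace(lo, hi, 200)
        ax.plot(grid, self.predict(grid), label=label)
        if points is not None:
            ax.errorbar(points["position"], points["proportion"],
                        yerr=[points["proportion"] - points["ci_low"],
                              points["ci_high"] - points["proportion"]],
                        fmt="o", capsize=2)
        ax.set_xlabel("continuum position")
        ax.set_ylabel("P(far-end category)")
        ax.set_ylim(-0.02, 1.02)
        return ax


class PsychometricModel:
    """MLE logistic psychometric function for binary categorisation trials.

    Parameters
    ----------
    positions : absolute continuum positions, one per trial
    responses : 1 when the far-end category was chosen, else 0
    n_steps : continuum length (used to bound degenerate fits)
    lapse : fixed lapse rate used during fitting
    """

    def __init__(self, positions, responses, n_steps: int, lapse: float = 0.02):
        self.x = np.asarray(positions, dtype=float)
        self.y = np.asarray(responses, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("positions and responses must have equal length")
        if len(np.unique(self.x)) < 2:
            raise ValueError("need at least two distinct positions to fit")
        self.n_steps = int(n_steps)
        self.lapse = float(lapse)

    def _fit_once(self, x, y) -> tuple[float, float, float, bool]:
        if np.all(y == y[0]):
            # all-same response: boundary is pushed to the continuum edge
            b = float(self.n_steps) if y[0] == 0 else 1.0
            return b, 0.5, 0.0, True
        b0 = float(np.interp(0.5, [0, 1], [x.min(), x.max()]))
        span = max(x.max() - x.min(), 1.0)
        best = None
        for s0 in (np.log(span / 10), np.log(span / 3)):
            res = optimize.minimize(
                _nll, np.array([b0, s0]), args=(x, y, self.lapse),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        b, log_sigma = best.x
        b = float(np.clip(b, 1 - self.n_steps, 2 * self.n_steps))
        return b, float(np.exp(log_sigma)), float(best.fun), False

    def fit(self, bootstrap: bool = False, n_boot: int = 1000,
            seed: Optional[int] = None) -> PsychometricResults:
        b, sigma, nll, degenerate = self._fit_once(self.x, self.y)
        boots_b = boots_s = None
        if bootstrap and not degenerate:
            rng = np.random.default_rng(seed)
            n = len(self.x)
            boots_b = np.empty(n_boot)
            boots_s = np.empty(n_boot)
            for i in range(n_boot):
                idx = rng.integers(n, size=n)
                xb, yb = self.x[idx], self.y[idx]
                if len(np.unique(xb)) < 2 or np.all(yb == yb[0]):
                    boots_b[i], boots_s[i] = b, sigma
                    continue
                bb, ss, _, _ = self._fit_once(xb, yb)
                boots_b[i], boots_s[i] = bb, ss
        return PsychometricResults(boundary=b, slope=sigma, lapse=self.lapse,
                                   degenerate=degenerate, nll=nll,
                                   boot_boundaries=boots_b, boot_slopes=boots_s)

    def binned_points(self, bin_size: int = 5, n_boot: int = 1000,
                      seed: Optional[int] = None) -> pd.DataFrame:
        """Display points: trials sorted by position, binned ``bin_size`` per bin.

        Returns per-bin mean position, proportion of far-category
        responses, and a percentile bootstrap 95% CI over the trials in
        the bin.
        """
        rng = np.random.default_rng(seed)
        order = np.argsort(self.x, kind="stable")
        xs, ys = self.x[order], self.y[order]
        rows = []
        for start in range(0, len(xs), bin_size):
            xb, yb = xs[start:start + bin_size], ys[start:start + bin_size]
            lo, hi = bootstrap_proportion_ci(yb, rng=rng, n_boot=n_boot)
            rows.append({"position": float(xb.mean()), "proportion": float(yb.mean()),
                         "ci_low": lo, "ci_high": hi, "n": len(xb)})
        return pd.DataFrame(rows)


def bootstrap_proportion_ci(values, rng: Optional[np.random.Generator] = None,
                            n_boot: int = 1000, alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI of a mean; zero-width for constant input."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if np.all(values == values[0]):
        return float(values[0]), float(values[0])
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.integers(len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    return (float(np.percentile(means, 100 * alpha / 2)),
            float(np.percentile(means, 100 * (1 - alpha / 2))))
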