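"""Path-sampling marginal likelihoods and MCMC diagnostics.

Thermodynamic integration: the log marginal likelihood of a model equals the
integral over beta in [0, 1] of E_beta[log L], the expected data
log-likelihood under the power posterior at inverse temperature beta.  With
only a handful of temperatures the raw trapezoid rule is biased wherever the
path curves, which is worst on the hottest interval: there the corrected
estimate fits a hyperbolic path shape (exact for chi-square-like likelihood
behavior; a plateau-hugging Bezier curve as fallback) through the endpoints
and the cold-side slope and integrates it in closed form, while the colder
rungs are integrated under a shape-preserving cubic (PCHIP).  Below the
hottest available beta the path is extended flat — with the default hottest
temperature of 1e5 that strip has width 1e-5 and is negligible unless the
prior is absurdly diffuse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator


@dataclass
class MarginalLikelihood:
    log_ml: float
    log_ml_trapezoid: float
    path: dict                 # beta -> mean log likelihood
    method: str = "bezier"


def _bezier_segment_integral(b1: float, e1: float, b2: float, e2: float,
                             d2: float) -> float:
    """Integral over [b1, b2] of a cubic Bezier that hugs the cold-side
    plateau and dives to (b1, e1) only near the left edge.

    The expected log likelihood rises from its prior value very steeply on a
    scale of roughly 1/range(log L), so between the hottest two rungs the
    true path spends almost the entire interval near the plateau that the
    colder rungs extrapolate.  Control points: the hot-end handle is placed
    vertically above (b1, e1) at the plateau height projected with the
    cold-side slope ``d2``; the cold-end handle points back along that slope.
    """
    delta = b2 - b1
    y1 = max(e2 - d2 * delta, e1)  # projected plateau, never below the hot value
    px = np.array([b1, b1, b2 - delta / 3.0, b2])
    py = np.array([e1, y1, e2 - d2 * delta / 3.0, e2])
    nodes, weights = np.polynomial.legendre.leggauss(5)
    t = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    # cubic Bernstein basis and derivative of x(t)
    b0 = (1 - t) ** 3
    b1_ = 3 * t * (1 - t) ** 2
    b2_ = 3 * t**2 * (1 - t)
    b3 = t**3
    y = b0 * py[0] + b1_ * py[1] + b2_ * py[2] + b3 * py[3]
    dx = 3 * (
        (1 - t) ** 2 * (px[1] - px[0])
        + 2 * t * (1 - t) * (px[2] - px[1])
        + t**2 * (px[3] - px[2])
    )
    return float(np.sum(w * y * dx))


def _hyperbolic_segment_integral(b1: float, e1: float, b2: float, e2: float,
                                 b3: float, e3: float) -> float | None:
    """Integral over [b1, b2] of E(beta) = c - a/(beta + b), fitted through
    the three hottest rungs.

    This is the exact path shape when the log likelihood behaves like a
    scaled chi-square under the power posterior, and it interpolates
    naturally between the chord (gentle paths) and the plateau-with-dive
    shape (strongly curved paths).  The three-point fit has a closed form:
    the ratio of the two chord rises is linear in the pole position b.
    Returns None when the rungs are inconsistent with the form (caller
    falls back to the Bezier curve).
    """
    r12 = e2 - e1
    r23 = e3 - e2
    if r12 <= 0 or r23 <= 0:
        return None
    rho = r12 / r23
    denom = rho * (b3 - b2) - (b2 - b1)
    if denom <= 0:
        return None
    b = ((b2 - b1) * b3 - rho * (b3 - b2) * b1) / denom
    if b <= 0:
        return None
    a = r12 / (1.0 / (b1 + b) - 1.0 / (b2 + b))
    if a <= 0:
        return None
    c = e1 + a / (b1 + b)
    return float(c * (b2 - b1) - a * math.log((b2 + b) / (b1 + b)))


def bezier_marginal_likelihood(mean_loglik_by_beta: dict) -> MarginalLikelihood:
    """Corrected path-sampling estimate of the log marginal likelihood.

    ``mean_loglik_by_beta`` maps each inverse temperature (the cold chain at
    1, hotter chains toward 0) to its post-burn-in mean log likelihood.  The
    corrected estimate integrates a Bezier curve over the hottest interval
    (where the path is most strongly curved and a straight chord is badly
    biased) and a monotone cubic through the remaining rungs; below the
    hottest rung the path is extended flat.  The plain trapezoid estimate is
    returned alongside.
    """
    if len(mean_loglik_by_beta) < 2:
        raise ValueError("need at least two temperatures for path sampling")
    betas = np.array(sorted(mean_loglik_by_beta))
    if betas[-1] != 1.0:
        raise ValueError("the cold chain (beta = 1) is required")
    e = np.array([mean_loglik_by_beta[b] for b in betas])
    left_strip = betas[0] * e[0]  # flat extension on [0, beta_min]
    trap = float(np.trapezoid(e, betas) + left_strip)
    if np.allclose(e, e[0]):
        smooth = float(e[0] * (1.0 - betas[0]) + left_strip)
    else:
        if len(betas) >= 3:
            d2 = (e[2] - e[1]) / (betas[2] - betas[1])
            upper = PchipInterpolator(betas[1:], e[1:])
            upper_part = float(upper.integrate(betas[1], 1.0))
            lowest = _hyperbolic_segment_integral(
                betas[0], e[0], betas[1], e[1], betas[2], e[2]
            )
        else:
            d2 = (e[1] - e[0]) / (betas[1] - betas[0])
            upper_part = 0.0
            lowest = None
        if lowest is None:
            lowest = _bezier_segment_integral(betas[0], e[0], betas[1], e[1], d2)
        smooth = lowest + upper_part + left_strip
    return MarginalLikelihood(
        log_ml=smooth,
        log_ml_trapezoid=trap,
        path=dict(zip(betas.tolist(), e.tolist())),
    )


def ess(trace) -> float:
    """Effective sample size by initial-positive-sequence truncation.

    Sums autocorrelations over lags, pairing consecutive lags and truncating
    at the first pair with a nonpositive sum (Geyer's initial positive
    sequence); a constant trace has no autocorrelation structure to estimate
    and returns its length.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("trace too short")
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    if var == 0.0:
        return float(n)
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        k += 2
    return float(min(n / tau, n))


def psrf(traces) -> float:
    """Gelman-Rubin potential scale reduction factor across replicate chains."""
    arr = np.asarray([np.asarray(t, dtype=float) for t in traces])
    m, n = arr.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 traces of length >= 10")
    means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0.0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def hpd(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing the requested posterior mass."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    k = max(int(np.ceil(mass * n)), 2)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])
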