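"""Closed-form reflagging calibration curves and the PIUR inversion.

Split a provider's patients at random into two halves A and B and flag each
half at one-sided level p.  Under the null linear model with provider-level
reliability IUR = R, the two half-sample Z-scores (of any one profiling
method) are bivariate normal with correlation

    rho = R / (2 - R),

and the probability of being flagged again in B given a flag in A has the
closed form G(R) = Phi2_rho(s, s) / Phi(s), where Phi2_rho is the bivariate
standard-normal CDF and s depends on the method:

* fixed effects (FE):          s = -z_p * sqrt(1 - rho)   (half-sample
  Z_FE has variance 1/(1-rho))
* random effects / BLUP (RE):  s = -z_p * sqrt((1 - rho) / rho)
* FE with random intercept (FERE): s = -z_p   (Z_FERE is marginally N(0,1))

The profile IUR (PIUR) of an observed reflagging rate theta is the R~ that
solves G(R~) = theta: the reliability a pure null model would need in order
to reflag that consistently.  Under a contamination mixture in which a
fraction pi1 of providers carry a fixed effect gamma * sigma_T, the
theoretical FERE reflagging rate is

    theta = [pi0 * Phi2_rho(-z_p, -z_p) + pi1 * Phi(s_out)^2]
            / [pi0 * Phi(-z_p) + pi1 * Phi(s_out)],

    s_out = -z_p / sqrt(1 - rho) + gamma / sqrt(2 - 2R),

the outlier term using that, given a fixed outlier effect, the two
half-sample Z-scores are independent with mean gamma/sqrt(2-2R) after
standardisation.  Feeding theta back through the G_FERE inversion gives the
theoretical PIUR of the contaminated population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri, owens_t

__all__ = [
    "bvn_cdf",
    "rho_of_R",
    "G_fe",
    "G_re",
    "G_fere",
    "MixtureSpec",
    "PIURResult",
    "mixture_theta",
    "piur_from_theta",
    "theoretical_piur",
    "calibration_curve",
]

_R_MAX = 1.0 - 1e-9
_G_TOL = 1e-8


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """Standard bivariate normal CDF Phi2_rho(h, k) (lower orthant).

    Computed from Owen's T function (Owen, 1956):

        Phi2(h,k,rho) = [Phi(h) + Phi(k)] / 2 - T(h, a_h) - T(k, a_k) - d,

    with a_h = (k - rho*h) / (h * sqrt(1-rho^2)) and d = 1/2 when h*k < 0
    (or h*k = 0 with h + k < 0), else 0.  Accurate to ~1e-14, well inside
    the 1e-8 budget the calibration curves need.
    """
    if not abs(rho) < 1.0:
        raise ValueError("|rho| must be < 1 (perfect-correlation limits are handled by callers)")
    if rho == 0.0:
        return float(ndtr(h) * ndtr(k))
    # nudge exact zeros off the removable singularity of the Owen formula
    eps = 1e-13
    h = eps if h == 0.0 else h
    k = eps if k == 0.0 else k
    root = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * root)
    ak = (h - rho * k) / (k * root)
    # opposite-sign correction; compare signs directly (h*k underflows
    # to -0.0 for tiny arguments and would silently drop the 1/2)
    delta = 0.5 if (h < 0.0) != (k < 0.0) else 0.0
    val = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - delta
    return float(min(1.0, max(0.0, val)))


def rho_of_R(R: float) -> float:
    """Correlation of the two half-sample Z-scores at reliability R: R/(2-R)."""
    if not 0.0 <= R < 1.0:
        raise ValueError("R must be in [0, 1)")
    return R / (2.0 - R)


def _zp(p: float) -> float:
    if not 0.0 < p < 0.5:
        raise ValueError("p must be in (0, 0.5)")
    return float(-ndtri(p))  # upper-p standard normal quantile


def G_fe(R: float, p: float) -> float:
    """Conditional reflagging probability of the fixed-effects method."""
    zp = _zp(p)
    rho = rho_of_R(R)
    s1 = -zp * np.sqrt(1.0 - rho)
    return bvn_cdf(s1, s1, rho) / ndtr(s1)


def G_re(R: float, p: float) -> float:
    """Conditional reflagging probability of the shrinkage (BLUP) method.

    Undefined at R = 0: the fully shrunk score is identically zero, so no
    provider is ever flagged and the conditioning event is empty.  For
    very small R the flag probability Phi(s2) underflows and the returned
    ratio loses meaning; values are numerically reliable for R >~ 0.15 at
    conventional levels.
    """
    zp = _zp(p)
    if R <= 0.0:
        raise ValueError("G_re is undefined at R = 0 (RE flags nothing at the null)")
    rho = rho_of_R(R)
    s2 = -zp * np.sqrt((1.0 - rho) / rho)
    return bvn_cdf(s2, s2, rho) / ndtr(s2)


def G_fere(R: float, p: float) -> float:
    """Conditional reflagging probability of the marginal (FERE) method."""
    zp = _zp(p)
    rho = rho_of_R(R)
    return bvn_cdf(-zp, -zp, rho) / ndtr(-zp)


_G_FUNCS = {"FE": G_fe, "RE": G_re, "FERE": G_fere, "EN": G_fere}


def calibration_curve(method: str, p: float):
    """Return the G(R) evaluator for a profiling method.

    The empirical-null method calibrates against the FERE curve: when the
    null model holds the two flagging rules agree asymptotically.
    """
    key = method.upper()
    if key not in _G_FUNCS:
        raise ValueError(f"unknown profiling method {method!r}")
    g = _G_FUNCS[key]
    return lambda R: g(R, p)


@dataclass(frozen=True)
class MixtureSpec:
    """Contamination mixture for provider effects.

    A provider is an outlier with probability ``pi1``; outliers carry a
    fixed positive effect ``gamma * sigma_T`` (point mass), where
    sigma_T = sqrt(sigma_b^2 + sigma_w^2/n') is the total SD of a provider
    mean; the rest draw from N(0, sigma_b^2).  ``truncated_density``
    replaces the point mass by a half-normal shifted to a support bound C
    (default 2*sigma_b), for model-faithful simulation only — the closed
    forms in this module require the point mass.
    """

    pi1: float = 0.0
    gamma: float = 2.0
    sigma_T: float = 1.0
    outlier_kind: str = "point_mass"
    C: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi1 < 1.0:
            raise ValueError("pi1 must be in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.sigma_T <= 0:
            raise ValueError("sigma_T must be > 0")
        if self.outlier_kind not in ("point_mass", "truncated_density"):
            raise ValueError("outlier_kind must be point_mass or truncated_density")


@dataclass(frozen=True)
class PIURResult:
    """A calibrated reliability: G_method(piur) = theta_hat (unless clamped)."""

    piur: float
    theta_hat: float
    method: str
    p: float
    clamped: bool = False
    n_flagged_A: int | None = None

    def to_dict(self) -> dict:
        return {
            "piur": self.piur,
            "theta_hat": self.theta_hat,
            "method": self.method,
            "p": self.p,
            "clamped": self.clamped,
            "n_flagged_A": self.n_flagged_A,
        }


def mixture_theta(R: float, mix: MixtureSpec, p: float) -> float:
    """Theoretical FERE reflagging rate under the contamination mixture."""
    if mix.outlier_kind != "point_mass":
        raise NotImplementedError(
            "no closed form for truncated_density outliers; use the split-half simulation route"
        )
    zp = _zp(p)
    rho = rho_of_R(R)
    s = -zp / np.sqrt(1.0 - rho) + mix.gamma / np.sqrt(2.0 - 2.0 * R)
    pi1 = mix.pi1
    pi0 = 1.0 - pi1
    phi_s = ndtr(s)
    num = pi0 * bvn_cdf(-zp, -zp, rho) + pi1 * phi_s**2
    den = pi0 * ndtr(-zp) + pi1 * phi_s
    return float(num / den)


def piur_from_theta(theta: float, p: float, method: str = "FERE") -> PIURResult:
    """Invert G_method to put a reflagging rate on the IUR scale.

    Bracketed root-finding on R in [0, 1); rates at or below the null
    reflagging rate G(0) clamp to 0, rates at or above the R -> 1 limit
    clamp to just below 1.  The tolerance is on G (|G(R~) - theta| <= 1e-8),
    not on R, because G is nearly flat near 0 for small p.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    g = calibration_curve(method, p)
    lo = 1e-12 if method.upper() == "RE" else 0.0
    g_lo, g_hi = g(lo), g(_R_MAX)
    if theta <= g_lo:
        return PIURResult(0.0, theta, method, p, clamped=True)
    if theta >= g_hi:
        return PIURResult(_R_MAX, theta, method, p, clamped=True)
    root = brentq(lambda R: g(R) - theta, lo, _R_MAX, xtol=1e-13, rtol=8.9e-16)
    if abs(g(root) - theta) > _G_TOL:
        raise RuntimeError("calibration inversion failed to reach tolerance")
    return PIURResult(float(root), theta, method, p, clamped=False)


def theoretical_piur(R: float, mix: MixtureSpec, p: float) -> float:
    """Theoretical PIUR of a contaminated population with base reliability R."""
    return piur_from_theta(mixture_theta(R, mix, p), p, "FERE").piur
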