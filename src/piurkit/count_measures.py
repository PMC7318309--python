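"""PIUR for standardized-ratio quality measures (SMR/SRR-style O/E data).

Count measures compare a provider's observed event count O_i with a
model-based expectation E_i computed under a population norm; the
standardized ratio O_i/E_i (an SMR when the events are deaths, an SRR for
readmissions) exceeds 1 when the provider does worse than the national
rate.  Under the null that the provider's rate equals the population rate,
O_i is approximately Poisson(E_i), giving exact tail P-values and the
normal-approximation Z-score (O - E)/sqrt(E).

These Z-scores feed the same empirical-null machinery as the linear model:
fit N(mu_M, sigma_M^2) robustly to the central Z-scores, flag providers
with Z > mu_M + z_p * sigma_M, and estimate the PIUR by half-splitting
each provider's patients (carrying their expecteds with them), reflagging
both halves, and referring the pooled reflagging rate to the FERE
calibration curve.

Only patient-level (y, e) pairs support splitting; ratio-only (O, E)
tables support the ratio and P-value operations but not the PIUR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtri
from scipy.stats import poisson

from .calibration import MixtureSpec, PIURResult, piur_from_theta
from .core_model import VarianceComponents, n_prime
from .profiling import fit_empirical_null
from .simulator import SimTruth, SizeModel, sample_provider_effects, sample_sizes

logger = logging.getLogger("piurkit")

__all__ = [
    "CountMeasureData",
    "standardized_ratio",
    "poisson_pvalue",
    "count_z",
    "simulate_count_panel",
    "piur_counts",
]


@dataclass(frozen=True)
class CountMeasureData:
    """One provider's patient-level events y_ij and expecteds e_ij."""

    provider_id: str
    y: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        e = np.asarray(self.e, dtype=float)
        if y.shape != e.shape:
            raise ValueError("y and e must have the same length")
        if np.any(y < 0):
            raise ValueError("event counts must be non-negative")
        if np.any(e <= 0):
            raise ValueError("expecteds must be > 0")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "e", e)

    @property
    def O(self) -> int:
        return int(self.y.sum())

    @property
    def E(self) -> float:
        return float(self.e.sum())


def standardized_ratio(data: CountMeasureData) -> float:
    """O/E: the SMR/SRR-style standardized ratio."""
    if data.E <= 0:
        raise ValueError("E must be > 0")
    return data.O / data.E


def poisson_pvalue(O: int, E: float, mid_p: bool = False) -> float:
    """Upper-tail Poisson P-value: Pr(Poisson(E) >= O).

    With ``mid_p``, returns Pr(> O) + Pr(= O)/2, which halves the
    conservatism of the exact tail for discrete counts.
    """
    if E <= 0:
        raise ValueError("E must be > 0")
    if mid_p:
        return float(poisson.sf(O, E) + 0.5 * poisson.pmf(O, E))
    return float(poisson.sf(O - 1, E))


def count_z(O, E, exact: bool = False):
    """FE-type Z-score for a count measure.

    Default is the Poisson normal approximation (O - E)/sqrt(E); with
    ``exact`` the mid-p Poisson tail is converted to a normal quantile,
    which behaves better for small E.  Vectorised over O, E.
    """
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("E must be > 0")
    if exact:
        p = poisson.sf(O, E) + 0.5 * poisson.pmf(O, E)
        out = -ndtri(np.clip(p, 1e-300, 1 - 1e-16))
    else:
        out = (O - E) / np.sqrt(E)
    return float(out) if out.ndim == 0 else out


def simulate_count_panel(
    m: int,
    size_model: SizeModel | None = None,
    rate_model: tuple[float, float] = (2.0, 0.10),
    mix: MixtureSpec | None = None,
    sigma_b2: float = 0.0,
    rng_seed: int | None = 0,
) -> tuple[list[CountMeasureData], SimTruth]:
    """Synthetic O/E panel with multiplicative provider effects.

    Patient expecteds e_ij ~ Gamma(shape, scale) from ``rate_model``
    (default mean 0.2 events per patient, giving facility expecteds around
    20 — the scale of annual dialysis mortality);
    events y_ij ~ Poisson(e_ij * exp(alpha_i)) with alpha_i drawn from the
    contamination mixture on the log-rate scale (sigma_b2 is the null
    between-provider variance of alpha).  A stand-in for the national
    risk-model pipelines that produce real expecteds.
    """
    rng = np.random.default_rng(rng_seed)
    size_model = size_model or SizeModel()
    sizes = sample_sizes(size_model, m, rng)
    shape, scale = rate_model
    mean_e = shape * scale
    # sigma_T on the Z scale: sd of (O-E)/sqrt(E) across providers at the
    # effective average size, sqrt(1 + E_i * sigma_b2) ~ linearised
    np_eff = n_prime(sizes)
    sigma_T = float(np.sqrt(sigma_b2 * mean_e * np_eff + 1.0) / np.sqrt(mean_e * np_eff))
    if mix is not None and mix.sigma_T != sigma_T:
        mix = MixtureSpec(mix.pi1, mix.gamma, sigma_T, mix.outlier_kind, mix.C)
    alphas, outliers = sample_provider_effects(m, sigma_b2, mix, rng)

    panel = []
    for i in range(m):
        e = rng.gamma(shape, scale, size=sizes[i])
        y = rng.poisson(e * np.exp(alphas[i]))
        panel.append(CountMeasureData(f"P{i + 1:05d}", y, e))
    truth = SimTruth(
        alphas=alphas,
        outlier_flags=outliers,
        sigma_b2=float(sigma_b2),
        sigma_T=sigma_T,
        components=VarianceComponents(0.0, (), max(float(sigma_b2), 0.0), 1.0),
    )
    return panel, truth


def _split_counts(
    data: CountMeasureData, rng: np.random.Generator
) -> tuple[tuple[int, float], tuple[int, float]]:
    """Random half-split of one provider's patients; conserves O and E."""
    n = data.y.size
    perm = rng.permutation(n)
    n_a = (n + 1) // 2 if rng.random() < 0.5 else n // 2
    a = perm[:n_a]
    O_a = int(data.y[a].sum())
    E_a = float(data.e[a].sum())
    return (O_a, E_a), (data.O - O_a, data.E - E_a)


def piur_counts(
    panel: Sequence[CountMeasureData],
    p: float = 0.025,
    n_splits: int = 200,
    rng_seed: int | None = 0,
    min_expected: float = 3.0,
    min_split_size: int = 2,
    exact_z: bool = True,
) -> PIURResult:
    """Empirical-null PIUR for a count measure via patient half-splits.

    Providers with full-panel E below ``min_expected`` (default 3, the
    usual facility-exclusion rule) or fewer than ``min_split_size``
    patients are excluded.  Per split: per-half (O, E) -> Z-scores -> an
    empirical null fitted within each half -> flags; the pooled reflagging
    rate is referred to the FERE calibration curve.

    Half-sample Z-scores default to the exact-tail form (mid-p Poisson
    tail mapped to a normal quantile): half-sample expecteds are small and
    the (O - E)/sqrt(E) approximation is right-skewed there, which would
    inflate the reflagging rate of a perfectly null panel.
    """
    keep = [d for d in panel if d.E >= min_expected and d.y.size >= min_split_size]
    dropped = len(panel) - len(keep)
    if dropped:
        logger.info("excluding %d providers (E < %.3g or too few patients)", dropped, min_expected)
    if len(keep) < 30:
        raise ValueError("too few eligible providers for an empirical-null PIUR")
    rng = np.random.default_rng(rng_seed)
    zp = float(-ndtri(p))
    cond = 0
    both = 0
    for _ in range(n_splits):
        halves = [_split_counts(d, rng) for d in keep]
        OA = np.array([h[0][0] for h in halves], dtype=float)
        EA = np.array([h[0][1] for h in halves])
        OB = np.array([h[1][0] for h in halves], dtype=float)
        EB = np.array([h[1][1] for h in halves])
        zA = count_z(OA, EA, exact=exact_z)
        zB = count_z(OB, EB, exact=exact_z)
        try:
            nullA = fit_empirical_null(zA)
            nullB = fit_empirical_null(zB)
        except RuntimeError:
            nullA = fit_empirical_null(zA, fit_method="huber")
            nullB = fit_empirical_null(zB, fit_method="huber")
        fA = zA > nullA.mu_M + zp * nullA.sigma_M
        fB = zB > nullB.mu_M + zp * nullB.sigma_M
        cond += int(fA.sum()) + int(fB.sum())
        both += 2 * int((fA & fB).sum())
    if cond == 0:
        raise ValueError("reflagging rate undefined: no provider was ever flagged")
    theta = both / cond
    res = piur_from_theta(theta, p, "FERE")
    return PIURResult(
        piur=res.piur, theta_hat=theta, method="EN", p=p,
        clamped=res.clamped, n_flagged_A=cond,
    )
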