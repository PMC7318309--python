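"""Split-half reflagging: the empirical route to the PIUR.

The procedure: randomly divide each provider's patients into two nearly
equal halves A and B; flag each half with the configured profiling method
at one-sided level p; repeat many times; the empirical reflagging rate
theta_hat is the pooled probability of being flagged in one half given a
flag in the other.  Referring theta_hat to the null calibration curve
G(R) of the method (EN calibrates against the FERE curve) and solving
G(R~) = theta_hat puts the rate on the IUR scale: R~ is the empirical PIUR.

Conventions:

* theta_hat pools flag events over all providers and all splits (the
  overall-IUR calibration target), with both conditional directions (B|A
  and A|B) counted — the two are exchangeable by construction and the
  symmetrisation halves the Monte-Carlo variance.
* Variance components for FE/RE/FERE half-sample Z-scores are estimated
  once from the full panel by ANOVA (or supplied); the empirical null is
  refitted inside each half because half-sample Z-scores have a different
  null variance.
* Half-sample Z-scores use the actual half sizes ceil(n_i/2)/floor(n_i/2);
  providers below ``min_split_size`` patients are excluded from splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .calibration import PIURResult, piur_from_theta
from .core_model import (
    ProviderPanel,
    VarianceComponents,
    estimate_variance_components,
)
from .profiling import FlagConfig, fit_empirical_null, z_fe, z_fere, z_re

logger = logging.getLogger("piurkit")

__all__ = [
    "SplitReflagEstimate",
    "split_panel",
    "reflag_once",
    "estimate_theta",
    "empirical_piur",
]


@dataclass(frozen=True)
class SplitReflagEstimate:
    """Pooled reflagging bookkeeping; theta_hat is NaN when nothing was flagged."""

    theta_hat: float
    n_splits: int
    flagged_A_total: int
    reflagged_total: int
    per_provider_rates: Mapping[str, tuple[int, int]]
    rng_seed: int | None

    @property
    def defined(self) -> bool:
        return self.flagged_A_total > 0


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _eligible(panel: ProviderPanel, min_split_size: int) -> np.ndarray:
    keep = panel.sizes >= min_split_size
    if not keep.all():
        logger.info(
            "excluding %d providers below min_split_size=%d from splitting",
            int((~keep).sum()), min_split_size,
        )
    return keep


def _half_masks(
    panel: ProviderPanel, rng: np.random.Generator
) -> np.ndarray:
    """Boolean record mask: True -> half A.

    Per provider, a uniformly random partition into ceil(n/2) and
    floor(n/2); for odd n a fair coin decides which half gets the extra
    patient.  Vectorised: rank records by a uniform draw within each
    provider block (the panel is stored provider-contiguous).
    """
    u = rng.random(panel.n_records)
    order = np.lexsort((u, panel.codes))
    rank = np.arange(panel.n_records) - np.repeat(panel.starts, panel.sizes)
    coin = rng.random(panel.m) < 0.5
    n_a = np.where(coin, (panel.sizes + 1) // 2, panel.sizes // 2)
    in_a = np.empty(panel.n_records, dtype=bool)
    in_a[order] = rank < np.repeat(n_a, panel.sizes)
    return in_a


def split_panel(
    panel: ProviderPanel,
    rng: np.random.Generator,
    min_split_size: int = 2,
) -> tuple[ProviderPanel, ProviderPanel]:
    """One random half-split, returned as two panels (A, B).

    Providers with fewer than ``min_split_size`` patients are dropped from
    both halves (logged, not an error).
    """
    keep_records = np.repeat(_eligible(panel, min_split_size), panel.sizes)
    in_a = _half_masks(panel, rng) & keep_records
    in_b = ~in_a & keep_records
    ids = panel.providers[panel.codes]

    def build(mask: np.ndarray) -> ProviderPanel:
        return ProviderPanel(
            ids[mask],
            panel.y_raw[mask],
            X=None if panel.X is None else panel.X[mask],
            y_adjusted=None if panel.y_adjusted is None else panel.y_adjusted[mask],
        )

    return build(in_a), build(in_b)


# ---------------------------------------------------------------------------
# Flagging both halves
# ---------------------------------------------------------------------------

def _half_flags(
    y_sum: np.ndarray,
    n_half: np.ndarray,
    config: FlagConfig,
    comp: VarianceComponents,
) -> np.ndarray:
    """Flags for one half, from per-provider sums and half sizes."""
    y_bar = y_sum / n_half
    zfe = z_fe(y_bar, comp.sigma_w2, n_half)
    if config.method == "FE":
        z, upper, lower = zfe, config.z_p, -config.z_p
    elif config.method == "RE":
        iur_half = comp.sigma_b2 / (comp.sigma_b2 + comp.sigma_w2 / n_half)
        z, upper, lower = z_re(zfe, iur_half), config.z_p, -config.z_p
    elif config.method == "FERE":
        z = z_fere(y_bar, comp.sigma_b2, comp.sigma_w2, n_half)
        upper, lower = config.z_p, -config.z_p
    else:  # EN: refit the null on this half's FE Z-scores
        try:
            null = fit_empirical_null(zfe)
        except RuntimeError as exc:
            # the truncated MLE can fail to exist on small flat half-samples;
            # fall back to the Huber route for this half
            logger.info("EN half refit fell back to Huber: %s", exc)
            null = fit_empirical_null(zfe, fit_method="huber")
        z = zfe
        upper = null.mu_M + config.z_p * null.sigma_M
        lower = null.mu_M - config.z_p * null.sigma_M
    return z > upper if config.direction == "worse" else z < lower


def reflag_once(
    panel: ProviderPanel,
    config: FlagConfig,
    components: VarianceComponents,
    rng: np.random.Generator,
    min_split_size: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One split: returns (eligible_mask, flagged_A, flagged_B) over providers."""
    if panel.y_adjusted is None:
        raise ValueError("panel is not risk-adjusted")
    eligible = _eligible(panel, min_split_size)
    in_a = _half_masks(panel, rng)
    w = in_a.astype(float)
    y = panel.y_adjusted
    sum_a = np.bincount(panel.codes, weights=y * w, minlength=panel.m)
    n_a = np.bincount(panel.codes, weights=w, minlength=panel.m)
    sum_b = np.bincount(panel.codes, weights=y, minlength=panel.m) - sum_a
    n_b = panel.sizes - n_a
    fa = np.zeros(panel.m, dtype=bool)
    fb = np.zeros(panel.m, dtype=bool)
    fa[eligible] = _half_flags(sum_a[eligible], n_a[eligible], config, components)
    fb[eligible] = _half_flags(sum_b[eligible], n_b[eligible], config, components)
    return eligible, fa, fb


# ---------------------------------------------------------------------------
# Pooled reflagging rate and the empirical PIUR
# ---------------------------------------------------------------------------

def estimate_theta(
    panel: ProviderPanel,
    config: FlagConfig,
    components: VarianceComponents | None = None,
    n_splits: int = 200,
    rng_seed: int | None = 0,
    min_split_size: int = 2,
) -> SplitReflagEstimate:
    """Empirical reflagging rate over repeated random half-splits.

    theta_hat = (# flagged in both halves, both directions) /
    (# flagged in the conditioning half), pooled over providers and
    splits.  When no provider is ever flagged the rate is undefined and
    returned as NaN (``.defined`` is False).
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if components is None:
        est = estimate_variance_components(panel)
        components = VarianceComponents(
            mu=0.0, beta=(), sigma_b2=est.sigma_b2_hat, sigma_w2=est.sigma_w2_hat
        )
    rng = np.random.default_rng(rng_seed)
    cond = np.zeros(panel.m, dtype=int)   # times flagged in a conditioning half
    both = np.zeros(panel.m, dtype=int)   # times reflagged in the other half
    for _ in range(n_splits):
        _, fa, fb = reflag_once(panel, config, components, rng, min_split_size)
        # int cast first: numpy bool + bool is logical OR, not a count
        cond += fa.astype(np.int64) + fb.astype(np.int64)
        both += 2 * (fa & fb).astype(np.int64)
    flagged_total = int(cond.sum())
    reflagged_total = int(both.sum())
    theta = reflagged_total / flagged_total if flagged_total > 0 else float("nan")
    per = {
        str(pid): (int(c), int(b))
        for pid, c, b in zip(panel.providers.tolist(), cond, both)
    }
    return SplitReflagEstimate(
        theta_hat=theta,
        n_splits=n_splits,
        flagged_A_total=flagged_total,
        reflagged_total=reflagged_total,
        per_provider_rates=per,
        rng_seed=rng_seed,
    )


def empirical_piur(
    panel: ProviderPanel,
    config: FlagConfig,
    n_splits: int = 200,
    rng_seed: int | None = 0,
    components: VarianceComponents | None = None,
    min_split_size: int = 2,
) -> PIURResult:
    """Algorithm-level composition: split-half theta_hat -> G inversion.

    The empirical-null method calibrates against the FERE curve (the two
    flagging rules coincide asymptotically under the null model).
    """
    est = estimate_theta(panel, config, components, n_splits, rng_seed, min_split_size)
    if not est.defined:
        raise ValueError(
            "reflagging rate undefined: no provider was ever flagged; "
            "use a larger panel or a higher p"
        )
    method = "FERE" if config.method == "EN" else config.method
    res = piur_from_theta(est.theta_hat, config.p, method)
    return PIURResult(
        piur=res.piur,
        theta_hat=est.theta_hat,
        method=config.method,
        p=config.p,
        clamped=res.clamped,
        n_flagged_A=est.flagged_A_total,
    )
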