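"""Synthetic panels from the contamination model.

Generates patient-level outcomes Y_ij = mu + alpha_i + X_ij' beta + eps_ij
with eps_ij ~ N(0, sigma_w2) and provider effects drawn from the mixture

    f(alpha) = pi0 * N(0, sigma_b^2) + pi1 * f1(alpha),

where f1 places outlying providers at a fixed positive effect
gamma * sigma_T (point mass; what the study designs use) or at a draw from
a half-normal shifted to a support bound C (default 2*sigma_b), and
sigma_T = sqrt(sigma_b^2 + sigma_w^2/n') is the total SD of a provider mean
at the effective average size n' of the realised size vector.

The between-variance can be specified directly or resolved from a target
overall IUR; provider sizes are either fixed (default 100) or drawn as
round(N(100, 50)) floored at 10, the two size regimes of the study designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import MixtureSpec
from .core_model import ProviderPanel, VarianceComponents, n_prime

__all__ = [
    "SizeModel",
    "SimulationConfig",
    "SimTruth",
    "resolve_sigma_b2",
    "sample_sizes",
    "sample_provider_effects",
    "simulate_panel",
]


@dataclass(frozen=True)
class SizeModel:
    """Provider size distribution: fixed n, or rounded-normal with a floor."""

    kind: str = "fixed"
    n_fixed: int = 100
    mean: float = 100.0
    sd: float = 50.0
    floor: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "normal_rounded"):
            raise ValueError("kind must be 'fixed' or 'normal_rounded'")
        if self.floor < 1:
            raise ValueError("floor must be >= 1")
        if self.kind == "fixed" and self.n_fixed < 1:
            raise ValueError("n_fixed must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic panel.

    Exactly one of ``target_iur`` / ``sigma_b2`` must be given.  When
    ``beta`` is non-empty, covariates are generated with provider-level
    means correlated with alpha_i (coefficient ``confounding``), the
    scenario in which pooled OLS is biased and the within-provider
    (fixed-effects) estimator is not.
    """

    m: int = 1000
    size_model: SizeModel = field(default_factory=SizeModel)
    sigma_w2: float = 1.0
    target_iur: float | None = None
    sigma_b2: float | None = None
    mix: MixtureSpec | None = None
    beta: tuple[float, ...] = ()
    confounding: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.sigma_w2 <= 0:
            raise ValueError("sigma_w2 must be > 0")
        if (self.target_iur is None) == (self.sigma_b2 is None):
            raise ValueError("specify exactly one of target_iur or sigma_b2")
        if self.target_iur is not None and not 0.0 <= self.target_iur < 1.0:
            raise ValueError("target_iur must be in [0, 1)")
        if self.sigma_b2 is not None and self.sigma_b2 < 0:
            raise ValueError("sigma_b2 must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind one simulated panel."""

    alphas: np.ndarray
    outlier_flags: np.ndarray
    sigma_b2: float
    sigma_T: float
    components: VarianceComponents

    @property
    def target_iur_realized(self) -> float:
        return self.sigma_b2 / self.sigma_T**2 if self.sigma_T > 0 else 0.0


def resolve_sigma_b2(target_iur: float, sigma_w2: float, sizes) -> float:
    """Between-variance that yields a given overall IUR at the realised sizes.

    Inverts IUR = sigma_b^2 / (sigma_b^2 + sigma_w^2/n'):
    sigma_b^2 = (sigma_w^2 / n') * R / (1 - R).
    """
    if not 0.0 <= target_iur < 1.0:
        raise ValueError("target_iur must be in [0, 1)")
    return (sigma_w2 / n_prime(sizes)) * target_iur / (1.0 - target_iur)


def sample_sizes(size_model: SizeModel, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw m provider sizes from the configured size model."""
    if m < 2:
        raise ValueError("m must be >= 2")
    if size_model.kind == "fixed":
        return np.full(m, size_model.n_fixed, dtype=int)
    n = np.rint(rng.normal(size_model.mean, size_model.sd, size=m)).astype(int)
    return np.maximum(n, size_model.floor)


def sample_provider_effects(
    m: int,
    sigma_b2: float,
    mix: MixtureSpec | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw provider effects from the contamination mixture.

    Returns (alphas, outlier_flags).  Outliers are one-sided positive
    (worse-than-expected), matching the upper-tail flagging convention.
    ``mix.sigma_T`` must already be resolved against the realised sizes.
    """
    sigma_b = np.sqrt(sigma_b2)
    alphas = rng.normal(0.0, sigma_b, size=m)
    if mix is None or mix.pi1 == 0.0:
        return alphas, np.zeros(m, dtype=bool)
    outlier = rng.random(m) < mix.pi1
    k = int(outlier.sum())
    if mix.outlier_kind == "point_mass":
        alphas[outlier] = mix.gamma * mix.sigma_T
    else:
        C = mix.C if mix.C is not None else 2.0 * sigma_b
        if C <= 0:
            raise ValueError("truncated_density outliers need a support bound C > 0")
        # half-normal of scale gamma*sigma_T shifted to alpha > C
        alphas[outlier] = C + np.abs(rng.normal(0.0, mix.gamma * mix.sigma_T, size=k))
    return alphas, outlier


def simulate_panel(
    config: SimulationConfig, rng_seed: int | np.random.Generator | None = None
) -> tuple[ProviderPanel, SimTruth]:
    """Generate one panel plus its ground truth; reproducible from the seed."""
    if isinstance(rng_seed, np.random.Generator):
        rng = rng_seed
    else:
        rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)

    sizes = sample_sizes(config.size_model, config.m, rng)
    np_eff = n_prime(sizes)
    if config.sigma_b2 is not None:
        sigma_b2 = config.sigma_b2
    else:
        sigma_b2 = resolve_sigma_b2(config.target_iur, config.sigma_w2, sizes)
    sigma_T = float(np.sqrt(sigma_b2 + config.sigma_w2 / np_eff))
    mix = config.mix
    if mix is not None and mix.sigma_T != sigma_T:
        mix = MixtureSpec(mix.pi1, mix.gamma, sigma_T, mix.outlier_kind, mix.C)

    alphas, outliers = sample_provider_effects(config.m, sigma_b2, mix, rng)

    total = int(sizes.sum())
    codes = np.repeat(np.arange(config.m), sizes)
    eps = rng.normal(0.0, np.sqrt(config.sigma_w2), size=total)
    y = alphas[codes] + eps

    beta = np.asarray(config.beta, dtype=float)
    X = None
    if beta.size:
        # provider-level covariate means tied to alpha_i plus patient scatter
        xbar = config.confounding * alphas[:, None] + rng.normal(
            0.0, 1.0, size=(config.m, beta.size)
        )
        X = xbar[codes] + rng.normal(0.0, 1.0, size=(total, beta.size))
        y = y + X @ beta

    ids = np.char.add("P", np.char.zfill((np.arange(config.m) + 1).astype(str), 5))
    panel = ProviderPanel(ids[codes], y, X=X, y_adjusted=None if beta.size else y)
    truth = SimTruth(
        alphas=alphas,
        outlier_flags=outliers,
        sigma_b2=float(sigma_b2),
        sigma_T=sigma_T,
        components=VarianceComponents(
            mu=0.0, beta=tuple(beta.tolist()), sigma_b2=float(sigma_b2),
            sigma_w2=config.sigma_w2,
        ),
    )
    return panel, truth
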