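"""Linear model for provider profiling: risk adjustment and ANOVA-based IUR.

The working model for a continuous quality measure is

    Y*_ij = mu + alpha_i + X_ij' beta + eps_ij,

with provider effects alpha_i ~ N(0, sigma_b^2) and patient-level noise
eps_ij ~ N(0, sigma_w^2); i indexes providers (i = 1..m) and j patients
within provider i (j = 1..n_i).  Large values of Y* are read as poor
outcomes.  After risk adjustment, Y_ij = Y*_ij - mu - X_ij' beta, the model
reduces to Y_ij = alpha_i + eps_ij and the provider mean Ybar_i estimates
alpha_i.

The inter-unit reliability (IUR) of the measure for a provider of size n is
the intraclass-correlation-type ratio

    IUR_n = sigma_b^2 / (sigma_b^2 + sigma_w^2 / n),

the share of the variance of Ybar_i attributable to real between-provider
differences.  The overall IUR replaces n by the effective average size n'
from the one-way ANOVA expectation E(SSB) = (m-1)(sigma_w^2 + n' sigma_b^2).

Variance components are estimated by ANOVA moments (method of moments on
the between/within sums of squares), not REML: the development of the IUR
is entirely in terms of SSB, and moments keep the estimator closed-form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("piurkit")

__all__ = [
    "PatientOutcome",
    "ProviderPanel",
    "VarianceComponents",
    "IUREstimate",
    "estimate_beta_fixed_effects",
    "center_mu",
    "risk_adjust",
    "provider_means",
    "n_prime",
    "estimate_variance_components",
    "read_panel",
]


@dataclass(frozen=True)
class PatientOutcome:
    """A single patient record: raw outcome, covariates, optional adjusted value."""

    provider_id: str
    y_raw: float
    covariates: tuple[float, ...] = ()
    y_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not self.provider_id:
            raise ValueError("provider_id must be non-empty")
        if not np.isfinite(self.y_raw):
            raise ValueError("y_raw must be finite")
        if not all(np.isfinite(c) for c in self.covariates):
            raise ValueError("covariates must be finite")


class ProviderPanel:
    """Patient-level outcomes grouped by provider.

    Internally the panel is stored sorted by provider so that each provider
    occupies a contiguous block; this makes the group-wise reductions used
    throughout (means, variance components, half-splits) cheap vectorised
    operations.

    Parameters
    ----------
    provider_ids : sequence of str, one per record
    y_raw : array of raw outcomes, one per record
    X : optional (N, k) covariate matrix
    y_adjusted : optional array of risk-adjusted outcomes
    """

    def __init__(
        self,
        provider_ids: Sequence[str],
        y_raw: np.ndarray,
        X: np.ndarray | None = None,
        y_adjusted: np.ndarray | None = None,
    ) -> None:
        ids = np.asarray(provider_ids)
        y = np.asarray(y_raw, dtype=float)
        if ids.shape[0] != y.shape[0]:
            raise ValueError("provider_ids and y_raw lengths differ")
        if not np.all(np.isfinite(y)):
            raise ValueError("y_raw contains non-finite values")
        uniq, codes = np.unique(ids, return_inverse=True)
        if uniq.size < 2:
            raise ValueError("a panel needs at least m >= 2 providers")
        order = np.argsort(codes, kind="stable")
        self.providers: np.ndarray = uniq
        self.codes: np.ndarray = codes[order]
        self.y_raw: np.ndarray = y[order]
        if X is not None:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[0] != y.shape[0]:
                raise ValueError("X and y_raw lengths differ")
            if not np.all(np.isfinite(X)):
                raise ValueError("covariates contain non-finite values")
            X = X[order]
        self.X: np.ndarray | None = X
        if y_adjusted is not None:
            y_adjusted = np.asarray(y_adjusted, dtype=float)[order]
        self.y_adjusted: np.ndarray | None = y_adjusted
        self.sizes: np.ndarray = np.bincount(self.codes, minlength=uniq.size)
        self.starts: np.ndarray = np.concatenate(([0], np.cumsum(self.sizes)[:-1]))

    # -- basic descriptors -------------------------------------------------
    @property
    def m(self) -> int:
        return int(self.providers.size)

    @property
    def n_records(self) -> int:
        return int(self.y_raw.size)

    @property
    def n_covariates(self) -> int:
        return 0 if self.X is None else self.X.shape[1]

    def __len__(self) -> int:
        return self.n_records

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ProviderPanel(m={self.m}, records={self.n_records}, "
            f"covariates={self.n_covariates}, "
            f"adjusted={self.y_adjusted is not None})"
        )

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[PatientOutcome]) -> "ProviderPanel":
        ids = [r.provider_id for r in records]
        y = np.array([r.y_raw for r in records], dtype=float)
        k = len(records[0].covariates) if records else 0
        if any(len(r.covariates) != k for r in records):
            raise ValueError("records have inconsistent covariate dimension")
        X = np.array([r.covariates for r in records], dtype=float) if k else None
        adj = None
        if all(r.y_adjusted is not None for r in records):
            adj = np.array([r.y_adjusted for r in records], dtype=float)
        return cls(ids, y, X, adj)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates: Sequence[str] = (),
        id_col: str = "provider_id",
        y_col: str = "y",
    ) -> "ProviderPanel":
        for col in [id_col, y_col, *covariates]:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        bad = df[[y_col, *covariates]].isna()
        if bad.any().any():
            rows = list(df.index[bad.any(axis=1)][:10])
            raise ValueError(f"missing values in rows {rows}")
        X = df[list(covariates)].to_numpy(dtype=float) if covariates else None
        return cls(df[id_col].astype(str).to_numpy(), df[y_col].to_numpy(dtype=float), X)

    def with_adjusted(self, y_adjusted: np.ndarray) -> "ProviderPanel":
        out = ProviderPanel.__new__(ProviderPanel)
        out.providers = self.providers
        out.codes = self.codes
        out.y_raw = self.y_raw
        out.X = self.X
        out.y_adjusted = np.asarray(y_adjusted, dtype=float)
        out.sizes = self.sizes
        out.starts = self.starts
        return out

    def group_means(self, values: np.ndarray) -> np.ndarray:
        """Per-provider arithmetic mean of a per-record array."""
        return np.bincount(self.codes, weights=values, minlength=self.m) / self.sizes


def read_panel(path: str, covariates: Sequence[str] = ()) -> ProviderPanel:
    """Read a delimited text panel (CSV, or TSV for a ``.tsv`` extension)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    return ProviderPanel.from_dataframe(pd.read_csv(path, sep=sep), covariates)


@dataclass(frozen=True)
class VarianceComponents:
    """Parameters (mu, beta, sigma_b^2, sigma_w^2) of the linear model."""

    mu: float = 0.0
    beta: tuple[float, ...] = ()
    sigma_b2: float = 0.0
    sigma_w2: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_w2 <= 0:
            raise ValueError("sigma_w2 must be > 0")
        if self.sigma_b2 < 0:
            raise ValueError("sigma_b2 must be >= 0")


@dataclass(frozen=True)
class IUREstimate:
    """ANOVA variance components plus the overall and per-provider IURs."""

    sigma_b2_hat: float
    sigma_w2_hat: float
    n_prime: float
    overall_iur: float
    per_provider_iur: Mapping[str, float]
    ssb: float
    grand_mean: float

    def to_dict(self) -> dict:
        return {
            "sigma_b2": self.sigma_b2_hat,
            "sigma_w2": self.sigma_w2_hat,
            "n_prime": self.n_prime,
            "iur_overall": self.overall_iur,
            "iur_by_provider": dict(self.per_provider_iur),
        }


# ---------------------------------------------------------------------------
# Risk adjustment
# ---------------------------------------------------------------------------

def estimate_beta_fixed_effects(panel: ProviderPanel) -> np.ndarray:
    """Within-provider (fixed-effects) least-squares coefficients.

    Demeaning outcome and covariates within each provider is equivalent to
    fitting one indicator per provider; it protects beta from bias when
    patient characteristics are correlated with provider effects.  Returns
    an empty vector when the panel carries no covariates.
    """
    if panel.X is None:
        return np.empty(0)
    Xd = panel.X - _expand(panel, _colwise_group_means(panel, panel.X))
    yd = panel.y_raw - np.repeat(panel.group_means(panel.y_raw), panel.sizes)
    k = Xd.shape[1]
    dof = panel.n_records - panel.m
    if dof < k:
        raise ValueError("not enough within-provider degrees of freedom for beta")
    rank = np.linalg.matrix_rank(Xd)
    if rank < k:
        from scipy.linalg import qr

        _, _, piv = qr(Xd, mode="economic", pivoting=True)
        dep = sorted(int(j) for j in piv[rank:])
        raise np.linalg.LinAlgError(
            f"singular demeaned design: collinear covariate columns {dep}"
        )
    beta, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
    return beta


def _colwise_group_means(panel: ProviderPanel, X: np.ndarray) -> np.ndarray:
    return np.column_stack([panel.group_means(X[:, j]) for j in range(X.shape[1])])


def _expand(panel: ProviderPanel, per_provider: np.ndarray) -> np.ndarray:
    return np.repeat(per_provider, panel.sizes, axis=0)


def center_mu(panel: ProviderPanel, beta: np.ndarray) -> float:
    """Observation-weighted grand mean of the covariate-adjusted outcomes.

    Used as the plug-in for mu so risk-adjusted outcomes average to zero.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size != panel.n_covariates:
        raise ValueError("beta dimension does not match covariates")
    resid = panel.y_raw if beta.size == 0 else panel.y_raw - panel.X @ beta
    return float(resid.mean())


def risk_adjust(panel: ProviderPanel, components: VarianceComponents) -> ProviderPanel:
    """Attach Y_ij = Y*_ij - mu - X_ij' beta to every record."""
    beta = np.asarray(components.beta, dtype=float)
    if beta.size != panel.n_covariates:
        raise ValueError("beta dimension does not match panel covariates")
    adj = panel.y_raw - components.mu
    if beta.size:
        adj = adj - panel.X @ beta
    return panel.with_adjusted(adj)


def provider_means(panel: ProviderPanel) -> dict[str, float]:
    """Per-provider mean of the risk-adjusted outcome (the alpha_i estimate)."""
    if panel.y_adjusted is None:
        raise ValueError("panel is not risk-adjusted; run risk_adjust first")
    means = panel.group_means(panel.y_adjusted)
    return dict(zip(panel.providers.tolist(), means.tolist()))


# ---------------------------------------------------------------------------
# ANOVA variance components and the IUR
# ---------------------------------------------------------------------------

def n_prime(sizes: Sequence[int]) -> float:
    """Effective average provider size in the unbalanced one-way ANOVA.

    n' = (sum n_i - sum n_i^2 / sum n_i) / (m - 1); equals n exactly when
    all providers have size n, and is otherwise below the plain mean.
    """
    n = np.asarray(sizes, dtype=float)
    if n.size < 2:
        raise ValueError("n_prime requires at least two providers")
    if np.any(n < 1):
        raise ValueError("provider sizes must be >= 1")
    total = n.sum()
    return float((total - (n**2).sum() / total) / (n.size - 1))


def estimate_variance_components(panel: ProviderPanel) -> IUREstimate:
    """One-way ANOVA moment estimates of (sigma_b^2, sigma_w^2) and the IURs.

    sigma_w^2 is the within mean square; sigma_b^2 solves the SSB moment
    equation E(SSB) = (m-1)(sigma_w^2 + n' sigma_b^2) and is clamped at 0
    when the moment solution goes negative (logged).
    """
    if panel.y_adjusted is None:
        raise ValueError("panel is not risk-adjusted; run risk_adjust first")
    y = panel.y_adjusted
    sizes = panel.sizes.astype(float)
    m = panel.m
    total_n = y.size
    if total_n == m:
        raise ValueError("all providers have a single record; sigma_w2 not estimable")

    grand = float(y.mean())
    means = panel.group_means(y)
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float((y**2).sum() - (sizes * means**2).sum())
    sigma_w2 = ssw / (total_n - m)
    if sigma_w2 <= 0:
        raise ValueError(
            "degenerate panel: zero within-provider variance (sigma_w2 must be > 0)"
        )
    np_eff = n_prime(panel.sizes)
    sigma_b2_raw = (ssb / (m - 1) - sigma_w2) / np_eff
    sigma_b2 = max(0.0, sigma_b2_raw)
    if sigma_b2_raw < 0:
        logger.info("negative between-variance moment %.4g clamped to 0", sigma_b2_raw)

    overall = sigma_b2 / (sigma_b2 + sigma_w2 / np_eff)
    per = sigma_b2 / (sigma_b2 + sigma_w2 / sizes)
    return IUREstimate(
        sigma_b2_hat=sigma_b2,
        sigma_w2_hat=sigma_w2,
        n_prime=np_eff,
        overall_iur=overall,
        per_provider_iur=dict(zip(panel.providers.tolist(), per.tolist())),
        ssb=ssb,
        grand_mean=grand,
    )
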