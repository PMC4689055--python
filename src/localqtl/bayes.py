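"""Bayesian-alphabet whole-genome regression (BayesA, BayesB, BayesC/C0, BayesCpi).

The fitted model is

    y_i = mu + sum_j z_ij * beta_j * delta_j + e_i

with z_ij the 0/1/2 marker dosage, beta_j the allele substitution effect and
delta_j a 0/1 inclusion indicator that is zero with prior probability pi.
The methods differ only in their effect-variance prior:

========  ==========================  =================
method    effect variances            pi
========  ==========================  =================
A         per marker, scaled inv-X2   0 (all fitted)
B         per marker, scaled inv-X2   fixed in (0, 1)
C / C0    one common scaled inv-X2    fixed (C0: pi=0)
Cpi       one common scaled inv-X2    Beta-sampled (uniform prior)
========  ==========================  =================

Dosages are centered before fitting and the intercept absorbs the mean;
this is algebraically equivalent to fitting raw 0/1/2 codes for prediction
correlations and numerically better behaved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._gibbs import gibbs_chain

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "PosteriorSummary",
    "run_chain",
    "expected_markers_per_iteration",
    "derive_scale_beta",
    "monitor_convergence",
]

_METHODS = {"A", "B", "C", "Cpi"}


@dataclass(frozen=True)
class PriorSpec:
    """Model family and hyperparameters.

    ``pi`` is the prior probability of a zero effect (fixed for B/C, the
    starting value for Cpi; pi = 1 would fit nothing and is rejected).
    ``scale_beta`` defaults to the value matching ``assumed_genetic_variance``
    (itself defaulting to var(y)) via :func:`derive_scale_beta`; ``scale_e``
    defaults to a nominal residual variance of 0.01 var(y) — with h² = 1 data
    the posterior is insensitive to it.  ``fix_sigma2_beta`` /
    ``fix_sigma2_e`` freeze a variance component instead of sampling it
    (used for the SNP-BLUP equivalence check).
    """

    method: str
    pi: float = 0.0
    nu_beta: float = 4.2
    scale_beta: Optional[float] = None
    nu_e: float = 4.0
    scale_e: Optional[float] = None
    assumed_genetic_variance: Optional[float] = None
    fix_sigma2_beta: Optional[float] = None
    fix_sigma2_e: Optional[float] = None

    def __post_init__(self) -> None:
        method = {"C0": "C", "CPI": "Cpi", "cpi": "Cpi"}.get(self.method, self.method)
        if method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {sorted(_METHODS)}")
        object.__setattr__(self, "method", method)
        if not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must lie in [0, 1); pi = 1 is degenerate")
        if self.nu_beta <= 2.0:
            raise ValueError("nu_beta must exceed 2 so the prior effect variance has a mean")
        if self.nu_e <= 2.0:
            raise ValueError("nu_e must exceed 2")
        for name in ("fix_sigma2_beta", "fix_sigma2_e"):
            v = getattr(self, name)
            if v is not None and v <= 0.0:
                raise ValueError(f"{name} must be positive")

    @property
    def label(self) -> str:
        if self.method == "Cpi":
            return f"BayesCpi{self.pi:g}"
        if self.method == "A":
            return "BayesA"
        if self.pi == 0.0:
            return f"Bayes{self.method}0"
        return f"Bayes{self.method}{self.pi:g}"


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings; ``thinning`` applies to optionally stored effect samples."""

    n_iterations: int = 4000
    burn_in: int = 500
    seed: int = 0
    thinning: int = 1
    store_samples: bool = False

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.burn_in >= self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must be a non-negative 31-bit integer")


@dataclass
class PosteriorSummary:
    """Post-burn-in posterior summaries of one chain.

    ``effect_mean`` is the posterior mean substitution effect beta_j*delta_j;
    ``inclusion_freq`` the model frequency (posterior mean of delta_j).
    ``column_means`` are the training dosage means used for centering, needed
    to form DGV for new individuals.
    """

    effect_mean: np.ndarray
    inclusion_freq: np.ndarray
    mu_mean: float
    sigma2_beta_mean: float
    sigma2_e_mean: float
    pi_mean: float
    mean_included_per_iteration: float
    column_means: np.ndarray
    prior: PriorSpec
    config: ChainConfig
    marker_ids: Optional[np.ndarray] = None
    effect_samples: Optional[np.ndarray] = None
    sample_offsets: Optional[np.ndarray] = None
    pi_samples: Optional[np.ndarray] = None

    @property
    def n_markers(self) -> int:
        return len(self.effect_mean)

    def to_frame(self) -> pd.DataFrame:
        ids = self.marker_ids if self.marker_ids is not None else np.arange(self.n_markers)
        return pd.DataFrame(
            {
                "marker_id": ids,
                "posterior_mean_effect": self.effect_mean,
                "model_frequency": self.inclusion_freq,
            }
        )


def expected_markers_per_iteration(pi: float, p: int) -> float:
    """Expected number of markers fitted with non-zero effect per iteration: (1 − pi)·p."""
    if not (0.0 <= pi <= 1.0):
        raise ValueError("pi must lie in [0, 1]")
    return (1.0 - pi) * p


def derive_scale_beta(
    assumed_genetic_variance: float,
    pi: float,
    nu_beta: float,
    mean_2pq: float,
    n_markers: int,
) -> float:
    """Scale S of the effect-variance prior matching an assumed genetic variance.

    Under the prior, each of the (1 − pi)·p fitted markers contributes
    2p_j q_j · E[sigma2_beta] = 2p_j q_j · nu S/(nu − 2) of genetic variance,
    so S = V (nu − 2) / (nu (1 − pi) p mean_2pq) makes the prior-implied
    total match ``assumed_genetic_variance``.
    """
    if nu_beta <= 2.0:
        raise ValueError("nu_beta must exceed 2")
    if pi >= 1.0:
        raise ValueError("pi = 1 leaves no fitted markers")
    if mean_2pq <= 0.0:
        raise ValueError("mean_2pq must be positive")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return (
        assumed_genetic_variance
        * (nu_beta - 2.0)
        / (nu_beta * (1.0 - pi) * n_markers * mean_2pq)
    )


def run_chain(
    Z: np.ndarray,
    y: np.ndarray,
    prior: PriorSpec,
    config: ChainConfig,
    marker_ids: Optional[Sequence[str]] = None,
) -> PosteriorSummary:
    """Run one single-site Gibbs chain and summarise the posterior.

    ``Z`` is an (n, p) dosage matrix (any subset of a panel — local window or
    whole genome; QTL columns are the caller's responsibility to exclude);
    ``y`` the phenotype.  Per iteration: intercept from its normal full
    conditional; each marker's inclusion indicator from its Bernoulli full
    conditional with the effect integrated out, then the effect from its
    normal full conditional if included; effect variance(s) and the residual
    variance from scaled inverse chi-square conditionals; and for Cpi, pi
    from Beta(#excluded + 1, #included + 1).
    """
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if Z.ndim != 2:
        raise ValueError("Z must be 2-D")
    n, p = Z.shape
    if len(y) != n:
        raise ValueError("y length does not match Z rows")
    if p < 1:
        raise ValueError("empty predictor set")
    vy = float(np.var(y))
    if vy <= 0.0:
        raise ValueError("phenotype is constant; refusing to fit")

    col_means = Z.mean(axis=0)
    Zc = np.asfortranarray(Z - col_means)

    freq = col_means / 2.0
    two_pq = 2.0 * freq * (1.0 - freq)
    mean_2pq = float(two_pq.mean())
    if mean_2pq <= 0.0:
        raise ValueError("all predictor columns are monomorphic")

    method = prior.method
    pi0 = 0.0 if method == "A" else prior.pi
    per_marker = method in ("A", "B")
    sample_pi = method == "Cpi"

    gvar = prior.assumed_genetic_variance if prior.assumed_genetic_variance is not None else vy
    S_b = (
        prior.scale_beta
        if prior.scale_beta is not None
        else derive_scale_beta(gvar, pi0, prior.nu_beta, mean_2pq, p)
    )
    nominal_resid = 0.01 * vy
    S_e = prior.scale_e if prior.scale_e is not None else nominal_resid * (prior.nu_e - 2.0) / prior.nu_e

    n_samples = config.n_iterations - config.burn_in
    n_store = -(-n_samples // config.thinning) if config.store_samples else 0

    (
        eff_mean,
        incl_freq,
        mu_mean,
        s2b_mean,
        s2e_mean,
        pi_mean,
        mean_incl,
        samples,
        offsets,
        pi_trace,
    ) = gibbs_chain(
        Zc,
        y,
        float(pi0),
        per_marker,
        sample_pi,
        float(prior.nu_beta),
        float(S_b),
        float(prior.nu_e),
        float(S_e),
        prior.fix_sigma2_beta is not None,
        float(prior.fix_sigma2_beta or 1.0),
        prior.fix_sigma2_e is not None,
        float(prior.fix_sigma2_e or 1.0),
        config.n_iterations,
        config.burn_in,
        config.thinning,
        n_store,
        config.seed,
    )

    return PosteriorSummary(
        effect_mean=eff_mean,
        inclusion_freq=incl_freq,
        mu_mean=float(mu_mean),
        sigma2_beta_mean=float(s2b_mean),
        sigma2_e_mean=float(s2e_mean),
        pi_mean=float(pi_mean),
        mean_included_per_iteration=float(mean_incl),
        column_means=col_means,
        prior=prior,
        config=config,
        marker_ids=np.asarray(marker_ids) if marker_ids is not None else None,
        effect_samples=samples if config.store_samples else None,
        sample_offsets=offsets if config.store_samples else None,
        pi_samples=pi_trace if sample_pi else None,
    )


def monitor_convergence(
    summary: PosteriorSummary,
    Z_train: np.ndarray,
    y_train: np.ndarray,
    checkpoints: Sequence[int],
) -> pd.DataFrame:
    """Training-correlation trajectory as the chain lengthens.

    For each checkpoint (a post-burn-in iteration count) the stored effect
    samples up to that point are averaged into running posterior-mean
    effects, fitted values are formed, and corr(y_train, fitted) reported.
    Requires a chain run with ``store_samples=True``.
    """
    if summary.effect_samples is None or len(summary.effect_samples) == 0:
        raise ValueError("chain was run without stored effect samples")
    checkpoints = list(checkpoints)
    if len(checkpoints) == 0:
        raise ValueError("no checkpoints requested")
    n_samples = summary.config.n_iterations - summary.config.burn_in
    rows = []
    Zc = np.asarray(Z_train, dtype=np.float64) - summary.column_means
    for cp in checkpoints:
        if cp < 1 or cp > n_samples:
            raise ValueError(f"checkpoint {cp} outside 1..{n_samples} post-burn-in iterations")
        use = summary.sample_offsets <= cp
        if not use.any():
            raise ValueError(f"no stored samples at or before checkpoint {cp}")
        running = summary.effect_samples[use].mean(axis=0)
        fitted = Zc @ running
        sd = fitted.std()
        if sd == 0.0:
            warnings.warn(f"fitted values constant at checkpoint {cp}; correlation undefined")
            corr = np.nan
        else:
            corr = float(np.corrcoef(y_train, fitted)[0, 1])
        rows.append({"checkpoint": cp, "n_samples_used": int(use.sum()), "correlation": corr})
    return pd.DataFrame(rows)
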