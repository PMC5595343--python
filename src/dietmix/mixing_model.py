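"""Bayesian mass-balance stable-isotope mixing model.

A consumer's isotope value on isotope j is modelled as a mixture of K
TDF-corrected source distributions weighted by the diet proportions p
(a point on the K-simplex):

    x_ij ~ Normal(m_j, sqrt(v_j + xi_j^2))
    m_j  = sum_k p_k (mu_kj + lambda_kj)
    v_j  = sum_k p_k^2 (sigma_kj^2 + tau_kj^2)

where mu/sigma are the source group mean/sd, lambda/tau the mean/sd of
the diet-to-tissue discrimination factor (TDF), and xi_j an optional
residual-error scale.  Priors: p ~ Dirichlet(alpha) (alpha = 1 by
default) and xi_j ~ Uniform(0, upper), upper defaulting to twice the
consumer sd on that isotope.

Inference is random-walk Metropolis on the additive-log-ratio transform
of p (last source as reference), which keeps every retained draw exactly
on the simplex; the proposal scale is adapted during the first half of
burn-in toward a 20-40% acceptance rate and then frozen.  Residual
scales are updated on the log scale.  Convergence is monitored with the
split-chain potential scale reduction factor (R-hat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SEED = 20170912

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixingData:
    """Consumer values, source summaries and discrimination factors.

    Arrays are per-source x per-isotope (K x J); a single shared TDF per
    isotope may be passed as a length-J vector and is broadcast to all
    sources.
    """

    consumers: np.ndarray  # n x J
    source_means: np.ndarray  # K x J
    source_sds: np.ndarray  # K x J
    tdf_means: np.ndarray  # K x J (or J, broadcast)
    tdf_sds: np.ndarray  # K x J (or J, broadcast)
    source_names: list[str] = field(default_factory=list)
    isotope_names: list[str] = field(default_factory=lambda: ["d13C", "d15N"])

    def __post_init__(self) -> None:
        self.consumers = np.atleast_2d(np.asarray(self.consumers, dtype=float))
        self.source_means = np.atleast_2d(np.asarray(self.source_means, dtype=float))
        self.source_sds = np.atleast_2d(np.asarray(self.source_sds, dtype=float))
        k, j = self.source_means.shape
        self.tdf_means = np.broadcast_to(
            np.asarray(self.tdf_means, dtype=float), (k, j)
        ).copy()
        self.tdf_sds = np.broadcast_to(np.asarray(self.tdf_sds, dtype=float), (k, j)).copy()
        if self.source_sds.shape != (k, j):
            raise ValueError("source_sds shape mismatch")
        if self.consumers.size and self.consumers.shape[1] != j:
            raise ValueError("consumer isotope dimension mismatch")
        if (self.source_sds < 0).any() or (self.tdf_sds < 0).any():
            raise ValueError("sds must be non-negative")
        if not self.source_names:
            self.source_names = [f"source_{i + 1}" for i in range(k)]

    @property
    def n_sources(self) -> int:
        return self.source_means.shape[0]

    @property
    def n_isotopes(self) -> int:
        return self.source_means.shape[1]

    @property
    def n_consumers(self) -> int:
        return 0 if self.consumers.size == 0 else self.consumers.shape[0]

    @property
    def corrected_means(self) -> np.ndarray:
        """TDF-corrected source means, mu + lambda (K x J)."""
        return self.source_means + self.tdf_means

    @property
    def corrected_vars(self) -> np.ndarray:
        """Combined source + TDF variances, sigma^2 + tau^2 (K x J)."""
        return self.source_sds**2 + self.tdf_sds**2

    @classmethod
    def from_frames(
        cls,
        consumers: pd.DataFrame,
        groups: pd.DataFrame,
        tdf: pd.DataFrame,
        isotopes: tuple[str, str] = ("d13C", "d15N"),
    ) -> "MixingData":
        """Assemble from the consumers / groups / tdf CSV schemas.

        ``tdf`` has columns ``isotope, mean, sd`` and optionally
        ``group_id`` for per-source factors.
        """
        groups = groups.sort_values("group_id").reset_index(drop=True)
        k, j = len(groups), len(isotopes)
        mu = groups[[f"mean_{iso}" for iso in isotopes]].to_numpy(dtype=float)
        sig = groups[[f"sd_{iso}" for iso in isotopes]].to_numpy(dtype=float)
        lam = np.zeros((k, j))
        tau = np.zeros((k, j))
        for jj, iso in enumerate(isotopes):
            sub = tdf[tdf["isotope"] == iso]
            if sub.empty:
                raise ValueError(f"no TDF row for isotope {iso!r}")
            if "group_id" in sub.columns and sub["group_id"].notna().any():
                per = sub.set_index("group_id")
                lam[:, jj] = per.loc[groups["group_id"], "mean"].to_numpy(dtype=float)
                tau[:, jj] = per.loc[groups["group_id"], "sd"].to_numpy(dtype=float)
            else:
                lam[:, jj] = float(sub["mean"].iloc[0])
                tau[:, jj] = float(sub["sd"].iloc[0])
        x = consumers[list(isotopes)].to_numpy(dtype=float)
        names = [str(g) for g in groups["group_id"]]
        return cls(x, mu, sig, lam, tau, source_names=names, isotope_names=list(isotopes))


@dataclass
class ModelConfig:
    n_chains: int = 3
    burn_in: int = 5000
    samples: int = 5000
    thin: int = 1
    prior_alpha: np.ndarray | None = None
    residual_error: bool = True
    residual_sd_upper: np.ndarray | None = None  # per isotope
    proposal_scale: float = 0.5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.burn_in < 1 or self.samples < 1:
            raise ValueError("burn_in and samples must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_alpha is not None:
            self.prior_alpha = np.asarray(self.prior_alpha, dtype=float)
            if (self.prior_alpha <= 0).any():
                raise ValueError("prior_alpha must be positive")

    def alpha(self, k: int) -> np.ndarray:
        if self.prior_alpha is None:
            return np.ones(k)
        if len(self.prior_alpha) != k:
            raise ValueError("prior_alpha length does not match source count")
        return self.prior_alpha

    def xi_upper(self, data: MixingData) -> np.ndarray:
        if self.residual_sd_upper is not None:
            return np.broadcast_to(
                np.asarray(self.residual_sd_upper, dtype=float), (data.n_isotopes,)
            ).copy()
        if data.n_consumers >= 2:
            sd = data.consumers.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            return 2.0 * sd
        return np.full(data.n_isotopes, 2.0)


@dataclass
class MixingPosterior:
    """Post-burn-in MCMC draws with per-chain diagnostics."""

    p_draws: np.ndarray  # chains x draws x K
    xi_draws: np.ndarray | None  # chains x draws x J
    acceptance: dict
    source_names: list[str]
    isotope_names: list[str]

    @property
    def flat_p(self) -> np.ndarray:
        c, n, k = self.p_draws.shape
        return self.p_draws.reshape(c * n, k)

    def to_frame(self) -> pd.DataFrame:
        c, n, k = self.p_draws.shape
        cols = {f"p_{name}": self.p_draws[:, :, i].ravel() for i, name in enumerate(self.source_names)}
        out = pd.DataFrame(cols)
        out.insert(0, "iteration", np.tile(np.arange(n), c))
        out.insert(0, "chain", np.repeat(np.arange(c), n))
        if self.xi_draws is not None:
            for j, iso in enumerate(self.isotope_names):
                out[f"xi_{iso}"] = self.xi_draws[:, :, j].ravel()
        return out


def _check_simplex(p: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < -tol).any() or abs(p.sum() - 1.0) > tol:
        raise ValueError("p is not on the probability simplex")
    return p


def mixture_moments(p: np.ndarray, data: MixingData) -> tuple[np.ndarray, np.ndarray]:
    """Mixture mean m_j and process variance v_j per isotope."""
    p = _check_simplex(p)
    m = p @ data.corrected_means
    v = (p**2) @ data.corrected_vars
    return m, v


def _suff_stats(x: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    if x.size == 0:
        j = x.shape[1] if x.ndim == 2 else 0
        return 0, np.zeros(j), np.zeros(j)
    return x.shape[0], x.sum(axis=0), (x**2).sum(axis=0)


def _log_likelihood(m: np.ndarray, s2: np.ndarray, n: int, sx: np.ndarray, sxx: np.ndarray) -> float:
    if n == 0:
        return 0.0
    if (s2 <= 0).any():
        return -np.inf
    ll = -0.5 * n * (_LOG_2PI + np.log(s2)) - (sxx - 2.0 * m * sx + n * m**2) / (2.0 * s2)
    return float(ll.sum())


def log_posterior(
    p: np.ndarray,
    xi: np.ndarray | None,
    data: MixingData,
    config: ModelConfig,
) -> float:
    """Unnormalised log posterior density at (p, xi).

    Returns -inf outside the support (off-simplex handled upstream, xi
    outside its uniform prior here).
    """
    p = _check_simplex(p)
    alpha = config.alpha(data.n_sources)
    if (p == 0).any() and (alpha < 1).any():
        return -np.inf
    m, v = p @ data.corrected_means, (p**2) @ data.corrected_vars
    if xi is None:
        xi = np.zeros(data.n_isotopes)
    xi = np.asarray(xi, dtype=float)
    upper = config.xi_upper(data)
    if config.residual_error:
        if (xi < 0).any() or (xi > upper).any():
            return -np.inf
    n, sx, sxx = _suff_stats(data.consumers)
    ll = _log_likelihood(m, v + xi**2, n, sx, sxx)
    with np.errstate(divide="ignore"):
        prior = float(((alpha - 1.0) * np.log(p, where=p > 0, out=np.zeros_like(p))).sum())
    return ll + prior


def _softmax_p(z: np.ndarray) -> np.ndarray:
    full = np.append(z, 0.0)
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def run_mcmc(data: MixingData, config: ModelConfig | None = None) -> MixingPosterior:
    """Sample the posterior of (p, xi) by adaptive random-walk Metropolis.

    p is updated jointly on its additive-log-ratio coordinates (with the
    simplex log-Jacobian sum_k log p_k), xi jointly on the log scale.
    """
    config = config or ModelConfig()
    k, j = data.n_sources, data.n_isotopes
    if k < 2:
        raise ValueError("need at least two sources")
    alpha = config.alpha(k)
    upper = config.xi_upper(data)
    n, sx, sxx = _suff_stats(data.consumers)
    mu_c = data.corrected_means
    var_c = data.corrected_vars
    use_xi = config.residual_error

    def target_z(z: np.ndarray, xi: np.ndarray) -> float:
        p = _softmax_p(z)
        if (p <= 0).any():  # numerical underflow far out in the tails
            return -np.inf
        m = p @ mu_c
        v = (p**2) @ var_c
        ll = _log_likelihood(m, v + xi**2, n, sx, sxx)
        # Dirichlet prior + ALR Jacobian: (alpha-1)'log p + sum log p
        return ll + float((alpha * np.log(p)).sum())

    def target_eta(eta: np.ndarray, z: np.ndarray) -> float:
        xi = np.exp(eta)
        if (xi > upper).any():
            return -np.inf
        # uniform prior on xi, log-scale Jacobian sum(eta)
        return target_z(z, xi) + float(eta.sum())

    seed_seq = np.random.SeedSequence(config.seed)
    chain_seeds = seed_seq.spawn(config.n_chains)
    n_keep = config.samples // config.thin
    p_draws = np.empty((config.n_chains, n_keep, k))
    xi_draws = np.empty((config.n_chains, n_keep, j)) if use_xi else None
    acc = {"p": [], "xi": []}
    adapt_end = config.burn_in // 2

    for c, cseed in enumerate(chain_seeds):
        rng = np.random.default_rng(cseed)
        # initialise from the priors; retry on a non-finite posterior
        for attempt in range(100):
            p0 = rng.dirichlet(alpha)
            xi0 = rng.uniform(0, upper) if use_xi else np.zeros(j)
            z = np.log(np.maximum(p0[:-1], 1e-300)) - np.log(max(p0[-1], 1e-300))
            eta = np.log(np.maximum(xi0, 1e-6)) if use_xi else np.zeros(j)
            lp = target_eta(eta, z) if use_xi else target_z(z, np.zeros(j))
            if np.isfinite(lp):
                break
        else:
            raise RuntimeError("could not initialise chain at a finite posterior value")

        scale_z = config.proposal_scale
        scale_eta = config.proposal_scale
        lp_z = target_z(z, np.exp(eta) if use_xi else np.zeros(j))
        acc_z = acc_eta = 0
        batch_z = batch_eta = 0
        kept = 0
        total = config.burn_in + config.samples
        for it in range(total):
            z_prop = z + scale_z * rng.standard_normal(k - 1)
            xi_cur = np.exp(eta) if use_xi else np.zeros(j)
            lp_prop = target_z(z_prop, xi_cur)
            if np.log(rng.random()) < lp_prop - lp_z:
                z, lp_z = z_prop, lp_prop
                acc_z += 1
                batch_z += 1
            if use_xi:
                eta_prop = eta + scale_eta * rng.standard_normal(j)
                lp_eta = lp_z + eta.sum()
                lp_eta_prop = target_eta(eta_prop, z)
                if np.log(rng.random()) < lp_eta_prop - lp_eta:
                    eta = eta_prop
                    lp_z = lp_eta_prop - eta.sum()
                    acc_eta += 1
                    batch_eta += 1
            if it < adapt_end and (it + 1) % 50 == 0:
                if batch_z / 50 > 0.4:
                    scale_z *= 1.1
                elif batch_z / 50 < 0.2:
                    scale_z /= 1.1
                if use_xi:
                    if batch_eta / 50 > 0.4:
                        scale_eta *= 1.1
                    elif batch_eta / 50 < 0.2:
                        scale_eta /= 1.1
                batch_z = batch_eta = 0
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and kept < n_keep:
                p_draws[c, kept] = _softmax_p(z)
                if use_xi:
                    xi_draws[c, kept] = np.exp(eta)
                kept += 1
        acc["p"].append(acc_z / total)
        acc["xi"].append(acc_eta / total if use_xi else np.nan)

    return MixingPosterior(
        p_draws=p_draws,
        xi_draws=xi_draws,
        acceptance=acc,
        source_names=list(data.source_names),
        isotope_names=list(data.isotope_names),
    )


def gelman_rubin(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``draws`` is chains x iterations; each chain is split in half, and
    the classic PSRF is computed on the half-chains.  Values below 1
    arise only from estimator noise, so the result is floored at 1.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    c, n = draws.shape
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    half = n // 2
    split = np.concatenate([draws[:, :half], draws[:, half: 2 * half]], axis=0)
    m, length = split.shape
    within = split.var(axis=1, ddof=1).mean()
    if within == 0:
        warnings.warn("zero within-chain variance; reporting R-hat = 1", RuntimeWarning)
        return 1.0
    between = length * split.mean(axis=1).var(ddof=1)
    var_hat = (length - 1) / length * within + between / length
    return max(float(np.sqrt(var_hat / within)), 1.0)


def posterior_rhat(posterior: MixingPosterior) -> pd.Series:
    """R-hat per diet proportion (and residual scale, if sampled)."""
    vals = {}
    for i, name in enumerate(posterior.source_names):
        vals[f"p_{name}"] = gelman_rubin(posterior.p_draws[:, :, i])
    if posterior.xi_draws is not None:
        for jj, iso in enumerate(posterior.isotope_names):
            vals[f"xi_{iso}"] = gelman_rubin(posterior.xi_draws[:, :, jj])
    return pd.Series(vals, name="rhat")


def summarize_posterior(posterior: MixingPosterior) -> pd.DataFrame:
    """Per-source posterior mean, median, sd and central 50/75/95% intervals."""
    flat = posterior.flat_p
    if flat.size == 0:
        raise ValueError("empty posterior")
    qs = np.percentile(flat, [2.5, 12.5, 25.0, 50.0, 75.0, 87.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "source": posterior.source_names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "median": qs[3],
            "lo50": qs[2],
            "hi50": qs[4],
            "lo75": qs[1],
            "hi75": qs[5],
            "lo95": qs[0],
            "hi95": qs[6],
        }
    )
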