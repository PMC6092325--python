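"""Bayesian stable-isotope mixing model (Dirichlet-normal, MCMC).

Estimates the proportional contribution p_1..p_K of K plankton size-class
sources to the consumer diet from J isotopes (here δ13C and δ15N), in the
standard fully specified source-uncertainty mixing structure: consumer
observation j is normal with

    mean_j = sum_k p_k (mu_jk + c_jk)
    var_j  = sum_k p_k^2 (omega_jk^2 + tau_jk^2) + sigma_j^2

where mu/omega are source means/SDs, c/tau are trophic enrichment factor
(TEF) means/SDs, and sigma_j is a per-isotope residual scale. Priors:
Dirichlet(1,..,1) on p (uniform over the simplex) and half-normal on sigma_j
with scale set to the observed consumer SD of that isotope.

Inference is random-walk Metropolis on an unconstrained parameterization
(additive-log-ratio/softmax for p, log for sigma) with step-size adaptation
during burn-in only, several independent chains, and Gelman-Rubin convergence
diagnostics. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ISOTOPES, IsotopeSampleSet, MCMCConfig

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SourceSpec:
    """One diet source: per-isotope mean and SD (per mil)."""

    name: str
    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.sd.values()):
            raise ValueError(f"source {self.name!r}: negative sd")


@dataclass(frozen=True)
class TEFSpec:
    """Trophic enrichment factor: per-isotope mean and SD (per mil)."""

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.sd.values()):
            raise ValueError("TEF: negative sd")


#: The consumer-to-diet fractionation used throughout: 2 +/- 0.3 per mil for
#: carbon, 3.2 +/- 0.1 per mil for nitrogen.
DEFAULT_TEF = TEFSpec(mean={"d13C": 2.0, "d15N": 3.2},
                      sd={"d13C": 0.3, "d15N": 0.1})


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, stacked over chains.

    ``p`` has shape (n_draws_total, K) rows on the simplex; ``sigma`` shape
    (n_draws_total, J); ``chain`` labels each draw's chain of origin.
    """

    p: np.ndarray
    sigma: np.ndarray
    chain: np.ndarray
    source_names: tuple[str, ...]
    isotopes: tuple[str, ...]
    seed: int
    acceptance_rate: float
    config: MCMCConfig = field(default_factory=MCMCConfig)

    @property
    def n_draws(self) -> int:
        return self.p.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.p, columns=[f"p_{s}" for s in self.source_names])
        for j, iso in enumerate(self.isotopes):
            df[f"sigma_{iso}"] = self.sigma[:, j]
        df.insert(0, "chain", self.chain)
        return df


def _spec_arrays(sources: Sequence[SourceSpec], tef: TEFSpec,
                 isotopes: Sequence[str]) -> tuple[np.ndarray, ...]:
    """(K,J) arrays mu, omega, c, tau in the requested isotope order."""
    try:
        mu = np.array([[s.mean[j] for j in isotopes] for s in sources], float)
        om = np.array([[s.sd[j] for j in isotopes] for s in sources], float)
        c = np.array([[tef.mean[j] for j in isotopes] for s in sources], float)
        tau = np.array([[tef.sd[j] for j in isotopes] for s in sources], float)
    except KeyError as err:
        raise ValueError(f"isotope {err} missing from a source or TEF spec") from err
    return mu, om, c, tau


def mixture_moments(p: Sequence[float], sources: Sequence[SourceSpec],
                    tef: TEFSpec, isotopes: Sequence[str] = ISOTOPES,
                    ) -> dict[str, dict[str, float]]:
    """Per-isotope mean and SD of the mixture for a given simplex point p."""
    p = np.asarray(p, float)
    if len(p) != len(sources):
        raise ValueError(f"p has {len(p)} entries for {len(sources)} sources")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p must lie on the probability simplex")
    mu, om, c, tau = _spec_arrays(sources, tef, isotopes)
    mean = p @ (mu + c)
    sd = np.sqrt((p ** 2) @ (om ** 2 + tau ** 2))
    return {iso: {"mean": float(mean[j]), "sd": float(sd[j])}
            for j, iso in enumerate(isotopes)}


def _consumer_matrix(consumers, isotopes: Sequence[str]) -> np.ndarray:
    if isinstance(consumers, IsotopeSampleSet):
        df = consumers.data
        if "group" in df.columns and (df["group"] == "consumer").any():
            df = df[df["group"] == "consumer"]
        return df[list(isotopes)].to_numpy(float)
    return np.asarray(consumers, float).reshape(-1, len(isotopes))


def log_posterior(p: Sequence[float], sigma: Sequence[float], consumers,
                  sources: Sequence[SourceSpec], tef: TEFSpec,
                  isotopes: Sequence[str] = ISOTOPES,
                  sigma_prior_scale: Sequence[float] | None = None) -> float:
    """Unnormalized log posterior density at (p, sigma); -inf off support."""
    p = np.asarray(p, float)
    sigma = np.asarray(sigma, float)
    if (np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8 or np.any(sigma <= 0)):
        return -math.inf
    X = _consumer_matrix(consumers, isotopes)
    mu, om, c, tau = _spec_arrays(sources, tef, isotopes)
    mean = p @ (mu + c)
    var = (p ** 2) @ (om ** 2 + tau ** 2) + sigma ** 2
    resid2 = (X - mean) ** 2
    loglik = float(np.sum(-0.5 * (_LOG_2PI + np.log(var) + resid2 / var)))
    # Dirichlet(1,..,1) prior on p is constant over the simplex.
    if sigma_prior_scale is None:
        scale = np.maximum(X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones_like(sigma), 1e-6)
    else:
        scale = np.asarray(sigma_prior_scale, float)
    logprior = float(np.sum(-0.5 * sigma ** 2 / scale ** 2))  # half-normal kernel
    return loglik + logprior


def _softmax_with_last_zero(z: np.ndarray) -> np.ndarray:
    full = np.append(z, 0.0)
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def sample_posterior(consumers, sources: Sequence[SourceSpec],
                     tef: TEFSpec = DEFAULT_TEF,
                     config: MCMCConfig | None = None,
                     seed: int | None = None,
                     isotopes: Sequence[str] = ISOTOPES) -> PosteriorDraws:
    """Random-walk Metropolis sampler for the mixing posterior.

    Works on unconstrained coordinates theta = (z_1..z_{K-1}, log sigma_1..J)
    with p = softmax(z, 0); the simplex and log Jacobians are included so the
    target on theta corresponds to the stated priors on (p, sigma). Step sizes
    adapt toward 20-40% acceptance during burn-in only, then freeze, keeping
    the post-burn-in kernel valid. K = 1 degenerates to p = 1 with only the
    residual scales sampled.
    """
    config = config or MCMCConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    K = len(sources)
    if K < 1:
        raise ValueError("need at least one source")
    J = len(isotopes)
    X = _consumer_matrix(consumers, isotopes)
    n = X.shape[0]
    if n < 1:
        X = np.empty((0, J))
    mu, om, c, tau = _spec_arrays(sources, tef, isotopes)
    mu_c = mu + c
    om2tau2 = om ** 2 + tau ** 2
    if n > 1:
        prior_scale = np.maximum(X.std(axis=0, ddof=1), 1e-6)
    else:
        prior_scale = np.ones(J)

    n_free = (K - 1) + J

    def log_target(theta: np.ndarray) -> float:
        z, logsig = theta[:K - 1], theta[K - 1:]
        p = _softmax_with_last_zero(z) if K > 1 else np.ones(1)
        sigma = np.exp(logsig)
        var = (p ** 2) @ om2tau2 + sigma ** 2
        if n:
            mean = p @ mu_c
            resid2 = (X - mean) ** 2
            loglik = np.sum(-0.5 * (_LOG_2PI + np.log(var) + resid2 / var))
        else:
            loglik = 0.0
        # log Jacobians: softmax -> sum log p_k; exp -> sum log sigma_j.
        logjac = (np.log(p).sum() if K > 1 else 0.0) + logsig.sum()
        logprior = np.sum(-0.5 * sigma ** 2 / prior_scale ** 2)
        return float(loglik + logprior + logjac)

    keep_iters = range(config.burnin, config.iterations, config.thin)
    n_keep = len(keep_iters)
    keep_mask = np.zeros(config.iterations, dtype=bool)
    keep_mask[list(keep_iters)] = True

    # Two update blocks per iteration — the simplex logits and the log residual
    # scales — each with its own adaptive step; sigma is only weakly identified
    # when source variance explains most of the spread, so a shared step would
    # let the well-identified block starve it.
    blocks = ([np.arange(K - 1), np.arange(K - 1, n_free)] if K > 1
              else [np.arange(n_free)])

    all_p, all_sigma, all_chain = [], [], []
    accept_post = 0
    total_post = 0
    root = np.random.default_rng(seed)
    chain_seeds = root.integers(0, 2 ** 31 - 1, size=config.chains)
    for ci in range(config.chains):
        rng = np.random.default_rng(int(chain_seeds[ci]))
        theta = np.concatenate([rng.normal(0, 0.5, size=K - 1),
                                np.log(prior_scale) + rng.normal(0, 0.2, size=J)])
        steps = [0.2] * len(blocks)
        lp = log_target(theta)
        window_acc = [0] * len(blocks)
        kept_p = np.empty((n_keep, K))
        kept_s = np.empty((n_keep, J))
        kidx = 0
        normals = rng.standard_normal((config.iterations, n_free))
        unifs = np.log(rng.random((config.iterations, len(blocks))))
        for it in range(config.iterations):
            for bi, idx in enumerate(blocks):
                prop = theta.copy()
                prop[idx] += steps[bi] * normals[it, idx]
                lp_prop = log_target(prop)
                if lp_prop - lp > unifs[it, bi]:
                    theta, lp = prop, lp_prop
                    window_acc[bi] += 1
                    if it >= config.burnin:
                        accept_post += 1
                if it >= config.burnin:
                    total_post += 1
            if it < config.burnin and (it + 1) % 100 == 0:
                for bi in range(len(blocks)):
                    rate = window_acc[bi] / 100.0
                    if rate < 0.20:
                        steps[bi] *= 0.8
                    elif rate > 0.40:
                        steps[bi] *= 1.25
                    window_acc[bi] = 0
            if keep_mask[it]:
                z, logsig = theta[:K - 1], theta[K - 1:]
                kept_p[kidx] = _softmax_with_last_zero(z) if K > 1 else 1.0
                kept_s[kidx] = np.exp(logsig)
                kidx += 1
        all_p.append(kept_p)
        all_sigma.append(kept_s)
        all_chain.append(np.full(n_keep, ci))

    return PosteriorDraws(
        p=np.vstack(all_p), sigma=np.vstack(all_sigma),
        chain=np.concatenate(all_chain),
        source_names=tuple(s.name for s in sources), isotopes=tuple(isotopes),
        seed=int(seed),
        acceptance_rate=(accept_post / total_post) if total_post else 1.0,
        config=config,
    )


def gelman_rubin(values: np.ndarray, chain: np.ndarray) -> float:
    """Potential scale reduction factor R-hat for one scalar parameter."""
    chains = np.unique(chain)
    if len(chains) < 2:
        return math.nan
    per = [values[chain == ci] for ci in chains]
    m = len(per)
    n = min(len(v) for v in per)
    per = [v[:n] for v in per]
    means = np.array([v.mean() for v in per])
    variances = np.array([v.var(ddof=1) for v in per])
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


@dataclass
class MixingSummary:
    """Posterior summaries per source proportion (and residual scales)."""

    table: pd.DataFrame  # parameter, mean, median, lo, hi, rhat
    level: float
    converged: bool
    acceptance_rate: float

    def source_row(self, name: str) -> pd.Series:
        return self.table.set_index("parameter").loc[f"p_{name}"]


RHAT_THRESHOLD = 1.1


def summarize_posterior(draws: PosteriorDraws, level: float = 0.95) -> MixingSummary:
    """Posterior mean/median and equal-tailed credibility interval per
    parameter, plus Gelman-Rubin R-hat across chains (nan for one chain)."""
    if draws.n_draws == 0:
        raise ValueError("no posterior draws to summarize")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0,1), got {level}")
    a = (1.0 - level) / 2.0
    rows = []
    cols = ([(f"p_{s}", draws.p[:, k]) for k, s in enumerate(draws.source_names)]
            + [(f"sigma_{iso}", draws.sigma[:, j])
               for j, iso in enumerate(draws.isotopes)])
    for name, v in cols:
        rows.append({
            "parameter": name,
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "lo": float(np.quantile(v, a)),
            "hi": float(np.quantile(v, 1.0 - a)),
            "rhat": gelman_rubin(v, draws.chain),
        })
    table = pd.DataFrame(rows)
    rhats = table["rhat"].dropna()
    converged = bool((rhats <= RHAT_THRESHOLD).all()) if len(rhats) else True
    return MixingSummary(table=table, level=level, converged=converged,
                         acceptance_rate=draws.acceptance_rate)


def read_sources_csv(path, isotopes: Sequence[str] = ISOTOPES) -> list[SourceSpec]:
    """Read source specs from CSV: columns name, <iso>_mean, <iso>_sd."""
    from .io import normalize_text

    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(SourceSpec(
            name=normalize_text(r["name"]),
            mean={iso: float(r[f"{iso}_mean"]) for iso in isotopes},
            sd={iso: float(r[f"{iso}_sd"]) for iso in isotopes},
        ))
    return out


def write_sources_csv(sources: Sequence[SourceSpec], path,
                      isotopes: Sequence[str] = ISOTOPES) -> None:
    rows = []
    for s in sources:
        row = {"name": s.name}
        for iso in isotopes:
            row[f"{iso}_mean"] = s.mean[iso]
            row[f"{iso}_sd"] = s.sd[iso]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
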