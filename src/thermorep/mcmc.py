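"""Adaptive random-walk Metropolis sampler and posterior summaries.

The kernel is a blockwise Gaussian random-walk Metropolis sampler: each
sweep proposes every coordinate block in turn from an isotropic normal
and accepts with the usual ratio. Proposal scales adapt toward a target
acceptance rate during burn-in only, so the retained portion of every
chain is a valid fixed-kernel Markov chain. The default schedule is four
chains of 250,000 retained-eligible draws after 25,000 burn-in sweeps,
thinned by 10; reduced schedules for testing differ only through
:class:`MCMCConfig`, never through a separate code path.

Summaries are posterior means with equal-tailed 95% credible intervals
(empirical 2.5/97.5% quantiles), plus split-chain R-hat and effective
sample size diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "MCMCConfig",
    "PosteriorSummary",
    "run_chains",
    "thin_and_pool",
    "summarize",
    "convergence",
]

#: Advisory split-chain R-hat threshold; reported, never silently enforced.
RHAT_ADVISORY = 1.01


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule and adaptation settings.

    ``n_draws`` counts retained-eligible sweeps per chain recorded after
    ``burn_in`` discarded sweeps. ``thin`` keeps every thin-th retained
    draw at summary time. Adaptation multiplies each block's proposal
    scale by ``exp(2 * (acceptance - target_accept))`` once per
    ``adapt_window`` burn-in sweeps.
    """

    n_chains: int = 4
    n_draws: int = 250_000
    burn_in: int = 25_000
    thin: int = 10
    seed: int = 0
    target_accept: float = 0.3
    adapt_window: int = 100
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_draws <= 0 or self.n_chains < 1:
            raise ValueError("need n_draws > 0 and n_chains >= 1")
        if self.burn_in < 0 or self.thin < 1:
            raise ValueError("need burn_in >= 0 and thin >= 1")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must lie in (0, 1)")

    def reduced(self, n_draws: int = 5_000, burn_in: int = 1_000) -> "MCMCConfig":
        """The same configuration at a smaller schedule (testing / demos)."""
        return MCMCConfig(
            n_chains=self.n_chains,
            n_draws=n_draws,
            burn_in=burn_in,
            thin=self.thin,
            seed=self.seed,
            target_accept=self.target_accept,
            adapt_window=self.adapt_window,
            init_scale=self.init_scale,
        )


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean and equal-tailed 95% credible interval for one quantity."""

    mean: float
    ci_low: float
    ci_high: float
    n_draws: int
    ess: float | None = None
    rhat: float | None = None

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("credible interval bounds out of order")

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_draws": self.n_draws,
            "ess": self.ess,
            "rhat": self.rhat,
        }


def _run_single_chain(
    log_target: Callable[[np.ndarray], float],
    x0: np.ndarray,
    blocks: Sequence[tuple[int, ...]],
    config: MCMCConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    x = np.array(x0, dtype=float)
    lp = float(log_target(x))
    if not np.isfinite(lp):
        raise ValueError(f"log target is not finite at initial point {x0}")
    scales = np.full(len(blocks), config.init_scale, dtype=float)
    accepted = np.zeros(len(blocks))
    proposed = np.zeros(len(blocks))
    out = np.empty((config.n_draws, x.size))
    total = config.burn_in + config.n_draws
    idx = [np.asarray(b, dtype=int) for b in blocks]
    for sweep in range(total):
        for bi, block in enumerate(idx):
            prop = x.copy()
            prop[block] = prop[block] + scales[bi] * rng.standard_normal(block.size)
            lpp = float(log_target(prop))
            proposed[bi] += 1
            if np.log(rng.uniform()) < lpp - lp:
                x, lp = prop, lpp
                accepted[bi] += 1
        adapting = sweep < config.burn_in
        if adapting and (sweep + 1) % config.adapt_window == 0:
            rates = accepted / proposed
            for bi, rate in enumerate(rates):
                if rate == 0.0:
                    warnings.warn(
                        f"block {bi}: every proposal rejected over an adaptation "
                        f"window (scale {scales[bi]:.3g})",
                        RuntimeWarning,
                        stacklevel=2,
                    )
            scales *= np.exp(2.0 * (rates - config.target_accept))
            accepted[:] = 0
            proposed[:] = 0
        if sweep >= config.burn_in:
            out[sweep - config.burn_in] = x
    return out


def run_chains(
    log_target: Callable[[np.ndarray], float],
    init: np.ndarray,
    config: MCMCConfig,
    blocks: Sequence[tuple[int, ...]] | None = None,
) -> np.ndarray:
    """Draw posterior samples; returns an array of shape (chains, draws, dim).

    ``init`` is either one starting point shared by all chains or an
    array of per-chain starting points. Identical (log_target, init,
    config) reproduce identical traces: each chain's generator is spawned
    deterministically from ``config.seed`` and the chain index.
    """
    init = np.atleast_2d(np.asarray(init, dtype=float))
    if init.shape[0] == 1:
        init = np.repeat(init, config.n_chains, axis=0)
    if init.shape[0] != config.n_chains:
        raise ValueError(f"got {init.shape[0]} starting points for {config.n_chains} chains")
    dim = init.shape[1]
    if blocks is None:
        blocks = [(j,) for j in range(dim)]
    covered = sorted(j for b in blocks for j in b)
    if covered != list(range(dim)):
        raise ValueError("blocks must partition the coordinate indices")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    traces = np.empty((config.n_chains, config.n_draws, dim))
    for c in range(config.n_chains):
        rng = np.random.Generator(np.random.PCG64(seeds[c]))
        traces[c] = _run_single_chain(log_target, init[c], blocks, config, rng)
    return traces


def thin_and_pool(traces: np.ndarray, thin: int) -> np.ndarray:
    """Keep every thin-th draw per chain (indices thin−1, 2·thin−1, …) and pool.

    Returns an array of shape (n_chains * floor(n_draws / thin), dim).
    """
    traces = np.asarray(traces)
    if traces.ndim != 3:
        raise ValueError("expected traces of shape (chains, draws, dim)")
    n_draws = traces.shape[1]
    if thin < 1 or thin > n_draws:
        raise ValueError(f"thin {thin} incompatible with trace length {n_draws}")
    kept = traces[:, thin - 1 :: thin, :]
    return kept.reshape(-1, traces.shape[2])


def summarize(
    draws: np.ndarray,
    transform: Callable[[np.ndarray], float] | None = None,
) -> PosteriorSummary:
    """Posterior mean and equal-tailed 95% CI of (a transform of) pooled draws.

    ``transform`` is applied per draw before summarizing — e.g. mapping a
    parameter vector to the expected proportion in a given year.
    """
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty set of draws")
    if transform is not None:
        if arr.ndim == 1:
            vals = np.asarray([transform(v) for v in arr], dtype=float)
        else:
            vals = np.asarray([transform(row) for row in arr], dtype=float)
    else:
        if arr.ndim != 1:
            raise ValueError("multi-dimensional draws require a transform")
        vals = arr
    if vals.size < 2:
        raise ValueError("need at least two draws to summarize")
    lo, hi = np.quantile(vals, [0.025, 0.975])
    return PosteriorSummary(
        mean=float(vals.mean()), ci_low=float(lo), ci_high=float(hi), n_draws=int(vals.size)
    )


def convergence(traces: np.ndarray) -> np.ndarray:
    """Split-chain R-hat per parameter (classical, non-rank-normalized form).

    Each chain is split in half; R-hat compares between- and within-
    sequence variance across the 2·m half-chains. Values near 1 indicate
    mixing; the advisory threshold is 1.01, reported but never enforced.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 3:
        raise ValueError("expected traces of shape (chains, draws, dim)")
    if traces.shape[0] < 2:
        raise ValueError("split-chain diagnostic requires at least two chains")
    half = traces.shape[1] // 2
    # stack first/second halves of every chain: (2*chains, half, dim)
    splits = np.concatenate([traces[:, :half, :], traces[:, half : 2 * half, :]], axis=0)
    n = splits.shape[1]
    chain_means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n - 1) / n * w + b / n
        rhat = np.sqrt(var_hat / w)
    # degenerate all-constant traces mix trivially
    return np.where((w == 0) & (b == 0), 1.0, rhat)
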