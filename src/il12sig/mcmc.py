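"""Metropolis–Hastings sampling with proposal tuning and convergence diagnostics.

The sampler targets an arbitrary log-posterior over a box domain with an
improper uniform prior: proposals falling outside the box are rejected.
New steps are proposed with independent zero-mean Gaussian increments per
parameter; the proposal scale is tuned during a discarded pilot phase so
that the acceptance fraction lands at a target (default 0.2), then frozen
before inference to preserve Markov-chain validity.

Convergence across multiple chains started from over-dispersed points is
assessed with the classic Gelman–Rubin potential scale reduction factor
(PSRF). For m chains of n post-burn-in draws with within-chain variances
``s_j^2`` and chain means ``x̄_j``::

    W    = mean_j s_j^2
    B/n  = var_j(x̄_j)            (sample variance over chain means)
    V̂    = (n - 1)/n * W + B/n
    PSRF = sqrt(V̂ / W)

(no rank normalization, no sampling-variability degrees-of-freedom
correction). A PSRF below 1.2 for every parameter declares convergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChainConfig",
    "ChainResult",
    "PosteriorSummary",
    "TuningError",
    "run_mcmc",
    "tune_proposals",
    "gelman_rubin",
    "summarize_posterior",
    "write_chains",
]

#: PSRF below this value declares multi-chain convergence.
PSRF_CONVERGED = 1.2

LogLik = Callable[[np.ndarray], float]
Domain = Sequence[tuple[float, float]]


class TuningError(RuntimeError):
    """Proposal tuning failed to reach the target acceptance fraction."""

    def __init__(self, message: str, last_acceptance: float):
        super().__init__(message)
        self.last_acceptance = last_acceptance


@dataclass
class ChainConfig:
    """Configuration of a multi-chain Metropolis–Hastings run.

    ``init_center`` / ``init_dispersion`` define the over-dispersed start
    box: each chain starts uniformly in ``center ± dispersion`` (clipped
    to the domain). The dispersion should span several times the expected
    posterior scale so the Gelman–Rubin diagnostic is meaningful.
    """

    n_steps: int
    init_center: tuple[float, ...]
    init_dispersion: tuple[float, ...]
    n_chains: int = 3
    target_acceptance: float = 0.2
    seed: int = 0
    burn_in: float = 0.5

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 for convergence diagnostics")
        if not (0 < self.target_acceptance < 1):
            raise ValueError("target_acceptance must be in (0, 1)")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be > 0")
        if not (0 <= self.burn_in < 1):
            raise ValueError("burn_in must be in [0, 1)")
        if len(self.init_center) != len(self.init_dispersion):
            raise ValueError("init_center and init_dispersion lengths differ")


@dataclass
class ChainResult:
    """Output of :func:`run_mcmc`.

    ``samples`` has shape (n_chains, n_steps, n_params); ``logpost``
    (n_chains, n_steps); ``accept_fraction`` one value per chain.
    """

    samples: np.ndarray
    logpost: np.ndarray
    accept_fraction: np.ndarray
    proposal_sd: np.ndarray
    burn_in: float
    psrf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.psrf is None:
            self.psrf = gelman_rubin(self.samples, self.burn_in)

    @property
    def converged(self) -> bool:
        return bool(np.all(self.psrf < PSRF_CONVERGED))

    def pooled(self, burn_in: float | None = None) -> np.ndarray:
        """Post-burn-in samples pooled across chains, shape (m*n_keep, k)."""
        b = self.burn_in if burn_in is None else burn_in
        n = self.samples.shape[1]
        start = int(np.floor(b * n))
        return self.samples[:, start:, :].reshape(-1, self.samples.shape[2])


@dataclass
class PosteriorSummary:
    """Posterior summary for one parameter of a pooled multi-chain sample."""

    median: float
    ml_value: np.ndarray  # full parameter vector at the highest visited log-posterior
    ci_95: tuple[float, float]
    tail_prob: float
    threshold: float

    @property
    def significant(self) -> bool:
        """True when P(parameter < threshold) < 0.05."""
        return self.tail_prob < 0.05


def _in_domain(x: np.ndarray, domain: Domain) -> bool:
    return all(lo <= xi <= hi for xi, (lo, hi) in zip(x, domain))


def _run_chain(
    loglik: LogLik,
    x0: np.ndarray,
    proposal_sd: np.ndarray,
    n_steps: int,
    domain: Domain,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    k = x0.size
    lo = np.array([d[0] for d in domain])
    hi = np.array([d[1] for d in domain])
    steps = rng.standard_normal((n_steps, k)) * proposal_sd
    log_u = np.log(rng.random(n_steps))
    samples = np.empty((n_steps, k))
    logpost = np.empty(n_steps)
    x = x0.copy()
    lp = loglik(x)
    n_accept = 0
    for t in range(n_steps):
        prop = x + steps[t]
        if np.all(prop >= lo) and np.all(prop <= hi):
            lp_prop = loglik(prop)
            if lp_prop - lp > log_u[t]:
                x = prop
                lp = lp_prop
                n_accept += 1
        samples[t] = x
        logpost[t] = lp
    return samples, logpost, n_accept / n_steps


def _draw_start(
    loglik: LogLik, config: ChainConfig, domain: Domain, rng: np.random.Generator
) -> np.ndarray:
    center = np.asarray(config.init_center, dtype=float)
    disp = np.asarray(config.init_dispersion, dtype=float)
    lo = np.maximum([d[0] for d in domain], center - disp)
    hi = np.minimum([d[1] for d in domain], center + disp)
    for _ in range(1000):
        x = rng.uniform(lo, hi)
        if np.isfinite(loglik(x)):
            return x
    raise RuntimeError(
        "could not find a finite-log-likelihood starting point in the init box"
    )


def tune_proposals(
    loglik: LogLik,
    config: ChainConfig,
    domain: Domain,
    initial_sd: np.ndarray | None = None,
    pilot_steps: int = 500,
    tolerance: float = 0.05,
    max_rounds: int = 40,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Tune the per-parameter proposal standard deviations.

    A pilot chain is run in rounds of ``pilot_steps``; after each round the
    sd vector is scaled multiplicatively toward the target acceptance
    fraction. All pilot samples are discarded. Returns sds whose pilot
    acceptance lies within ``target ± tolerance``.

    A completely flat target accepts every in-domain proposal regardless
    of scale; that case is detected (acceptance pinned at ~1 while the sd
    grows) and the initial sd is returned unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    disp = np.asarray(config.init_dispersion, dtype=float)
    sd = (disp / 10.0) if initial_sd is None else np.asarray(initial_sd, float).copy()
    sd0 = sd.copy()
    x0 = _draw_start(loglik, config, domain, rng)
    target = config.target_acceptance
    acceptances: list[float] = []
    for _ in range(max_rounds):
        samples, _, acc = _run_chain(loglik, x0, sd, pilot_steps, domain, rng)
        acceptances.append(acc)
        if abs(acc - target) <= tolerance:
            return sd
        # multiplicative update; the +0.1 floor keeps the factor finite at acc=0
        sd = sd * (acc + 0.1) / (target + 0.1)
        x0 = samples[-1]
    if all(a >= 0.99 for a in acceptances):
        return sd0  # flat target: acceptance cannot be driven below ~1
    raise TuningError(
        f"acceptance {acceptances[-1]:.3f} did not reach "
        f"{target}±{tolerance} in {max_rounds} rounds",
        last_acceptance=acceptances[-1],
    )


def run_mcmc(
    loglik: LogLik,
    config: ChainConfig,
    domain: Domain,
    proposal_sd: np.ndarray | None = None,
    tune: bool = True,
) -> ChainResult:
    """Run ``config.n_chains`` Metropolis–Hastings chains.

    Starting points are drawn uniformly from the over-dispersed init box.
    When ``proposal_sd`` is not given and ``tune`` is true, the proposal
    scale is tuned first (on a separate random substream) and frozen.
    The run is bit-reproducible for a fixed ``config.seed``.
    """
    k = len(config.init_center)
    if len(domain) != k:
        raise ValueError("domain length must match number of parameters")
    ss = np.random.SeedSequence(config.seed)
    child_seqs = ss.spawn(config.n_chains + 1)
    tune_rng = np.random.default_rng(child_seqs[0])

    if proposal_sd is None:
        if tune:
            proposal_sd = tune_proposals(loglik, config, domain, rng=tune_rng)
        else:
            proposal_sd = np.asarray(config.init_dispersion, float) / 10.0
    proposal_sd = np.asarray(proposal_sd, dtype=float)

    samples = np.empty((config.n_chains, config.n_steps, k))
    logpost = np.empty((config.n_chains, config.n_steps))
    accept = np.empty(config.n_chains)
    for j in range(config.n_chains):
        rng = np.random.default_rng(child_seqs[j + 1])
        x0 = _draw_start(loglik, config, domain, rng)
        s, lp, a = _run_chain(loglik, x0, proposal_sd, config.n_steps, domain, rng)
        samples[j], logpost[j], accept[j] = s, lp, a
    return ChainResult(
        samples=samples,
        logpost=logpost,
        accept_fraction=accept,
        proposal_sd=proposal_sd,
        burn_in=config.burn_in,
    )


def gelman_rubin(samples: np.ndarray, burn_in: float = 0.5) -> np.ndarray:
    """Classic potential scale reduction factor, one value per parameter.

    ``samples`` has shape (n_chains, n_steps, n_params). Raises on fewer
    than two chains, fewer than 10 post-burn-in draws, or a chain with
    zero within-chain variance (a stuck, degenerate chain).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3:
        raise ValueError("samples must have shape (n_chains, n_steps, n_params)")
    m = samples.shape[0]
    if m < 2:
        raise ValueError("need >= 2 chains for the Gelman-Rubin diagnostic")
    n_total = samples.shape[1]
    start = int(np.floor(burn_in * n_total))
    post = samples[:, start:, :]
    n = post.shape[1]
    if n < 10:
        raise ValueError(f"need >= 10 post-burn-in draws per chain, got {n}")
    chain_var = post.var(axis=1, ddof=1)  # (m, k)
    if np.any(chain_var == 0):
        raise ValueError("degenerate chain: zero within-chain variance")
    w = chain_var.mean(axis=0)
    chain_mean = post.mean(axis=1)  # (m, k)
    b_over_n = chain_mean.var(axis=0, ddof=1)
    v_hat = (n - 1) / n * w + b_over_n
    return np.sqrt(v_hat / w)


def summarize_posterior(
    result: ChainResult,
    burn_in: float | None = None,
    threshold: float = 0.0,
    param: int = 0,
    check_convergence: bool = True,
) -> PosteriorSummary:
    """Pooled posterior summary for one parameter.

    ``tail_prob`` is the fraction of pooled post-burn-in samples below
    ``threshold`` — the posterior tail probability used as the
    significance criterion (significant when below 0.05). ``ml_value``
    is the visited parameter vector with the highest log-posterior.
    """
    if check_convergence and not result.converged:
        raise RuntimeError(
            f"chains not converged (PSRF {result.psrf}); "
            "pass check_convergence=False to override"
        )
    pooled = result.pooled(burn_in)
    if pooled.shape[0] == 0:
        raise ValueError("empty pooled sample")
    x = pooled[:, param]
    lo, hi = np.percentile(x, [2.5, 97.5])
    flat_idx = int(np.argmax(result.logpost))
    chain, step = np.unravel_index(flat_idx, result.logpost.shape)
    return PosteriorSummary(
        median=float(np.median(x)),
        ml_value=result.samples[chain, step].copy(),
        ci_95=(float(lo), float(hi)),
        tail_prob=float(np.mean(x < threshold)),
        threshold=threshold,
    )


def write_chains(
    result: ChainResult,
    out_dir: str | Path,
    param_names: Sequence[str],
    config: ChainConfig | None = None,
) -> None:
    """Persist chains as one CSV per chain plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for j in range(result.samples.shape[0]):
        df = pd.DataFrame(result.samples[j], columns=list(param_names))
        df.insert(0, "step", np.arange(result.samples.shape[1]))
        df["logpost"] = result.logpost[j]
        df["accepted"] = np.concatenate(
            [[True], np.any(np.diff(result.samples[j], axis=0) != 0, axis=1)]
        )
        df.to_csv(out / f"chain_{j}.csv", index=False)
    manifest = {
        "param_names": list(param_names),
        "psrf": result.psrf.tolist(),
        "accept_fraction": result.accept_fraction.tolist(),
        "proposal_sd": result.proposal_sd.tolist(),
        "burn_in": result.burn_in,
        "converged": result.converged,
    }
    if config is not None:
        manifest["config"] = {
            "n_chains": config.n_chains,
            "n_steps": config.n_steps,
            "target_acceptance": config.target_acceptance,
            "seed": config.seed,
            "init_center": list(config.init_center),
            "init_dispersion": list(config.init_dispersion),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
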