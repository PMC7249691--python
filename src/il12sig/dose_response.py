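"""EC50-shift viability model for the IL-12 rescue of a cytotoxic drug.

The model describes the fraction of live cells after a drug challenge
(imatinib, concentration ``c_im`` in μM) in the presence of a cytokine
(IL-12, concentration ``c_il12`` in ng/mL)::

    live % = 100 * [1 - c_im / (c_im + EC50 * (1 + alpha * c_il12 / (c_il12 + K_d)))]

IL-12 enters only through a saturable right-shift of the drug's EC50:
at saturating IL-12 the effective EC50 is ``EC50 * (1 + alpha)``, so
``alpha`` is the fractional EC50 increase the cytokine can produce and
``K_d`` (default 40 ng/mL) is the IL-12 binding constant that sets the
half-maximal rescue concentration.

The likelihood used for posterior inference is the sum-of-squared-error
marginalized form ``L ∝ SSE**(-N/2)``, so :func:`neg_log_likelihood`
returns ``(N/2) * log(SSE)`` and no explicit noise variance is sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseParams",
    "ViabilityObservation",
    "predict_viability",
    "neg_log_likelihood",
    "read_viability_csv",
    "write_viability_csv",
]

#: Default IL-12 equilibrium binding constant (ng/mL); fixed, not inferred.
DEFAULT_KD = 40.0

VIABILITY_COLUMNS = ["c_im_uM", "c_il12_ng_ml", "live_pct", "assay"]


@dataclass(frozen=True)
class DoseResponseParams:
    """Parameters of the EC50-shift viability model.

    Parameters
    ----------
    ec50 : float
        Drug concentration producing a 50% viability drop in the absence
        of cytokine (μM, > 0).
    alpha : float
        Dimensionless rescue effect; the EC50 multiplier at saturating
        IL-12 is ``1 + alpha``. Must exceed -1 so the effective EC50
        stays positive at every cytokine dose.
    kd : float
        IL-12 equilibrium binding constant (ng/mL, > 0). Fixed at 40
        by default; exposed for configuration, never fitted.
    """

    ec50: float
    alpha: float
    kd: float = DEFAULT_KD

    def __post_init__(self) -> None:
        if not (self.ec50 > 0):
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if not (self.alpha > -1):
            raise ValueError(f"alpha must be > -1, got {self.alpha}")
        if not (self.kd > 0):
            raise ValueError(f"kd must be > 0, got {self.kd}")


@dataclass(frozen=True)
class ViabilityObservation:
    """One well of a viability assay.

    ``live_pct`` is nominally in [0, 100] but raw assay values above 100
    occur (plate noise) and are accepted unmodified — clipping before
    residual computation would bias the SSE.
    """

    c_im: float
    c_il12: float
    live_pct: float
    assay: str = "flow"

    def __post_init__(self) -> None:
        if self.c_im < 0:
            raise ValueError(f"c_im must be >= 0, got {self.c_im}")
        if self.c_il12 < 0:
            raise ValueError(f"c_il12 must be >= 0, got {self.c_il12}")


def predict_viability(
    params: DoseResponseParams,
    c_im: float | np.ndarray,
    c_il12: float | np.ndarray,
) -> float | np.ndarray:
    """Predicted percent live cells at the given drug and cytokine doses.

    Vectorized over ``c_im`` and ``c_il12``. Returns values in (0, 100]:
    100 at zero drug, 50 when the drug sits at its (IL-12-shifted)
    effective EC50.
    """
    c_im = np.asarray(c_im, dtype=float)
    c_il12 = np.asarray(c_il12, dtype=float)
    if np.any(c_im < 0) or np.any(c_il12 < 0):
        raise ValueError("doses must be non-negative")
    shift = 1.0 + params.alpha * c_il12 / (c_il12 + params.kd)
    out = 100.0 * (1.0 - c_im / (c_im + params.ec50 * shift))
    if out.ndim == 0:
        return float(out)
    return out


def sse(params: DoseResponseParams, obs: Sequence[ViabilityObservation]) -> float:
    """Sum of squared residuals of the observations around the model curve."""
    if len(obs) == 0:
        raise ValueError("observation list is empty")
    c_im = np.array([o.c_im for o in obs])
    c_il12 = np.array([o.c_il12 for o in obs])
    y = np.array([o.live_pct for o in obs])
    pred = predict_viability(params, c_im, c_il12)
    return float(np.sum((y - pred) ** 2))


def neg_log_likelihood(
    params: DoseResponseParams, obs: Sequence[ViabilityObservation]
) -> float:
    """Negative log of the SSE-marginalized likelihood, ``(N/2) log SSE``.

    Lower is better. A perfect fit (SSE = 0) is degenerate under this
    likelihood and is signalled by returning ``-inf``.
    """
    s = sse(params, obs)
    n = len(obs)
    if s == 0.0:
        return -math.inf
    return 0.5 * n * math.log(s)


def viability_loglik(
    obs: Sequence[ViabilityObservation], kd: float = DEFAULT_KD
):
    """Fast log-likelihood closure over (ec50, alpha) for MCMC sampling.

    Returns a callable mapping a parameter vector ``[ec50, alpha]`` to the
    log of the SSE-marginalized likelihood, ``-(N/2) log SSE``, with the
    observation arrays hoisted out of the sampling loop.
    """
    c_im = np.array([o.c_im for o in obs])
    c_il12 = np.array([o.c_il12 for o in obs])
    y = np.array([o.live_pct for o in obs])
    n = len(obs)
    rescue = c_il12 / (c_il12 + kd)

    def loglik(theta: np.ndarray) -> float:
        ec50, alpha = theta
        if ec50 <= 0 or alpha <= -1:
            return -math.inf
        pred = 100.0 * (1.0 - c_im / (c_im + ec50 * (1.0 + alpha * rescue)))
        s = float(np.sum((y - pred) ** 2))
        if s == 0.0:
            return math.inf
        return -0.5 * n * math.log(s)

    return loglik


def fit_viability_posterior(
    obs: Sequence[ViabilityObservation],
    n_steps: int = 50_000,
    n_chains: int = 3,
    seed: int = 0,
    kd: float = DEFAULT_KD,
    init_center: tuple[float, float] = (20.0, 2.0),
    init_dispersion: tuple[float, float] = (19.0, 2.9),
    burn_in: float = 0.5,
    check_convergence: bool = True,
):
    """Infer the posterior of (EC50, alpha) from viability data by MCMC.

    Tunes the proposal scale to a 0.2 acceptance fraction, runs
    ``n_chains`` chains from over-dispersed starts, checks the
    Gelman–Rubin diagnostic, and returns
    ``(ChainResult, {"ec50": PosteriorSummary, "alpha": PosteriorSummary})``.
    The flat prior is uniform over ec50 > 0, alpha > -1.
    """
    from il12sig import mcmc

    config = mcmc.ChainConfig(
        n_steps=n_steps,
        n_chains=n_chains,
        seed=seed,
        init_center=init_center,
        init_dispersion=init_dispersion,
        burn_in=burn_in,
    )
    domain = [(1e-12, math.inf), (-1.0 + 1e-12, math.inf)]
    loglik = viability_loglik(obs, kd=kd)
    result = mcmc.run_mcmc(loglik, config, domain)
    summaries = {
        "ec50": mcmc.summarize_posterior(
            result, param=0, check_convergence=check_convergence
        ),
        "alpha": mcmc.summarize_posterior(
            result, param=1, check_convergence=check_convergence
        ),
    }
    return result, summaries


def read_viability_csv(path: str | Path) -> list[ViabilityObservation]:
    """Read a viability table (columns ``c_im_uM, c_il12_ng_ml, live_pct, assay``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in VIABILITY_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"viability table {path} is missing columns: {missing}")
    if "assay" not in df.columns:
        df["assay"] = "flow"
    return [
        ViabilityObservation(
            c_im=float(r.c_im_uM),
            c_il12=float(r.c_il12_ng_ml),
            live_pct=float(r.live_pct),
            assay=str(r.assay),
        )
        for r in df.itertuples()
    ]


def write_viability_csv(obs: Iterable[ViabilityObservation], path: str | Path) -> None:
    """Write observations in the schema :func:`read_viability_csv` consumes."""
    df = pd.DataFrame(
        [(o.c_im, o.c_il12, o.live_pct, o.assay) for o in obs],
        columns=VIABILITY_COLUMNS,
    )
    df.to_csv(path, index=False)
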