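"""Maximum-likelihood mechanism fitting and Bayes-factor model selection.

Each candidate mechanism (canonical, non-canonical, hybrid) is fitted to
IL12RB2-stratified phospho data by minimizing the summed squared error

    SSE_i = Σ_u (Y_u - Y_model_i(Θ))²

over the mechanism's free parameters (positivity enforced by optimizing
on log10 scale from a deterministic multi-start grid). The strength of
evidence for mechanism i over mechanism j is the Bayes factor estimated
from the maximum-likelihood SSEs,

    B_ij = (SSE_i / SSE_j)^(-N_obs / 2),

graded on the conventional scale: 1–3 weak, 3–20 positive, 20–150
strong, > 150 very strong evidence.

The ligand binding constant K_C reflects extracellular binding affinity,
which should not depend on which intracellular readout is observed, so
:func:`fit_shared_kc` couples a cell line's pAkt and pSTAT4 fits through
a common K_C while every other parameter stays per-readout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from il12sig.receptor_models import (
    MechanismParams,
    PhosphoObservation,
    ReceptorContext,
    complex_density,
    total_akt_correction,
)

__all__ = [
    "ModelId",
    "FitResult",
    "BayesFactorMatrix",
    "predict_mfi",
    "fit_mechanism",
    "fit_shared_kc",
    "bayes_factor",
    "grade_evidence",
    "select_mechanism",
    "MODEL_IDS",
]

ModelId = Literal["canonical", "noncanonical", "hybrid"]
MODEL_IDS: tuple[ModelId, ...] = ("canonical", "noncanonical", "hybrid")

#: Free parameters per mechanism, in optimization order.
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "canonical": ("k_c", "tots", "k_d_phos"),
    "noncanonical": ("k_n", "tots", "k_d_phos"),
    "hybrid": ("k_c", "k_n", "tots", "k_d_phos"),
}

#: Bayes-factor evidence grades: upper edges of weak / positive / strong.
GRADE_EDGES = (3.0, 20.0, 150.0)


@dataclass(frozen=True)
class FitResult:
    """Optimum of one mechanism fitted to one (cell line, readout) dataset."""

    model_id: ModelId
    readout: str
    cell_line: str
    params: MechanismParams
    sse: float
    n_obs: int
    n_free: int

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")
        if self.n_obs <= self.n_free:
            raise ValueError(
                f"n_obs ({self.n_obs}) must exceed n_free ({self.n_free}) "
                "for the parameters to be identifiable"
            )


@dataclass
class BayesFactorMatrix:
    """Pairwise Bayes factors B_ij (row model i over column model j)."""

    models: tuple[str, ...]
    values: np.ndarray
    grades: list[list[str]]
    fits: dict[str, FitResult] = field(default_factory=dict)

    @property
    def ranked(self) -> list[str]:
        """Models ordered best (lowest SSE) first."""
        return sorted(self.models, key=lambda m: self.fits[m].sse)


def _as_arrays(obs: Sequence[PhosphoObservation]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    il12 = np.array([o.il12 for o in obs])
    copies = np.array([o.il12rb2_copies for o in obs])
    mfi = np.array([o.mfi for o in obs])
    return il12, copies, mfi


def _arc_total(
    model_id: str,
    il12: np.ndarray,
    totrc: np.ndarray,
    k_c: float,
    k_n: float,
) -> np.ndarray:
    if model_id == "canonical":
        return totrc * il12 / (k_c + il12)
    if model_id == "noncanonical":
        return totrc / (k_n + 1.0)
    if model_id == "hybrid":
        f = il12 / (k_c + il12)
        g = 1.0 / (k_n + 1.0)
        arc1 = totrc * f * (1.0 - g) / (1.0 - f * g)
        arc2 = (totrc - arc1) / (k_n + 1.0)
        return arc1 + arc2
    raise ValueError(f"unknown model_id {model_id!r}")


def predict_mfi(
    model_id: ModelId,
    params: MechanismParams,
    ctx: ReceptorContext,
    il12: np.ndarray,
    il12rb2_copies: np.ndarray,
    tots_per_obs: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted phospho-MFI for stratified observations.

    Each observation's TOTRC is the receptor-complex count implied by its
    subset's IL12RB2 copies under the context's stoichiometry. When
    ``tots_per_obs`` is given (total-Akt correction) it replaces
    ``params.tots`` element-wise.
    """
    totrc = np.asarray(ctx.complexes(np.asarray(il12rb2_copies, float)))
    arc = _arc_total(model_id, np.asarray(il12, float), totrc, params.k_c, params.k_n)
    tots = params.tots if tots_per_obs is None else np.asarray(tots_per_obs, float)
    return tots * arc / (params.k_d_phos + arc)


def _tots_per_obs(
    ctx: ReceptorContext, copies: np.ndarray, akt_correction: bool
) -> np.ndarray | None:
    if not akt_correction:
        return None
    density = ctx.complexes(copies) / (ctx.area_um2 * ctx.fsc_scale)
    return total_akt_correction(density)


def _start_grid(
    free: tuple[str, ...],
    copies: np.ndarray,
    mfi: np.ndarray,
    ctx: ReceptorContext,
) -> list[np.ndarray]:
    """Deterministic multi-start grid on log10 scale, centered on data scales."""
    centers = {
        "k_c": 10.0,  # ng/mL, mid-range of the tested dose span
        "k_n": 3.0,
        "tots": max(float(mfi.max()), 1.0) * 1.5,
        "k_d_phos": max(float(np.median(ctx.complexes(copies))), 1.0),
    }
    axes = [
        [math.log10(centers[p]) + d for d in (-1.5, 0.0, 1.5)] for p in free
    ]
    return [np.array(p) for p in itertools.product(*axes)]


def _multistart_minimize(objective, starts: list[np.ndarray]) -> tuple[float, np.ndarray | None]:
    """Coarse Nelder–Mead from every start, then polish the best few."""
    coarse = []
    for x0 in starts:
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400, "maxfev": 600},
        )
        coarse.append((float(res.fun), res.x))
    coarse.sort(key=lambda t: t[0])
    best_val, best_x = math.inf, None
    for _, x0 in coarse[:3]:
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000, "maxfev": 6000},
        )
        if res.fun < best_val:
            best_val, best_x = float(res.fun), res.x
    return best_val, best_x


def fit_mechanism(
    model_id: ModelId,
    observations: Sequence[PhosphoObservation],
    ctx: ReceptorContext,
    akt_correction: bool = False,
) -> FitResult:
    """Fit one mechanism to stratified phospho data by SSE minimization.

    Derivative-free (Nelder–Mead) local searches from a fixed grid of
    multi-starts on log10-scaled parameters; positivity holds by
    construction and the run is deterministic. With ``akt_correction``
    the per-observation total Akt replaces the free TOTS parameter.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    il12, copies, mfi = _as_arrays(observations)
    if np.unique(copies).size < 2:
        raise ValueError("observations must span >= 2 distinct il12rb2_copies values")
    if model_id != "noncanonical" and np.unique(il12).size < 2:
        raise ValueError(
            f"ligand-dependent model {model_id!r} needs >= 2 distinct il12 doses "
            "to identify k_c"
        )
    free = FREE_PARAMS[model_id]
    if akt_correction:
        free = tuple(p for p in free if p != "tots")
    tots_obs = _tots_per_obs(ctx, copies, akt_correction)

    def objective(log_theta: np.ndarray) -> float:
        # clamp to avoid float under/overflow of 10**v at extreme steps
        kwargs = {p: 10.0 ** min(max(v, -15.0), 15.0) for p, v in zip(free, log_theta)}
        params = MechanismParams(**kwargs)
        pred = predict_mfi(model_id, params, ctx, il12, copies, tots_obs)
        return float(np.sum((mfi - pred) ** 2))

    best_val, best_x = _multistart_minimize(objective, _start_grid(free, copies, mfi, ctx))
    if best_x is None:
        raise RuntimeError(f"all optimizer starts failed for model {model_id!r}")
    params = MechanismParams(**{p: 10.0 ** v for p, v in zip(free, best_x)})
    readouts = {o.readout for o in observations}
    cell_lines = {o.cell_line for o in observations}
    return FitResult(
        model_id=model_id,
        readout=readouts.pop() if len(readouts) == 1 else "mixed",
        cell_line=cell_lines.pop() if len(cell_lines) == 1 else "mixed",
        params=params,
        sse=best_val,
        n_obs=len(observations),
        n_free=len(free),
    )


def fit_shared_kc(
    model_id: ModelId,
    datasets: Mapping[str, Sequence[PhosphoObservation]],
    ctx: ReceptorContext,
    akt_correction_readouts: frozenset[str] | set[str] = frozenset(),
) -> dict[str, FitResult]:
    """Fit one mechanism to several readouts with a common K_C.

    ``datasets`` maps readout name (e.g. ``"pAkt"``/``"pSTAT4"``) to its
    observations for one cell line. All parameters except K_C remain
    per-readout; for a single readout this reduces exactly to
    :func:`fit_mechanism`. ``akt_correction_readouts`` names the readouts
    whose TOTS comes from the total-Akt/density relationship instead of
    being fitted.
    """
    if not datasets:
        raise ValueError("datasets must contain >= 1 readout")
    if model_id == "noncanonical":
        # no K_C in this mechanism: nothing to share
        return {
            r: fit_mechanism(model_id, obs, ctx, akt_correction=r in akt_correction_readouts)
            for r, obs in datasets.items()
        }
    if len(datasets) == 1:
        (readout, obs), = datasets.items()
        return {
            readout: fit_mechanism(
                model_id, obs, ctx, akt_correction=readout in akt_correction_readouts
            )
        }

    readouts = list(datasets)
    arrays = {r: _as_arrays(datasets[r]) for r in readouts}
    other = tuple(p for p in FREE_PARAMS[model_id] if p != "k_c")
    per_readout_free = {
        r: tuple(p for p in other if not (p == "tots" and r in akt_correction_readouts))
        for r in readouts
    }
    tots_obs = {
        r: _tots_per_obs(ctx, arrays[r][1], r in akt_correction_readouts)
        for r in readouts
    }

    # parameter vector: [log k_c] + concat(per-readout other params)
    offsets: dict[str, slice] = {}
    pos = 1
    for r in readouts:
        offsets[r] = slice(pos, pos + len(per_readout_free[r]))
        pos += len(per_readout_free[r])

    def unpack(x: np.ndarray) -> dict[str, MechanismParams]:
        k_c = 10.0 ** min(max(x[0], -15.0), 15.0)
        out = {}
        for r in readouts:
            kwargs = {
                p: 10.0 ** min(max(v, -15.0), 15.0)
                for p, v in zip(per_readout_free[r], x[offsets[r]])
            }
            out[r] = MechanismParams(k_c=k_c, **kwargs)
        return out

    def objective(x: np.ndarray) -> float:
        total = 0.0
        for r, params in unpack(x).items():
            il12, copies, mfi = arrays[r]
            pred = predict_mfi(model_id, params, ctx, il12, copies, tots_obs[r])
            total += float(np.sum((mfi - pred) ** 2))
        return total

    # multi-start: k_c axis crossed with the per-readout grid centers
    starts: list[np.ndarray] = []
    center_blocks = []
    for r in readouts:
        il12, copies, mfi = arrays[r]
        grid = _start_grid(per_readout_free[r], copies, mfi, ctx)
        center_blocks.append(grid[len(grid) // 2])  # central start per readout
    for kc_log in (-1.0, 0.5, 2.0):
        starts.append(np.concatenate([[kc_log], *center_blocks]))

    best_val, best_x = _multistart_minimize(objective, starts)
    assert best_x is not None
    params_by_readout = unpack(best_x)
    results = {}
    for r in readouts:
        il12, copies, mfi = arrays[r]
        pred = predict_mfi(model_id, params_by_readout[r], ctx, il12, copies, tots_obs[r])
        cell_lines = {o.cell_line for o in datasets[r]}
        results[r] = FitResult(
            model_id=model_id,
            readout=r,
            cell_line=cell_lines.pop() if len(cell_lines) == 1 else "mixed",
            params=params_by_readout[r],
            sse=float(np.sum((mfi - pred) ** 2)),
            n_obs=len(datasets[r]),
            n_free=len(per_readout_free[r]) + 1,
        )
    return results


def bayes_factor(fit_i: FitResult, fit_j: FitResult) -> float:
    """Evidence for model i over model j, ``(SSE_i / SSE_j)^(-N/2)``.

    Both fits must be to the same data (equal N_obs). Values above ~1e308
    saturate to ``inf``.
    """
    if fit_i.n_obs != fit_j.n_obs:
        raise ValueError(
            f"fits compare different data: n_obs {fit_i.n_obs} != {fit_j.n_obs}"
        )
    if fit_j.sse == 0.0:
        raise ZeroDivisionError("degenerate comparison: SSE_j = 0 (perfect fit)")
    if fit_i.sse == 0.0:
        return math.inf
    log_b = -0.5 * fit_i.n_obs * (math.log(fit_i.sse) - math.log(fit_j.sse))
    if log_b > 709.0:
        return math.inf
    return math.exp(log_b)


def grade_evidence(b: float) -> str:
    """Evidence grade on the conventional Bayes-factor scale.

    For b >= 1 the grade describes evidence for model i; for b < 1 the
    reciprocal 1/b is graded (evidence for the other model).
    """
    if not b > 0:
        raise ValueError("Bayes factor must be > 0")
    b_eff = b if b >= 1.0 else 1.0 / b
    weak, positive, strong = GRADE_EDGES
    if b_eff < weak:
        return "weak"
    if b_eff < positive:
        return "positive"
    if b_eff <= strong:
        return "strong"
    return "very_strong"


def select_mechanism(
    observations: Sequence[PhosphoObservation],
    ctx: ReceptorContext,
    akt_correction: bool = False,
) -> BayesFactorMatrix:
    """Fit all three mechanisms and compare them pairwise.

    Returns the 3x3 Bayes-factor matrix (row model i over column model
    j, diagonal 1) with evidence grades; entries above 150 carry the
    ``very_strong`` designation.
    """
    fits = {
        m: fit_mechanism(m, observations, ctx, akt_correction=akt_correction)
        for m in MODEL_IDS
    }
    values = np.empty((3, 3))
    grades: list[list[str]] = []
    for i, mi in enumerate(MODEL_IDS):
        row = []
        for j, mj in enumerate(MODEL_IDS):
            b = 1.0 if i == j else bayes_factor(fits[mi], fits[mj])
            values[i, j] = b
            row.append(grade_evidence(b) if i != j else "weak")
        grades.append(row)
    return BayesFactorMatrix(models=MODEL_IDS, values=values, grades=grades, fits=fits)
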