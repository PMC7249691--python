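"""Equilibrium receptor-activation mechanisms and the phosphorylation stage.

Three competing mechanisms produce an activated receptor complex (ARC)
from a pool of TOTRC total complexes per cell:

* canonical (ligand-dependent): reversible IL-12 binding,
  ``ARC = TOTRC * IL12 / (K_C + IL12)`` with ``K_C = k_r1/k_f1``;
* non-canonical (receptor-dependent): spontaneous activation,
  ``ARC = TOTRC / (K_N + 1)`` with ``K_N = k_r2/k_f2``, independent of
  ligand — the molecular-crowding mode enabled by receptor overexpression;
* hybrid: both routes at once, partitioning the pool into ligand-activated
  (ARC1) and spontaneously activated (ARC2) complexes.

Either kind of activated complex phosphorylates a signaling intermediate
(Akt or STAT4) with the same kinetics, opposed by a generic phosphatase,
giving the saturable steady state
``pS = TOTS * (ARC1 + ARC2) / (K_D + ARC1 + ARC2)``.

The raw rate constants and the phosphatase abundance enter only through
the ratios K_C, K_N, TOTS and K_D; individually they are unidentifiable
at equilibrium.

The module also carries the surface-density bookkeeping used to compare
cell lines on a common axis: receptor complexes per μm² of membrane
(heterodimer: one complex per IL12RB2 copy; homodimer: one per two
copies), with an optional forward-scatter size normalization, and the
empirical linear relationship between total Akt and receptor density used
to correct TOTS for receptor-correlated total-Akt expression.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MechanismParams",
    "ReceptorContext",
    "ActivationState",
    "PhosphoObservation",
    "arc_canonical",
    "arc_noncanonical",
    "arc_hybrid",
    "phospho_response",
    "complex_density",
    "total_akt_correction",
    "read_phospho_csv",
    "write_phospho_csv",
]

#: Membrane surface areas (μm²) estimated for the two cell lines.
DEFAULT_AREAS = {"2D6": 104.0, "B16F0": 344.0}

#: Slope and intercept of the total-Akt vs receptor-density relationship
#: (MFI per complexes/μm², MFI).
TOTAL_AKT_SLOPE = 0.352
TOTAL_AKT_INTERCEPT = 382.0

PHOSPHO_COLUMNS = ["cell_line", "readout", "il12_ng_ml", "il12rb2_copies", "mfi"]


@dataclass(frozen=True)
class MechanismParams:
    """Equilibrium and phospho-stage constants for one mechanism fit.

    k_c : ligand binding constant K_C (ng/mL); k_n : spontaneous
    activation constant K_N (dimensionless); tots : total signaling
    intermediate TOTS (MFI units); k_d_phos : phospho half-saturation
    K_D (activated-complex copies). All strictly positive.
    """

    k_c: float = 1.0
    k_n: float = 1.0
    tots: float = 1.0
    k_d_phos: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_c", "k_n", "tots", "k_d_phos"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class ReceptorContext:
    """Per-cell-line receptor bookkeeping.

    ``stoichiometry`` maps measured IL12RB2 copies to receptor complexes:
    ``heterodimer`` (IL12RB1:IL12RB2, complexes = IL12RB2 copies, the
    T-cell arrangement) or ``homodimer`` (IL12RB2:IL12RB2, complexes =
    copies / 2, the melanoma arrangement). ``fsc_scale`` is a
    forward-scatter cell-size normalization applied multiplicatively to
    the membrane area (subset mean FSC-A over the cell-line reference
    mean; 1 when no FSC data are available).
    """

    cell_line: str
    totrc: float = 0.0
    stoichiometry: Literal["heterodimer", "homodimer"] = "heterodimer"
    area_um2: float | None = None
    fsc_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.totrc < 0:
            raise ValueError("totrc must be >= 0")
        if self.stoichiometry not in ("heterodimer", "homodimer"):
            raise ValueError(f"unknown stoichiometry {self.stoichiometry!r}")
        if self.area_um2 is None:
            object.__setattr__(
                self, "area_um2", DEFAULT_AREAS.get(self.cell_line, 100.0)
            )
        if not (self.area_um2 > 0):
            raise ValueError("area_um2 must be > 0")
        if not (self.fsc_scale > 0):
            raise ValueError("fsc_scale must be > 0")

    def complexes(self, il12rb2_copies: float | np.ndarray) -> float | np.ndarray:
        """Receptor complexes implied by measured IL12RB2 copies."""
        copies = np.asarray(il12rb2_copies, dtype=float)
        out = copies if self.stoichiometry == "heterodimer" else copies / 2.0
        return float(out) if out.ndim == 0 else out

    def with_totrc_from_copies(self, il12rb2_copies: float) -> "ReceptorContext":
        return replace(self, totrc=float(self.complexes(il12rb2_copies)))


@dataclass(frozen=True)
class ActivationState:
    """Activated receptor complexes at equilibrium.

    ``arc1`` is the ligand-activated pool, ``arc2`` the spontaneously
    activated pool (zero for the pure ligand-dependent mechanism; by
    convention ``arc1`` is zero for the pure receptor-dependent one).
    """

    arc1: float
    arc2: float = 0.0

    def __post_init__(self) -> None:
        if self.arc1 < -1e-9 or self.arc2 < -1e-9:
            raise ValueError("activated complex counts must be >= 0")

    @property
    def total(self) -> float:
        return self.arc1 + self.arc2


@dataclass(frozen=True)
class PhosphoObservation:
    """One IL12RB2-stratified flow-cytometry subset at one treatment dose."""

    cell_line: str
    il12: float
    il12rb2_copies: float
    readout: Literal["pAkt", "pSTAT4"]
    mfi: float
    n_events: int | None = None

    def __post_init__(self) -> None:
        if self.il12 < 0:
            raise ValueError("il12 must be >= 0")
        if self.il12rb2_copies < 0:
            raise ValueError("il12rb2_copies must be >= 0")
        if self.mfi < 0:
            raise ValueError("mfi must be >= 0")


def arc_canonical(ctx: ReceptorContext, il12: float, k_c: float) -> ActivationState:
    """Ligand-dependent activation: ``ARC = TOTRC * IL12 / (K_C + IL12)``."""
    if il12 < 0:
        raise ValueError("il12 must be >= 0")
    if not k_c > 0:
        raise ValueError("k_c must be > 0")
    return ActivationState(arc1=ctx.totrc * il12 / (k_c + il12), arc2=0.0)


def arc_noncanonical(ctx: ReceptorContext, k_n: float) -> ActivationState:
    """Spontaneous activation: ``ARC = TOTRC / (K_N + 1)``, ligand-free."""
    if not k_n > 0:
        raise ValueError("k_n must be > 0")
    return ActivationState(arc1=0.0, arc2=ctx.totrc / (k_n + 1.0))


def arc_hybrid(
    ctx: ReceptorContext, il12: float, k_c: float, k_n: float
) -> ActivationState:
    """Both activation routes at once.

    The ligand-activated pool is
    ``ARC1 = TOTRC * f * (1 - g) / (1 - f * g)`` with
    ``f = IL12/(K_C + IL12)`` and ``g = 1/(K_N + 1)``, and the
    spontaneously activated remainder is
    ``ARC2 = (TOTRC - ARC1) / (K_N + 1)``. The state reduces to the
    non-canonical one at zero ligand and to the canonical one as
    K_N → ∞.
    """
    if il12 < 0:
        raise ValueError("il12 must be >= 0")
    if not (k_c > 0 and k_n > 0):
        raise ValueError("k_c and k_n must be > 0")
    f = il12 / (k_c + il12)
    g = 1.0 / (k_n + 1.0)
    arc1 = ctx.totrc * f * (1.0 - g) / (1.0 - f * g)
    arc2 = (ctx.totrc - arc1) / (k_n + 1.0)
    return ActivationState(arc1=arc1, arc2=arc2)


def phospho_response(params: MechanismParams, state: ActivationState) -> float:
    """Steady-state phospho-MFI for a given activation state.

    ``pS = TOTS * (ARC1 + ARC2) / (K_D + ARC1 + ARC2)`` — saturable in
    total activated complexes with the same kinetics for both pools,
    bounded above by TOTS.
    """
    arc = state.total
    return params.tots * arc / (params.k_d_phos + arc)


def complex_density(ctx: ReceptorContext) -> float:
    """Receptor complexes per μm² of (size-normalized) membrane.

    Uses ``ctx.totrc`` as the complex count and divides by
    ``area_um2 * fsc_scale``.
    """
    return ctx.totrc / (ctx.area_um2 * ctx.fsc_scale)


def total_akt_correction(density: float | np.ndarray) -> float | np.ndarray:
    """Estimated total Akt (MFI) at a given receptor density (complexes/μm²).

    The empirical linear relationship
    ``Total Akt (MFI) = 0.352 * density + 382`` derived from
    serum-saturated phospho-Akt measurements; used in place of a free
    TOTS when the receptor-correlated total-Akt correction is enabled.
    """
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise ValueError("density must be >= 0")
    out = TOTAL_AKT_SLOPE * density + TOTAL_AKT_INTERCEPT
    return float(out) if out.ndim == 0 else out


def read_phospho_csv(path: str | Path) -> list[PhosphoObservation]:
    """Read a stratified phospho table.

    Columns ``cell_line, readout, il12_ng_ml, il12rb2_copies, mfi`` are
    required; ``n_events`` is optional and used only for reporting.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PHOSPHO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phospho table {path} is missing columns: {missing}")
    has_events = "n_events" in df.columns
    return [
        PhosphoObservation(
            cell_line=str(r.cell_line),
            readout=str(r.readout),  # type: ignore[arg-type]
            il12=float(r.il12_ng_ml),
            il12rb2_copies=float(r.il12rb2_copies),
            mfi=float(r.mfi),
            n_events=int(r.n_events) if has_events and pd.notna(r.n_events) else None,
        )
        for r in df.itertuples()
    ]


def write_phospho_csv(obs: Iterable[PhosphoObservation], path: str | Path) -> None:
    """Write observations in the schema :func:`read_phospho_csv` consumes."""
    rows = []
    for o in obs:
        rows.append((o.cell_line, o.readout, o.il12, o.il12rb2_copies, o.mfi, o.n_events))
    df = pd.DataFrame(rows, columns=PHOSPHO_COLUMNS + ["n_events"])
    if df["n_events"].isna().all():
        df = df.drop(columns=["n_events"])
    df.to_csv(path, index=False)
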