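"""Chemical-shift-perturbation binding analysis.

The combined amide CSP is

    CSP = sqrt(ΔδH² + 0.1 ΔδN²)   [ppm]

and a 1:1 protein-ligand equilibrium at protein concentration P0 and
total ligand L0 follows the single-site quadratic isotherm

    CSP(L0) = Δδ_max · (P0 + L0 + K_D − sqrt((P0 + L0 + K_D)² − 4 P0 L0))
              / (2 P0).

The two-stage scheme used for titrations that do not reach saturation:
first a reference (wild-type) fit determines K_D and the per-residue
Δδ_max jointly; variant titrations are then fitted globally with those
Δδ_max values fixed and a single free K_D, and reported as the
fold-change K_D(variant)/K_D(reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

_KD_BOUNDS = (1e-12, 1e6)   # µM
_DMAX_BOUNDS = (1e-12, 10.0)  # ppm


@dataclass
class TitrationSeries:
    """Per-residue CSPs across ligand concentrations at fixed protein
    concentration.  ``data`` columns: residue, L0_uM, csp_ppm, flag;
    the flag value ``disappeared`` marks peaks lost to intermediate
    exchange, which are excluded point-wise from fits."""

    p0_uM: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.p0_uM <= 0:
            raise ValueError("protein concentration must be positive")
        d = self.data
        if (d["L0_uM"] < 0).any():
            raise ValueError("ligand concentrations must be non-negative")
        if (d["csp_ppm"] < 0).any():
            raise ValueError("CSPs must be non-negative")

    def points(self, residues: list[str]) -> pd.DataFrame:
        """Usable (not disappeared) titration points for the residues."""
        d = self.data
        sel = d["residue"].astype(str).isin([str(r) for r in residues])
        sel &= d["flag"].fillna("") != "disappeared"
        return d[sel]


@dataclass
class BindingFit:
    """Result of an isotherm fit."""

    residues: list[str]
    K_D: float
    delta_max: dict[str, float]
    K_D_stderr: float
    residual_sum: float
    fold_change: float | None = None
    delta_max_stderr: dict[str, float] = field(default_factory=dict)


def csp(delta_H: float, delta_N: float) -> float:
    """Combined 1H/15N chemical shift perturbation in ppm."""
    return float(np.sqrt(np.asarray(delta_H) ** 2 + 0.1 * np.asarray(delta_N) ** 2))


def isotherm(P0, L0, K_D, delta_max):
    """Single-site quadratic binding isotherm (ppm).

    Vectorized over L0.  The discriminant is non-negative for any valid
    concentrations; an internal assertion guards against misuse.
    """
    P0 = float(P0)
    if P0 <= 0:
        raise ValueError("P0 must be positive")
    L0 = np.asarray(L0, dtype=float)
    s = P0 + L0 + K_D
    disc = s**2 - 4.0 * P0 * L0
    assert np.all(disc >= -1e-9 * np.maximum(s**2, 1.0)), "negative discriminant"
    bound = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * P0)
    return delta_max * bound


def _multistart_least_squares(residual_fn, x0_list, bounds):
    best = None
    for x0 in x0_list:
        try:
            res = least_squares(residual_fn, x0, bounds=bounds, method="trf")
        except Exception:  # keep trying other starts
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        state = None if best is None else (best.x, best.fun)
        raise RuntimeError(f"isotherm fit did not converge; last iterate: {state}")
    return best


def _stderr_from_jacobian(res) -> np.ndarray:
    """Asymptotic standard errors from the Jacobian at the optimum."""
    m, n = res.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def fit_reference(series: TitrationSeries, residues: list[str]) -> BindingFit:
    """Joint fit of K_D and per-residue Δδ_max on the reference titration.

    All named residues share one K_D; each has its own Δδ_max.  Residuals
    are unweighted.  Requires at least 3 usable titration points per
    residue.  Three log-spaced K_D starts guard against the shallow χ²
    surface of unsaturated titrations.
    """
    residues = [str(r) for r in residues]
    pts = series.points(residues)
    groups = {r: g for r, g in pts.groupby(pts["residue"].astype(str))}
    for r in residues:
        if r not in groups or len(groups[r]) < 3:
            n = 0 if r not in groups else len(groups[r])
            raise ValueError(
                f"residue {r!r} has only {n} usable titration points (need >= 3)"
            )

    L0 = {r: groups[r]["L0_uM"].to_numpy(float) for r in residues}
    y = {r: groups[r]["csp_ppm"].to_numpy(float) for r in residues}

    def residual(x):
        kd = x[0]
        out = []
        for i, r in enumerate(residues):
            out.append(isotherm(series.p0_uM, L0[r], kd, x[1 + i]) - y[r])
        return np.concatenate(out)

    dmax0 = [max(y[r].max(), 1e-3) for r in residues]
    starts = [np.array([kd0] + dmax0) for kd0 in (10.0, 300.0, 5000.0)]
    lb = [_KD_BOUNDS[0]] + [_DMAX_BOUNDS[0]] * len(residues)
    ub = [_KD_BOUNDS[1]] + [_DMAX_BOUNDS[1]] * len(residues)
    res = _multistart_least_squares(residual, starts, (lb, ub))
    stderr = _stderr_from_jacobian(res)
    return BindingFit(
        residues=residues,
        K_D=float(res.x[0]),
        delta_max={r: float(res.x[1 + i]) for i, r in enumerate(residues)},
        K_D_stderr=float(stderr[0]),
        delta_max_stderr={r: float(stderr[1 + i]) for i, r in enumerate(residues)},
        residual_sum=float(2.0 * res.cost),
    )


def fit_relative(
    series_variant: TitrationSeries,
    reference_fit: BindingFit,
    residues: list[str] | None = None,
) -> BindingFit:
    """Global one-parameter K_D fit with Δδ_max fixed to the reference.

    All named residues' CSPs are fitted simultaneously with the single
    free K_D; the result carries ``fold_change =
    K_D(variant) / K_D(reference)``.
    """
    residues = [str(r) for r in (residues or reference_fit.residues)]
    for r in residues:
        if r not in reference_fit.delta_max:
            raise ValueError(f"reference fit has no Δδ_max for residue {r!r}")
    pts = series_variant.points(residues)
    groups = {r: g for r, g in pts.groupby(pts["residue"].astype(str))}
    for r in residues:
        if r not in groups or len(groups[r]) < 3:
            n = 0 if r not in groups else len(groups[r])
            raise ValueError(
                f"residue {r!r} has only {n} usable titration points (need >= 3)"
            )

    L0 = {r: groups[r]["L0_uM"].to_numpy(float) for r in residues}
    y = {r: groups[r]["csp_ppm"].to_numpy(float) for r in residues}
    dmax = {r: reference_fit.delta_max[r] for r in residues}

    def residual(x):
        kd = x[0]
        return np.concatenate(
            [isotherm(series_variant.p0_uM, L0[r], kd, dmax[r]) - y[r] for r in residues]
        )

    starts = [np.array([kd0]) for kd0 in (10.0, 300.0, 5000.0)]
    res = _multistart_least_squares(residual, starts, ([_KD_BOUNDS[0]], [_KD_BOUNDS[1]]))
    stderr = _stderr_from_jacobian(res)
    return BindingFit(
        residues=residues,
        K_D=float(res.x[0]),
        delta_max=dmax,
        K_D_stderr=float(stderr[0]),
        residual_sum=float(2.0 * res.cost),
        fold_change=float(res.x[0] / reference_fit.K_D),
    )
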