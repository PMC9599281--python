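"""Small-angle scattering: Guinier R_g, coarse Debye profiles, reduced χ².

The Guinier fit estimates R_g from the low-q expansion
``I(q) ≈ I0 exp(−q² R_g²/3)``, iterating the q_max cutoff until
``q_max · R_g`` equals a target (0.9, the customary bound for
disordered chains, instead of the 1.3 used for globular proteins).

Ensemble scattering uses a one-bead-per-residue Debye sum over Cα
positions with a uniform form factor — a deliberately coarse stand-in
for atomistic predictors with hydration layers, adequate for validating
the pipeline on synthetic ensembles but not equivalent to them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ensemble import WeightedEnsemble
from .io import ScatteringCurve

logger = logging.getLogger(__name__)


@dataclass
class GuinierFit:
    """Result of the iterative Guinier fit (R_g in the q unit's inverse)."""

    Rg: float
    I0: float
    q_max_used: float
    n_points_used: int
    n_iterations: int

    def __post_init__(self) -> None:
        if self.q_max_used * self.Rg > 0.9 + 0.05:
            logger.warning(
                "Guinier window exceeds q_max*Rg=0.9 (%.3f)",
                self.q_max_used * self.Rg,
            )


def _weighted_guinier(q, I, sigma):
    """Weighted linear fit of ln I vs q²; returns (Rg, I0).

    Weights are 1/σ_lnI² with the first-order propagation σ_lnI = σ/I.
    """
    if np.any(I <= 0):
        raise ValueError("non-positive intensities in the Guinier window")
    x = q**2
    y = np.log(I)
    w = (I / sigma) ** 2
    W = w.sum()
    xm = (w * x).sum() / W
    ym = (w * y).sum() / W
    sxx = (w * (x - xm) ** 2).sum()
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    if slope >= 0:
        raise ValueError("non-negative Guinier slope: Rg² < 0")
    return float(np.sqrt(-3.0 * slope)), float(np.exp(intercept))


def guinier_fit(
    curve: ScatteringCurve,
    target: float = 0.9,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> GuinierFit:
    """Iterative Guinier fit with a self-consistent q_max·Rg cutoff.

    Starting from a fit on the 10 lowest-q points, the window
    ``q <= target / Rg`` is re-fitted until Rg changes by less than
    ``tol`` (relative).  At least 5 points must remain below the cutoff.
    """
    q, I, s = curve.q, curve.I, curve.sigma
    if len(curve) < 5:
        raise ValueError("scattering curve needs at least 5 points")
    # Initial fit on the lowest 10 points; if noise leaves that window
    # without net decay (non-negative slope), widen it until it decays.
    n0 = min(10, len(curve))
    while True:
        try:
            rg, i0 = _weighted_guinier(q[:n0], I[:n0], s[:n0])
            break
        except ValueError:
            if n0 >= len(curve):
                raise
            n0 = min(2 * n0, len(curve))
    n_used = n0
    history = [rg]
    for it in range(1, max_iter + 1):
        mask = q <= target / rg
        n_used = int(mask.sum())
        if n_used < 5:
            raise ValueError(
                f"only {n_used} points below the q_max*Rg={target} cutoff "
                "(need >= 5)"
            )
        rg_new, i0 = _weighted_guinier(q[mask], I[mask], s[mask])
        history.append(rg_new)
        if abs(rg_new - rg) <= tol * rg:
            return GuinierFit(rg_new, i0, float(q[mask].max()), n_used, it)
        rg = rg_new
    raise RuntimeError(
        f"Guinier fit did not converge in {max_iter} iterations; "
        f"Rg trace: {[f'{r:.4g}' for r in history]}"
    )


def debye_profile(
    ensemble: WeightedEnsemble,
    q_grid: np.ndarray,
    form_factor: float = 1.0,
) -> ScatteringCurve:
    """Weighted ensemble scattering from a one-bead-per-residue Debye sum.

    Per frame, ``I_f(q) = Σ_ij f² sinc(q r_ij)`` over Cα beads with a
    uniform form factor f; the ensemble curve is the weight-averaged
    ``Σ_f w_f I_f(q)``.  ``q_grid`` must be in Å⁻¹ (coordinates are Å).
    The sigma column is a nominal 1% of I, so χ² comparisons stay defined.
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    q = np.asarray(q_grid, dtype=float)
    ca = ensemble.coords[:, :, ensemble.atom_index("CA"), :]
    w = ensemble.weights
    I = np.zeros(q.size)
    for f in range(ensemble.n_frames):
        diff = ca[f, :, None, :] - ca[f, None, :, :]
        r = np.sqrt((diff**2).sum(axis=-1))
        iu = np.triu_indices(r.shape[0], k=1)
        rij = r[iu]
        qr = q[:, None] * rij[None, :]
        # sinc handles qr=0; np.sinc uses sin(pi x)/(pi x)
        frame_I = r.shape[0] + 2.0 * np.sinc(qr / np.pi).sum(axis=1)
        I += w[f] * frame_I
    I *= form_factor**2
    return ScatteringCurve(q, I, np.maximum(0.01 * I, 1e-12), q_unit="A^-1")


def reduced_chi2(
    model: ScatteringCurve,
    data: ScatteringCurve,
    error_correction: float = 1.0,
    n_free_params: int | None = None,
    fit_background: bool = False,
) -> float:
    """Reduced χ² between a model curve and data.

    The model is linearly interpolated onto the data's q grid and a
    scale factor c (plus an optional constant background b) minimizing
    χ² is fitted first; the experimental σ are multiplied by
    ``error_correction`` (a user-supplied factor accounting for
    mis-estimated errors).  ``n_free_params`` defaults to the number of
    fitted nuisance parameters (1, or 2 with background).
    """
    if data.q.min() < model.q.min() - 1e-12 or data.q.max() > model.q.max() + 1e-12:
        raise ValueError("model q range does not cover the data")
    Im = np.interp(data.q, model.q, model.I)
    sig = error_correction * data.sigma
    y = data.I / sig
    if fit_background:
        A = np.column_stack([Im / sig, 1.0 / sig])
    else:
        A = (Im / sig)[:, None]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    k = A.shape[1] if n_free_params is None else n_free_params
    dof = max(len(data) - k, 1)
    return float((resid**2).sum() / dof)
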