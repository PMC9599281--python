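"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (composition profiling, binding
fits, scattering and diffusion estimators, ensemble census) can be
exercised on data from these generators, whose parameters define the
truth the analyses are expected to recover:

- two sequence populations with controlled per-residue frequencies;
- 1:1 binding titrations from the quadratic isotherm with Gaussian noise;
- backbone ensembles with a tunable contiguous transient helix, grown by
  a two-state along-chain Markov chain, plus metadynamics-like bias values;
- Guinier scattering curves and Stejskal-Tanner diffusion decays.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import binding, hydrodynamics
from .ensemble import WeightedEnsemble, ensemble_rg
from .geometry import build_backbone
from .io import CANONICAL_AA, ScatteringCurve, SequenceRecord, sequence_to_res_names

#: (phi, psi) of the ideal alpha helix, degrees.
HELIX_PHI_PSI = (-57.0, -47.0)

#: Coil basin centers (phi, psi) and mixture weights: beta, PPII, alpha_R.
COIL_BASINS = ((-135.0, 135.0), (-75.0, 150.0), (-60.0, -45.0))
COIL_WEIGHTS = (0.35, 0.45, 0.20)
COIL_JITTER_DEG = 15.0


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Sequence sets
# ---------------------------------------------------------------------------

def _as_freq_vector(freq) -> np.ndarray:
    """Accept a dict {aa: freq} or a 20-vector ordered like CANONICAL_AA."""
    if isinstance(freq, dict):
        v = np.array([freq.get(a, 0.0) for a in CANONICAL_AA], dtype=float)
    else:
        v = np.asarray(freq, dtype=float)
        if v.size != 20:
            raise ValueError("frequency vector must have 20 entries")
    if np.any(v < 0):
        raise ValueError("negative amino-acid frequency")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 (got {v.sum():.12f})")
    return v


def gen_sequence_sets(
    freq_query,
    freq_background,
    n_seqs: int = 500,
    length_range: tuple[int, int] = (50, 250),
    seed: int = 0,
    taxon_tags: tuple[str | None, str | None] = (None, None),
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Two sequence populations with stated per-residue frequencies.

    Residues are i.i.d. draws from the respective frequency vector;
    sequence lengths are uniform over ``length_range`` (inclusive).
    """
    rng = _rng(seed)
    fq = _as_freq_vector(freq_query)
    fb = _as_freq_vector(freq_background)
    aa = np.frombuffer(CANONICAL_AA.encode(), dtype="S1").astype("U1")

    def make(freq: np.ndarray, label: str, tag: str | None) -> list[SequenceRecord]:
        recs = []
        lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_seqs)
        for i, L in enumerate(lengths):
            seq = "".join(rng.choice(aa, size=L, p=freq))
            recs.append(SequenceRecord(f"{label}_{i:05d}", seq, tag))
        return recs

    return (
        make(fq, "query", taxon_tags[0]),
        make(fb, "background", taxon_tags[1]),
    )


def uniform_aa_frequencies(**overrides: float) -> dict[str, float]:
    """Uniform 20-letter frequencies with named overrides, renormalized
    over the untouched letters so the vector sums to one."""
    base = {a: 0.05 for a in CANONICAL_AA}
    fixed = sum(overrides.values())
    if fixed >= 1.0:
        raise ValueError("overrides must sum to less than 1")
    free = [a for a in CANONICAL_AA if a not in overrides]
    rest = (1.0 - fixed) / len(free)
    for a in free:
        base[a] = rest
    base.update(overrides)
    return base


# ---------------------------------------------------------------------------
# Binding titrations
# ---------------------------------------------------------------------------

@dataclass
class TitrationGroundTruth:
    """Known truth for a synthetic 1:1 titration.

    ``delta_max`` maps residue labels to their saturation CSP in ppm;
    concentrations are µM.
    """

    K_D: float
    delta_max: dict[str, float]
    P0: float = 50.0
    L0_list: tuple[float, ...] = (50.0, 150.0, 300.0, 450.0, 1000.0, 2000.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_D <= 0 or self.P0 <= 0:
            raise ValueError("K_D and P0 must be positive")
        if any(v <= 0 for v in self.delta_max.values()):
            raise ValueError("delta_max values must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_titration(truth: TitrationGroundTruth) -> "binding.TitrationSeries":
    """Forward-model a titration from the quadratic isotherm plus noise.

    The default ligand series corresponds to 1:1, 1:3, 1:6, 1:9, 1:20 and
    1:40 molar equivalents at 50 µM protein.  Noisy CSPs are clipped at
    zero (a CSP is a magnitude).
    """
    import pandas as pd

    rng = _rng(truth.seed)
    rows = []
    for res, dmax in truth.delta_max.items():
        for L0 in truth.L0_list:
            csp = binding.isotherm(truth.P0, L0, truth.K_D, dmax)
            if truth.noise_sd > 0:
                csp = max(csp + rng.normal(0.0, truth.noise_sd), 0.0)
            rows.append({"residue": res, "L0_uM": L0, "csp_ppm": csp, "flag": ""})
    return binding.TitrationSeries(p0_uM=truth.P0, data=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Backbone ensembles with a transient helix
# ---------------------------------------------------------------------------

@dataclass
class HelixModel:
    """Two-state along-chain Markov model of a contiguous transient helix.

    Walking N→C inside ``helix_region`` (1-based, inclusive), a coil
    residue nucleates a helix with probability ``p_nucleate`` and a
    helical residue stays helical with probability ``p_stay``; residues
    outside the region are always coil.  Helical residues take ideal
    alpha dihedrals plus Gaussian noise of ``dihedral_noise_deg``; coil
    residues sample a three-basin (beta / PPII / alpha_R) distribution.
    """

    n_residues: int
    helix_region: tuple[int, int]
    p_nucleate: float = 0.05
    p_stay: float = 0.95
    dihedral_noise_deg: float = 5.0
    sequence: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.helix_region
        if not (1 <= lo <= hi <= self.n_residues):
            raise ValueError("helix_region must lie within the chain")
        for p in (self.p_nucleate, self.p_stay):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")


def _sample_helix_flags(model: HelixModel, rng: np.random.Generator) -> np.ndarray:
    flags = np.zeros(model.n_residues, dtype=bool)
    lo, hi = model.helix_region
    state = False
    for i in range(lo - 1, hi):
        if state:
            state = rng.random() < model.p_stay
        else:
            state = rng.random() < model.p_nucleate
        flags[i] = state
    return flags


def gen_ensemble(model: HelixModel, n_frames: int = 100) -> WeightedEnsemble:
    """Generate backbone frames with ground-truth helical flags.

    The returned ensemble has zero bias (uniform weights) and carries
    the generated per-(frame, residue) helical flags in ``helix_truth``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _rng(model.seed)
    n = model.n_residues
    coords = np.empty((n_frames, n, 5, 3))
    truth = np.empty((n_frames, n), dtype=bool)

    basin_centers = np.array(COIL_BASINS)
    basin_p = np.array(COIL_WEIGHTS)
    for f in range(n_frames):
        flags = _sample_helix_flags(model, rng)
        truth[f] = flags
        phi = np.empty(n)
        psi = np.empty(n)
        helix_noise = rng.normal(0.0, model.dihedral_noise_deg, size=(n, 2))
        coil_idx = rng.choice(len(COIL_BASINS), size=n, p=basin_p)
        coil_jitter = rng.normal(0.0, COIL_JITTER_DEG, size=(n, 2))
        for i in range(n):
            if flags[i]:
                phi[i] = HELIX_PHI_PSI[0] + helix_noise[i, 0]
                psi[i] = HELIX_PHI_PSI[1] + helix_noise[i, 1]
            else:
                c = basin_centers[coil_idx[i]]
                phi[i] = c[0] + coil_jitter[i, 0]
                psi[i] = c[1] + coil_jitter[i, 1]
        coords[f] = build_backbone(phi, psi)

    if model.sequence is not None:
        res_names = sequence_to_res_names(model.sequence)
    else:
        res_names = ["ALA"] * n
    return WeightedEnsemble(coords, res_names, bias=None, helix_truth=truth)


def gen_bias(
    ensemble: WeightedEnsemble,
    bias_fn=None,
    kappa: float = 50.0,
    rg0: float | None = None,
) -> np.ndarray:
    """Metadynamics-like static bias per frame.

    The default collective variable is the per-frame Cα radius of
    gyration: ``V = kappa * (Rg - rg0)**2`` (kJ/mol, Rg in nm), with
    ``rg0`` defaulting to the ensemble mean so extended and compact
    frames are up-weighted symmetrically.  A custom ``bias_fn`` receives
    the per-frame Rg array and returns V.
    """
    rg = ensemble_rg(ensemble)
    if bias_fn is not None:
        v = np.asarray(bias_fn(rg), dtype=float)
    else:
        center = float(rg.mean()) if rg0 is None else rg0
        v = kappa * (rg - center) ** 2
    if v.shape != (ensemble.n_frames,):
        raise ValueError("bias function must return one value per frame")
    if not np.all(np.isfinite(v)):
        raise ValueError("bias values must be finite")
    return v


# ---------------------------------------------------------------------------
# Scattering and diffusion forward models
# ---------------------------------------------------------------------------

def gen_scattering(
    Rg_true: float,
    I0: float = 1.0,
    q_grid: np.ndarray | None = None,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> ScatteringCurve:
    """Guinier forward model: I = I0 exp(-q² Rg²/3) (1 + ε), ε ~ N(0, noise).

    ``Rg_true`` in nm, ``q_grid`` in nm⁻¹ (default 0.05–2.0).  The sigma
    column is ``I * noise_frac`` (or 1% of I for a noiseless curve, so
    weighted fits remain defined).
    """
    rng = _rng(seed)
    if q_grid is None:
        q_grid = np.linspace(0.05, 2.0, 200)
    q = np.asarray(q_grid, dtype=float)
    ideal = I0 * np.exp(-(q**2) * Rg_true**2 / 3.0)
    if noise_frac > 0:
        I = ideal * (1.0 + rng.normal(0.0, noise_frac, size=q.size))
        sigma = ideal * noise_frac
    else:
        I = ideal
        sigma = ideal * 0.01
    return ScatteringCurve(q, I, sigma)


def gen_debye_curve(
    Rg_true: float,
    I0: float = 1.0,
    q_grid: np.ndarray | None = None,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> ScatteringCurve:
    """Gaussian-chain (Debye) scattering: I/I0 = 2(exp(-x)-1+x)/x², x=q²Rg².

    Useful to probe the small Guinier bias on realistic chain scattering.
    """
    rng = _rng(seed)
    if q_grid is None:
        q_grid = np.linspace(0.02, 2.5, 300)
    q = np.asarray(q_grid, dtype=float)
    x = (q * Rg_true) ** 2
    ideal = I0 * 2.0 * (np.exp(-x) - 1.0 + x) / x**2
    if noise_frac > 0:
        I = ideal * (1.0 + rng.normal(0.0, noise_frac, size=q.size))
        sigma = ideal * noise_frac
    else:
        I = ideal
        sigma = ideal * 0.01
    return ScatteringCurve(q, I, sigma)


def gen_dosy(
    D_true: float,
    gradient_strengths: np.ndarray | None = None,
    Delta: float = 0.200,
    delta: float = 0.003,
    noise_sd: float = 0.0,
    seed: int = 0,
    I0: float = 1.0,
    max_gradient: float = 0.5,
) -> "hydrodynamics.DecayCurve":
    """Stejskal-Tanner decay: I(g) = I0 exp(-D γ² g² δ² (Δ - δ/3)) + noise.

    Defaults mirror the acquisition used for small IDPs: Δ = 200 ms,
    δ = 3 ms, gradients from 2% to 98% of a 0.5 T/m maximum, proton γ.
    ``noise_sd`` is additive, in units of I0.
    """
    rng = _rng(seed)
    if gradient_strengths is None:
        gradient_strengths = np.linspace(0.02, 0.98, 16) * max_gradient
    g = np.asarray(gradient_strengths, dtype=float)
    gamma = hydrodynamics.GAMMA_1H
    I = I0 * np.exp(-D_true * gamma**2 * g**2 * delta**2 * (Delta - delta / 3.0))
    if noise_sd > 0:
        I = I + rng.normal(0.0, noise_sd * I0, size=g.size)
        # magnitude-mode intensities never go negative; floor at a
        # detection limit well below the noise
        I = np.maximum(I, 1e-6 * I0)
    return hydrodynamics.DecayCurve(g=g, I=I, Delta=Delta, delta=delta, gamma=gamma)
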