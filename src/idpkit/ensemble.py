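"""Analysis of weighted conformational ensembles of disordered proteins.

A :class:`WeightedEnsemble` holds backbone coordinates (N, CA, C, O, H per
residue, in Å) for a set of frames together with an optional per-frame
static bias energy ``V`` (kJ/mol), e.g. the accumulated metadynamics bias
after the simulation has converged.  Unbiased ensemble averages are
recovered by weighting each frame with ``exp(V / kT)``.

The secondary-structure operator implements the classic
hydrogen-bond-energy based dictionary assignment: a backbone H-bond between
the carbonyl of residue *i* and the amide of residue *j* is scored with the
Coulomb four-point energy

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  [kcal/mol]

and accepted when ``E < -0.5`` kcal/mol.  Two consecutive n-turns
(i -> i+n H-bonds, n = 3, 4, 5) start a 3_10, alpha or pi helix
respectively; any of the three classes counts as "helical" for the census.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Boltzmann constant in kJ/(mol K).
KB_KJ_MOL_K = 0.008314462618

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 283.0

#: Backbone atom layout of every frame, in storage order.
BACKBONE_ATOMS = ("N", "CA", "C", "O", "H")

# H-bond energy constants: q1*q2*f = 0.42*0.20*332 = 27.888 kcal Å/mol
_HB_PREFACTOR = 0.084 * 332.0
_HB_CUTOFF = -0.5  # kcal/mol
_HB_MIN_DIST = 0.5  # Å; below this the pair is counted as clashing, E = min


@dataclass
class WeightedEnsemble:
    """Backbone ensemble with optional per-frame bias energies.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_residues, 5, 3)
        Cartesian coordinates in Å, atom axis ordered as
        ``("N", "CA", "C", "O", "H")``.
    res_names : list of str
        Three-letter residue names, length ``n_residues``.
    bias : ndarray, shape (n_frames,), optional
        Static bias energy V per frame in kJ/mol.  ``None`` means zero
        bias, i.e. uniform weights.
    temperature : float
        Temperature in K used for reweighting.
    helix_truth : ndarray of bool, optional
        Ground-truth helical flags per (frame, residue) when the ensemble
        was produced by the synthetic generator; analysis never reads it.
    """

    coords: np.ndarray
    res_names: list[str]
    bias: np.ndarray | None = None
    temperature: float = DEFAULT_TEMPERATURE
    helix_truth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[2] != len(BACKBONE_ATOMS) \
                or self.coords.shape[3] != 3:
            raise ValueError(
                "coords must have shape (n_frames, n_residues, 5, 3); "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.res_names) != self.coords.shape[1]:
            raise ValueError("res_names length must match the residue axis")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != (self.n_frames,):
                raise ValueError(
                    f"bias has {self.bias.shape} entries for "
                    f"{self.n_frames} frames"
                )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, name: str) -> int:
        return BACKBONE_ATOMS.index(name)

    @property
    def weights(self) -> np.ndarray:
        """Normalized frame weights ``exp(V/kT)/Z`` (uniform if no bias)."""
        if self.bias is None:
            return np.full(self.n_frames, 1.0 / self.n_frames)
        return reweight(self.bias, self.temperature)


def reweight(bias: np.ndarray, temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Boltzmann weights from a static bias, w_f ∝ exp(V_f / kT).

    The maximum bias is subtracted before exponentiation so arbitrarily
    large biases do not overflow.
    """
    v = np.asarray(bias, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("bias values must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = v / (KB_KJ_MOL_K * temperature)
    x -= x.max()
    w = np.exp(x)
    return w / w.sum()


def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> np.ndarray:
    """Radius of gyration in nm for one frame or a stack of frames.

    Parameters
    ----------
    coords : ndarray, shape (..., n_points, 3)
        Point coordinates in Å (typically the Cα atoms, matching the
        collective variable biased in the simulations).
    masses : ndarray, optional
        Per-point masses; uniform if omitted.
    """
    xyz = np.asarray(coords, dtype=float)
    if masses is None:
        m = np.ones(xyz.shape[-2])
    else:
        m = np.asarray(masses, dtype=float)
    mtot = m.sum()
    com = (xyz * m[:, None]).sum(axis=-2) / mtot
    d2 = ((xyz - com[..., None, :]) ** 2).sum(axis=-1)
    rg_A = np.sqrt((d2 * m).sum(axis=-1) / mtot)
    return rg_A / 10.0  # Å -> nm


def ensemble_rg(ensemble: WeightedEnsemble) -> np.ndarray:
    """Per-frame Cα radius of gyration (nm)."""
    ca = ensemble.coords[:, :, ensemble.atom_index("CA"), :]
    return radius_of_gyration(ca)


def _hbond_energy(o: np.ndarray, c: np.ndarray, n: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Electrostatic H-bond energy (kcal/mol) for arrays of O,C vs N,H atoms."""
    def dist(a, b):
        return np.sqrt(((a - b) ** 2).sum(axis=-1))

    r_on = dist(o, n)
    r_ch = dist(c, h)
    r_oh = dist(o, h)
    r_cn = dist(c, n)
    r = np.stack([r_on, r_ch, r_oh, r_cn])
    clash = (r < _HB_MIN_DIST).any(axis=0)
    with np.errstate(divide="ignore"):
        e = _HB_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return np.where(clash, -9.9, e)


def backbone_hbonds(frame: np.ndarray) -> np.ndarray:
    """Boolean matrix hb[i, j]: CO of residue i H-bonds the NH of residue j.

    ``frame`` has shape (n_residues, 5, 3) in the standard atom order.
    Donors at the chain start (no amide H defined) and pairs |i-j| < 2
    are excluded, matching the dictionary convention.
    """
    n_res = frame.shape[0]
    o = frame[:, BACKBONE_ATOMS.index("O"), :]
    c = frame[:, BACKBONE_ATOMS.index("C"), :]
    n = frame[:, BACKBONE_ATOMS.index("N"), :]
    h = frame[:, BACKBONE_ATOMS.index("H"), :]

    e = _hbond_energy(
        o[:, None, :], c[:, None, :], n[None, :, :], h[None, :, :]
    )
    hb = e < _HB_CUTOFF
    ii, jj = np.indices((n_res, n_res))
    hb &= np.abs(ii - jj) >= 2
    hb[:, 0] = False  # N-terminal amide has no defined H
    return hb


def assign_secondary_structure(
    frame: np.ndarray, pi_over_alpha: bool = False
) -> np.ndarray:
    """Per-residue helix class for one frame: 'H', 'G', 'I' or '-'.

    Minimal helices follow the turn rule: an n-turn at residue i is an
    H-bond CO(i) -> NH(i+n); two consecutive n-turns (at i-1 and i) mark
    residues i..i+n-1 as helical of the corresponding class.  Classic
    precedence is alpha ('H') over 3_10 ('G') over pi ('I');
    ``pi_over_alpha=True`` switches to the modern ordering where pi wins.
    """
    n_res = frame.shape[0]
    hb = backbone_hbonds(np.asarray(frame, dtype=float))

    def helix_mask(n_turn: int) -> np.ndarray:
        turn = np.zeros(n_res, dtype=bool)
        idx = np.arange(n_res - n_turn)
        turn[idx] = hb[idx, idx + n_turn]
        mask = np.zeros(n_res, dtype=bool)
        for i in range(1, n_res - n_turn):
            if turn[i - 1] and turn[i]:
                mask[i : i + n_turn] = True
        return mask

    g_mask = helix_mask(3)
    h_mask = helix_mask(4)
    i_mask = helix_mask(5)

    ss = np.full(n_res, "-", dtype="<U1")
    if pi_over_alpha:
        order = [("G", g_mask), ("H", h_mask), ("I", i_mask)]
    else:
        order = [("I", i_mask), ("G", g_mask), ("H", h_mask)]
    for label, mask in order:
        ss[mask] = label
    return ss


def is_helical(ss: np.ndarray) -> np.ndarray:
    """Helical flag: any of alpha, 3_10 or pi counts."""
    return np.isin(ss, ("H", "G", "I"))


def helix_census(
    ensemble: WeightedEnsemble, pi_over_alpha: bool = False
) -> np.ndarray:
    """Weighted per-residue helical fraction across the ensemble.

    Frames are weighted by the reweighted (unbiased) frame weights; with a
    constant bias this reduces to the plain average over frames.
    """
    w = ensemble.weights
    frac = np.zeros(ensemble.n_residues)
    for f in range(ensemble.n_frames):
        ss = assign_secondary_structure(ensemble.coords[f], pi_over_alpha)
        frac += w[f] * is_helical(ss)
    return frac


def contact_map(
    ensemble: WeightedEnsemble, cutoff: float = 8.5, stride: int = 10
) -> np.ndarray:
    """Weighted Cα-Cα contact frequencies.

    A residue pair is in contact in a frame when their Cα distance is at
    or below ``cutoff`` (Å).  Every ``stride``-th frame is used and the
    frame weights are renormalized over the strided subset, so the map is
    the weighted fraction of (sampled) time each pair spends in contact.
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    sel = np.arange(0, ensemble.n_frames, stride)
    w = ensemble.weights[sel]
    w = w / w.sum()
    ca = ensemble.coords[sel, :, ensemble.atom_index("CA"), :]
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    contacts = (d <= cutoff).astype(float)
    # round-off from the weighted sum can leave 1 + eps; entries are frequencies
    return np.clip(np.einsum("f,fij->ij", w, contacts), 0.0, 1.0)


def contact_log_ratio(
    map_variant: np.ndarray,
    map_reference: np.ndarray,
    pseudocount: float | None = None,
    n_frames_used: int | None = None,
) -> np.ndarray:
    """Natural-log ratio map log((f_var + p) / (f_ref + p)).

    The pseudocount regularizes pairs never seen in contact; by default
    it is half a count, ``1/(2 * n_frames_used)``.
    """
    fv = np.asarray(map_variant, dtype=float)
    fr = np.asarray(map_reference, dtype=float)
    if fv.shape != fr.shape:
        raise ValueError("contact maps must have matching shapes")
    if pseudocount is None:
        if n_frames_used is None:
            raise ValueError("provide pseudocount or n_frames_used")
        pseudocount = 1.0 / (2.0 * n_frames_used)
    return np.log(fv + pseudocount) - np.log(fr + pseudocount)


def block_average_error(
    series: np.ndarray,
    weights: np.ndarray | None = None,
    plateau_rtol: float = 0.05,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Standard error of a correlated series by block averaging.

    The series is cut into contiguous blocks of size 2^k; the error of the
    mean at each block size is the standard deviation of the block means
    over sqrt(n_blocks).  For correlated data the estimate grows with the
    block size until blocks are effectively independent; the reported
    error is read off at the smallest block size where the estimate
    changes by less than ``plateau_rtol`` over the next two doublings.
    If no block size satisfies the rule the largest usable size is used
    and a warning is logged.

    Returns ``(error, block_sizes, block_errors)``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise ValueError("weights must match the series")
    else:
        w = np.ones(n)
    if n < 8:
        raise ValueError("series too short for block averaging (need >= 8 points)")

    sizes, errors = [], []
    size = 1
    while n // size >= 8:
        nb = n // size
        xb = x[: nb * size].reshape(nb, size)
        wb = w[: nb * size].reshape(nb, size)
        bw = wb.sum(axis=1)
        bm = (xb * wb).sum(axis=1) / bw
        p = bw / bw.sum()
        mean = (p * bm).sum()
        var = (p * (bm - mean) ** 2).sum() / max(1.0 - (p**2).sum(), 1e-300)
        errors.append(np.sqrt(var * (p**2).sum()))
        sizes.append(size)
        size *= 2
    sizes = np.array(sizes)
    errors = np.array(errors)

    chosen = None
    for k in range(len(sizes) - 2):
        ref = errors[k]
        nxt = errors[k + 1 : k + 3]
        if ref == 0.0 and np.all(nxt == 0.0):
            chosen = k
            break
        if ref > 0 and np.all(np.abs(nxt - ref) <= plateau_rtol * ref):
            chosen = k
            break
    if chosen is None:
        # No block size satisfied the strict rule (noisy error curve).
        # The theoretical curve rises monotonically to its plateau, so the
        # maximum over block sizes that still retain >= 32 blocks is a
        # conservative plateau proxy.
        stable = n // sizes >= 32
        cand = np.flatnonzero(stable) if stable.any() else np.arange(len(sizes))
        chosen = cand[np.argmax(errors[cand])]
        logger.warning(
            "block-averaging error curve did not satisfy the plateau rule; "
            "reporting the maximum estimate (block size %d)", sizes[chosen],
        )
    return float(errors[chosen]), sizes, errors


def weighted_mean(series: np.ndarray, weights: np.ndarray) -> float:
    """Weighted ensemble average of a per-frame observable."""
    w = np.asarray(weights, dtype=float)
    return float((np.asarray(series, dtype=float) * w).sum() / w.sum())
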