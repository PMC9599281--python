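"""Secondary chemical shifts and the fractional-helicity statistic.

The secondary chemical shift (SCS) of a nucleus is the observed shift
minus the random-coil reference shift,

    SCS = Δδ = δ_observed − δ_random-coil ,

so positive Cα SCS reports helical propensity and negative SCS extended
structure.  The fractional helicity of a residue window is the mean Cα
SCS over the window divided by the mean Cα SCS of a fully formed helix
(reference_max_helix, ppm), reported as a percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: Literature bracket for the Cα SCS of a fully formed helix (ppm); the
#: default reference is their midpoint.
REFERENCE_MAX_HELIX_LOW = 3.1
REFERENCE_MAX_HELIX_HIGH = 3.8
DEFAULT_REFERENCE_MAX_HELIX = 0.5 * (REFERENCE_MAX_HELIX_LOW + REFERENCE_MAX_HELIX_HIGH)


@dataclass
class HelicityResult:
    """Fractional helicity of a residue window."""

    residue_range: tuple[int, int]
    mean_scs_ca: float
    reference_max_helix: float
    n_residues_used: int
    n_residues_missing: int

    @property
    def helicity_fraction(self) -> float:
        return self.mean_scs_ca / self.reference_max_helix

    @property
    def helicity_percent(self) -> float:
        return 100.0 * self.helicity_fraction


def secondary_shifts(observed: pd.DataFrame, random_coil: pd.DataFrame) -> pd.DataFrame:
    """Elementwise SCS on the intersection of the two shift tables.

    Both inputs are shift tables (columns residue_number, residue_type,
    nucleus, shift_ppm).  Entries present in only one table are dropped
    with a logged count; zero overlap is an error.
    """
    keys = ["residue_number", "nucleus"]
    merged = observed.merge(
        random_coil, on=keys, suffixes=("_obs", "_rc"), how="inner"
    )
    n_dropped = len(observed) + len(random_coil) - 2 * len(merged)
    if merged.empty:
        raise ValueError("observed and random-coil tables share no entries")
    if n_dropped:
        logger.info("dropped %d unmatched shift entries", n_dropped)
    out = merged[keys].copy()
    out["residue_type"] = merged["residue_type_obs"]
    out["scs_ppm"] = merged["shift_ppm_obs"] - merged["shift_ppm_rc"]
    return out.sort_values(keys).reset_index(drop=True)


def fractional_helicity(
    scs: pd.DataFrame,
    residue_range: tuple[int, int],
    reference_max_helix: float = DEFAULT_REFERENCE_MAX_HELIX,
) -> HelicityResult:
    """Fractional helicity over an inclusive residue window.

    Only Cα SCS values inside the window enter the mean; residues with
    no Cα SCS are skipped (never imputed) and counted as missing.
    """
    first, last = residue_range
    if last < first:
        raise ValueError("empty residue range")
    ca = scs[(scs["nucleus"] == "CA")
             & (scs["residue_number"] >= first)
             & (scs["residue_number"] <= last)]
    n_expected = last - first + 1
    if ca.empty:
        raise ValueError(
            f"no Cα secondary shifts in residue range {first}-{last}"
        )
    mean_scs = float(ca["scs_ppm"].mean())
    return HelicityResult(
        residue_range=(first, last),
        mean_scs_ca=mean_scs,
        reference_max_helix=reference_max_helix,
        n_residues_used=len(ca),
        n_residues_missing=n_expected - len(ca),
    )


def relative_change(h_ref: float, h_var: float) -> float:
    """Relative change of a helicity (or any positive statistic), percent:
    ``100 * (h_var - h_ref) / h_ref``."""
    if h_ref == 0:
        raise ValueError("reference helicity is zero; relative change undefined")
    return 100.0 * (h_var - h_ref) / h_ref
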