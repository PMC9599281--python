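"""Readers and writers for every external representation the pipeline touches.

Formats
-------
- FASTA for sequence sets (taxonomy carried in a ``taxon=`` header key);
- a simple CSV dialect for chemical-shift tables, titrations, diffusion
  decays and bias traces;
- 3-column whitespace text (q, I, sigma; ``#`` comments) for scattering
  curves;
- multi-model PDB (MODEL/ENDMDL) for backbone ensembles.

Readers validate strictly and never silently drop rows: every discard is
logged with a count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .ensemble import BACKBONE_ATOMS, WeightedEnsemble

logger = logging.getLogger(__name__)

#: The 20 canonical one-letter amino-acid codes, alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Nuclei for which chemical shifts are accepted.
NUCLEI = ("CA", "CB", "C", "N", "H", "HA")

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class SequenceRecord:
    """A labeled protein sequence with an optional taxonomy tag."""

    id: str
    sequence: str
    taxon_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")


@dataclass
class ScatteringCurve:
    """Small-angle scattering curve: q (nm^-1 by default), I, sigma."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    q_unit: str = "nm^-1"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise ValueError("q, I, sigma must have equal length")
        if np.any(self.q <= 0):
            raise ValueError("q values must be positive")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma values must be positive")
        if np.any(np.diff(self.q) < 0):
            logger.warning("scattering curve q not sorted; sorting")
            order = np.argsort(self.q)
            self.q, self.I, self.sigma = self.q[order], self.I[order], self.sigma[order]
        if np.any(np.diff(self.q) == 0):
            raise ValueError("duplicate q values")

    def __len__(self) -> int:
        return self.q.size


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, strict: bool = True) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    A ``taxon=<tag>`` key anywhere in the header line populates
    ``taxon_tag``.  In strict mode (default) any residue outside the
    canonical 20-letter alphabet raises; in permissive mode the offending
    sequence is dropped and the discard logged, so composition statistics
    are never contaminated by ambiguity codes.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = None
        for token in rec.description.split():
            if token.startswith("taxon="):
                taxon = token.split("=", 1)[1]
        seq = str(rec.seq).upper()
        bad = sorted(set(seq) - set(CANONICAL_AA))
        if bad:
            if strict:
                raise ValueError(
                    f"record {rec.id!r} contains non-canonical residue(s) "
                    f"{''.join(bad)!r}"
                )
            n_dropped += 1
            continue
        records.append(SequenceRecord(rec.id, seq, taxon))
    if n_dropped:
        logger.warning("dropped %d sequence(s) with non-canonical residues", n_dropped)
    if not records:
        raise ValueError(f"no valid sequences in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    bio = []
    for r in records:
        desc = f"taxon={r.taxon_tag}" if r.taxon_tag else ""
        bio.append(_BioRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(bio, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# Chemical-shift tables
# ---------------------------------------------------------------------------

SHIFT_COLUMNS = ["residue_number", "residue_type", "nucleus", "shift_ppm"]


def validate_shift_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a shift table: required columns, unique (residue, nucleus),
    finite shifts, known nuclei."""
    missing = set(SHIFT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"shift table missing columns: {sorted(missing)}")
    df = df[SHIFT_COLUMNS].copy()
    df["residue_number"] = df["residue_number"].astype(int)
    df["shift_ppm"] = pd.to_numeric(df["shift_ppm"], errors="raise")
    if not np.all(np.isfinite(df["shift_ppm"])):
        raise ValueError("non-finite shift values")
    unknown = set(df["nucleus"]) - set(NUCLEI)
    if unknown:
        raise ValueError(f"unknown nuclei: {sorted(unknown)}")
    dup = df.duplicated(subset=["residue_number", "nucleus"])
    if dup.any():
        pairs = df.loc[dup, ["residue_number", "nucleus"]].values.tolist()
        raise ValueError(f"duplicate (residue, nucleus) entries: {pairs}")
    return df.sort_values(["residue_number", "nucleus"]).reset_index(drop=True)


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Read the package's shift-table CSV (header row required)."""
    return validate_shift_table(pd.read_csv(path))


def write_shift_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_shift_table(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Titration tables
# ---------------------------------------------------------------------------

TITRATION_COLUMNS = ["residue", "L0_uM", "csp_ppm", "flag"]


def read_titration(path: str | Path, p0_uM: float) -> "TitrationSeries":
    """Read a titration CSV (residue, L0_uM, csp_ppm, flag).

    ``flag`` is free text; the value ``disappeared`` marks points where the
    peak was lost to intermediate exchange (excluded from fits).
    """
    from .binding import TitrationSeries

    df = pd.read_csv(path)
    missing = set(TITRATION_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"titration table missing columns: {sorted(missing)}")
    if "flag" not in df.columns:
        df["flag"] = ""
    df["flag"] = df["flag"].fillna("")
    return TitrationSeries(p0_uM=p0_uM, data=df[TITRATION_COLUMNS])


def write_titration(series: "TitrationSeries", path: str | Path) -> None:
    series.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scattering curves
# ---------------------------------------------------------------------------

def read_scattering(path: str | Path, q_unit: str = "nm^-1") -> ScatteringCurve:
    """Read 3-column whitespace text (q, I, sigma); ``#`` starts a comment."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 3:
        raise ValueError("scattering file needs 3 columns: q I sigma")
    if arr.shape[0] < 5:
        raise ValueError("scattering curve needs at least 5 points")
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], q_unit=q_unit)


def write_scattering(curve: ScatteringCurve, path: str | Path) -> None:
    header = f"q ({curve.q_unit})  I  sigma"
    np.savetxt(
        path, np.column_stack([curve.q, curve.I, curve.sigma]),
        header=header, fmt="%.10g",
    )


# ---------------------------------------------------------------------------
# Diffusion decays
# ---------------------------------------------------------------------------

def read_decay(
    path: str | Path, Delta: float, delta: float,
    gamma: float | None = None, max_gradient: float | None = None,
) -> "DecayCurve":
    """Read a diffusion decay CSV (columns g, I).

    Gradient strengths given as fractions of the maximum (0-1) are
    converted to T/m via ``max_gradient``; absolute values pass through.
    """
    from .hydrodynamics import GAMMA_1H, DecayCurve

    df = pd.read_csv(path)
    if not {"g", "I"} <= set(df.columns):
        raise ValueError("decay table needs columns g, I")
    g = df["g"].to_numpy(dtype=float)
    if max_gradient is not None:
        g = g * max_gradient
    return DecayCurve(
        g=g, I=df["I"].to_numpy(dtype=float),
        Delta=Delta, delta=delta,
        gamma=GAMMA_1H if gamma is None else gamma,
    )


# ---------------------------------------------------------------------------
# Ensembles (multi-model PDB + bias trace)
# ---------------------------------------------------------------------------

def read_bias(path: str | Path) -> np.ndarray:
    """Read a per-frame bias trace CSV (single column ``bias_kJ_mol``)."""
    df = pd.read_csv(path)
    if "bias_kJ_mol" not in df.columns:
        raise ValueError("bias table needs a bias_kJ_mol column")
    v = df["bias_kJ_mol"].to_numpy(dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite bias values")
    return v


def write_bias(bias: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"bias_kJ_mol": np.asarray(bias, dtype=float)}).to_csv(path, index=False)


def read_ensemble(
    path: str | Path, bias_path: str | Path | None = None,
    temperature: float = 283.0,
) -> WeightedEnsemble:
    """Read a multi-model PDB into a :class:`WeightedEnsemble`.

    Every MODEL must share the same residue count and atom layout and
    carry the backbone atoms N, CA, C, O and H.  A missing bias file
    means zero bias, i.e. uniform frame weights.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure()  # AtomArrayStack, coords in Å
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    res_ids = np.unique(stack.res_id)
    n_res = res_ids.size
    coords = np.empty((stack.stack_depth(), n_res, len(BACKBONE_ATOMS), 3))
    res_names = []
    for ri, rid in enumerate(res_ids):
        res_mask = stack.res_id == rid
        res_names.append(str(stack.res_name[res_mask][0]))
        for ai, aname in enumerate(BACKBONE_ATOMS):
            mask = res_mask & (stack.atom_name == aname)
            idx = np.flatnonzero(mask)
            if idx.size != 1:
                raise ValueError(
                    f"residue {rid} must have exactly one {aname} atom "
                    f"(found {idx.size})"
                )
            coords[:, ri, ai, :] = stack.coord[:, idx[0], :]

    bias = None
    if bias_path is not None:
        bias = read_bias(bias_path)
        if bias.size != coords.shape[0]:
            raise ValueError(
                f"bias trace has {bias.size} entries for "
                f"{coords.shape[0]} frames"
            )
    return WeightedEnsemble(coords, res_names, bias=bias, temperature=temperature)


def write_ensemble(ensemble: WeightedEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB (MODEL/ENDMDL records)."""
    n_res = ensemble.n_residues
    n_atoms = n_res * len(BACKBONE_ATOMS)
    template = struc.AtomArray(n_atoms)
    k = 0
    for ri in range(n_res):
        for aname in BACKBONE_ATOMS:
            template.chain_id[k] = "A"
            template.res_id[k] = ri + 1
            template.res_name[k] = ensemble.res_names[ri]
            template.atom_name[k] = aname
            template.element[k] = aname[0]
            template.hetero[k] = False
            k += 1
    stack = struc.AtomArrayStack(ensemble.n_frames, n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = ensemble.coords.reshape(ensemble.n_frames, n_atoms, 3)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def sequence_to_res_names(sequence: str) -> list[str]:
    """One-letter sequence to three-letter residue names."""
    try:
        return [_ONE_TO_THREE[a] for a in sequence.upper()]
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None
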