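"""Amino-acid composition enrichment of a query set against a background.

The enrichment of amino acid *a* in the query (e.g. disordered) set
relative to the background (e.g. folded) set is the difference of pooled
residue frequencies normalized to the background frequency:

    enrichment(a) = (f_query(a) - f_background(a)) / f_background(a)

Confidence intervals come from a nonparametric bootstrap that resamples
whole sequences with replacement, independently in the two sets (residues
within a protein are not exchangeable, so the sequence is the resampling
unit).  An amino acid is flagged significant when its percentile interval
excludes zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CANONICAL_AA, SequenceRecord

logger = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_AA)}


def _count_matrix(records: list[SequenceRecord]) -> np.ndarray:
    """Per-sequence residue counts, shape (n_seqs, 20)."""
    counts = np.zeros((len(records), 20), dtype=np.int64)
    for i, rec in enumerate(records):
        seq = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        counts[i] = np.bincount(seq, minlength=128)[
            np.frombuffer(CANONICAL_AA.encode(), dtype=np.uint8)
        ]
    return counts


def residue_frequencies(records: list[SequenceRecord]) -> pd.Series:
    """Pooled residue frequencies over all sequences of a set."""
    if not records:
        raise ValueError("empty sequence set")
    counts = _count_matrix(records).sum(axis=0)
    return pd.Series(counts / counts.sum(), index=list(CANONICAL_AA), name="freq")


def stratify(records: list[SequenceRecord], tag: str) -> list[SequenceRecord]:
    """Subset of the records carrying the given taxonomy tag."""
    subset = [r for r in records if r.taxon_tag == tag]
    if not subset:
        raise ValueError(f"no sequences with taxon tag {tag!r}")
    return subset


def drop_exact_duplicates(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Optional exact-duplicate dropper (off by default in the profile)."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.sequence not in seen:
            seen.add(r.sequence)
            out.append(r)
    if len(out) < len(records):
        logger.info("dropped %d exact duplicate sequence(s)", len(records) - len(out))
    return out


def _bootstrap_enrichment(
    counts_q: np.ndarray,
    counts_b: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    batch: int = 2000,
) -> np.ndarray:
    """Bootstrap enrichment replicates, shape (n_boot, 20).

    Whole sequences are resampled with replacement, independently in the
    query and background sets; frequencies and enrichment are recomputed
    for every replicate.
    """
    nq, nb = counts_q.shape[0], counts_b.shape[0]
    out = np.empty((n_boot, 20))
    done = 0
    while done < n_boot:
        m = min(batch, n_boot - done)
        iq = rng.integers(0, nq, size=(m, nq))
        ib = rng.integers(0, nb, size=(m, nb))
        cq = counts_q[iq].sum(axis=1).astype(float)
        cb = counts_b[ib].sum(axis=1).astype(float)
        fq = cq / cq.sum(axis=1, keepdims=True)
        fb = cb / cb.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[done : done + m] = (fq - fb) / fb
        done += m
    return out


def enrichment_profile(
    query: list[SequenceRecord],
    background: list[SequenceRecord],
    n_boot: int = 50_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment profile with percentile bootstrap confidence intervals.

    Returns a DataFrame indexed by amino acid with columns
    ``freq_query, freq_background, enrichment, ci_low, ci_high,
    significant``.  Amino acids absent from the background have undefined
    enrichment and are reported as NaN with a warning.
    """
    if not query or not background:
        raise ValueError("query and background sets must be non-empty")
    counts_q = _count_matrix(query)
    counts_b = _count_matrix(background)
    fq = counts_q.sum(axis=0) / counts_q.sum()
    fb = counts_b.sum(axis=0) / counts_b.sum()

    missing = fb == 0
    if missing.any():
        logger.warning(
            "background frequency zero for %s; enrichment undefined there",
            [CANONICAL_AA[i] for i in np.flatnonzero(missing)],
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(missing, np.nan, (fq - fb) / fb)

    rng = np.random.default_rng(seed)
    reps = _bootstrap_enrichment(counts_q, counts_b, n_boot, rng)
    lo = np.full(20, np.nan)
    hi = np.full(20, np.nan)
    ok = ~missing
    lo[ok] = np.nanquantile(reps[:, ok], alpha / 2.0, axis=0)
    hi[ok] = np.nanquantile(reps[:, ok], 1.0 - alpha / 2.0, axis=0)
    significant = ~missing & ((lo > 0) | (hi < 0))

    return pd.DataFrame(
        {
            "freq_query": fq,
            "freq_background": fb,
            "enrichment": enrich,
            "ci_low": lo,
            "ci_high": hi,
            "significant": significant,
        },
        index=list(CANONICAL_AA),
    )
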