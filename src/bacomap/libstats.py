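"""BAC-library characterization statistics.

Fold coverage, locus-recovery probability (Clarke-Carbon complement),
observed screening depth, GC content, and a size-weighted chi-square
test of the chromosomal distribution of mapped clones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats as sps

__all__ = [
    "LibraryStats",
    "ChromDistTest",
    "fold_coverage",
    "prob_locus_recovered",
    "observed_depth",
    "gc_fraction",
    "chrom_uniformity_test",
]


@dataclass(frozen=True)
class LibraryStats:
    n_clones: int
    mean_insert: float
    genome_size: float

    def __post_init__(self):
        if self.n_clones < 0 or self.mean_insert <= 0 or self.genome_size <= 0:
            raise ValueError("inputs must be positive (clone count >= 0)")

    @property
    def fold_coverage(self) -> float:
        return fold_coverage(self.n_clones, self.mean_insert, self.genome_size)


@dataclass
class ChromDistTest:
    categories: Tuple[str, ...]
    observed: Tuple[float, ...]
    chrom_sizes: Tuple[float, ...]
    sex_mode: str
    expected: Tuple[float, ...]
    chi2: float
    df: int
    p_value: float


def fold_coverage(n_clones: int, mean_insert: float, genome_size: float) -> float:
    """Theoretical fold coverage n * L / G (unrounded)."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    return n_clones * mean_insert / genome_size


def prob_locus_recovered(coverage: float) -> float:
    """Probability a random locus is represented: 1 - exp(-coverage)."""
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    return -np.expm1(-coverage)


def observed_depth(screening: pd.DataFrame,
                   excluded_clone_ids: Optional[Iterable[str]] = None) -> float:
    """Mean clones-per-probe from a long (probe_id, clone_id) table.

    Rows with an empty clone_id mark probes with zero hits; clones in
    ``excluded_clone_ids`` are removed before averaging (e.g. clones
    falling in non-anchored contigs).
    """
    if screening.empty:
        raise ValueError("screening table is empty")
    for col in ("probe_id", "clone_id"):
        if col not in screening.columns:
            raise ValueError(f"screening table lacks column {col!r}")
    excl: Set[str] = set(excluded_clone_ids or ())
    df = screening.fillna({"clone_id": ""})
    hit = df[(df["clone_id"] != "") & ~df["clone_id"].isin(excl)]
    counts = hit.groupby("probe_id").size()
    counts = counts.reindex(df["probe_id"].unique(), fill_value=0)
    return float(counts.mean())


def gc_fraction(fasta: Union[str, "os.PathLike", Iterable[str]]) -> float:
    """Pooled (G+C)/(A+C+G+T) over all records; N is excluded from the
    denominator.  Accepts a FASTA path or an iterable of sequences."""
    if isinstance(fasta, (str, bytes)) or hasattr(fasta, "__fspath__"):
        seqs = (str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta"))
    else:
        seqs = (str(s) for s in fasta)
    gc = total = 0
    for s in seqs:
        u = s.upper()
        gc += u.count("G") + u.count("C")
        total += u.count("A") + u.count("T") + u.count("G") + u.count("C")
    if total == 0:
        raise ValueError("no countable A/C/G/T bases")
    return gc / total


def chrom_uniformity_test(
    observed: Dict[str, float],
    chrom_sizes: Dict[str, float],
    sex_mode: str = "none",
) -> ChromDistTest:
    """Pearson chi-square of observed clone counts against expectations
    proportional to chromosome size.

    With ``sex_mode='male'`` the X and Y weights are halved (one copy
    each in the source animal) before normalizing the expectations to
    the observed total.  df = k - 1.
    """
    if sex_mode not in ("male", "female", "none"):
        raise ValueError("sex_mode must be male, female or none")
    cats = tuple(observed)
    if set(cats) != set(chrom_sizes):
        raise ValueError("observed and chrom_sizes categories differ")
    obs = np.array([observed[c] for c in cats], float)
    weights = np.array([chrom_sizes[c] for c in cats], float)
    if sex_mode == "male":
        for i, c in enumerate(cats):
            if c.upper().lstrip("CHR") in ("X", "Y"):
                weights[i] *= 0.5
    elif sex_mode == "female":
        for i, c in enumerate(cats):
            if c.upper().lstrip("CHR") == "Y":
                weights[i] = 0.0
    total = obs.sum()
    if weights.sum() <= 0:
        raise ValueError("chromosome weights sum to zero")
    exp = weights / weights.sum() * total
    if np.any(exp <= 0):
        bad = [c for c, e in zip(cats, exp) if e <= 0]
        raise ValueError(
            f"expected count is zero for {bad}; merge these categories"
        )
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(cats) - 1
    p = float(sps.chi2.sf(chi2, df))
    return ChromDistTest(
        categories=cats, observed=tuple(obs), chrom_sizes=tuple(
            chrom_sizes[c] for c in cats),
        sex_mode=sex_mode, expected=tuple(exp), chi2=chi2, df=df, p_value=p,
    )
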