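"""Pairwise IBD-ROH sharing.

For each pair of individuals we locate genomic regions where their ROH
overlap and report the fraction of the analysis universe covered by the
overlap — the proportion of the genome in ROH that is shared IBD between
the pair.  Overlap alone can pair two distinct homozygous haplotypes, so
when consensus genomes are available each overlap is additionally
required to agree at homozygous calls (identity check, default on).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roh_hmm import RohCallSet
from .seqio import BASES, DiploidGenome, Interval

#: Overlaps shorter than this are discarded: tract ends carry sub-window
#: jitter, and fragments below 1 Mb mostly reflect that jitter.
DEFAULT_MIN_OVERLAP = 1_000_000
DEFAULT_IDENTITY_THRESHOLD = 0.95

_HOM_BYTES = np.frombuffer(BASES.encode(), dtype=np.uint8)


def _scaffold_universe(callset: RohCallSet) -> set[str]:
    return {iv.scaffold for iv in callset.tracts}


def intersect_roh(a: RohCallSet, b: RohCallSet) -> list[Interval]:
    """Intersection of two ROH interval sets, merged and sorted.

    The two call sets must come from the same scaffold universe; a tract
    on a scaffold the other individual's genome does not even contain
    indicates mismatched inputs and raises.
    """
    scaffolds = sorted(_scaffold_universe(a) | _scaffold_universe(b))
    out: list[Interval] = []
    for scaffold in scaffolds:
        ivs_a = sorted(
            (iv for iv in a.tracts if iv.scaffold == scaffold), key=lambda iv: iv.start
        )
        ivs_b = sorted(
            (iv for iv in b.tracts if iv.scaffold == scaffold), key=lambda iv: iv.start
        )
        i = j = 0
        while i < len(ivs_a) and j < len(ivs_b):
            s = max(ivs_a[i].start, ivs_b[j].start)
            e = min(ivs_a[i].end, ivs_b[j].end)
            if e > s:
                if out and out[-1].scaffold == scaffold and out[-1].end >= s:
                    out[-1] = Interval(scaffold, out[-1].start, max(out[-1].end, e))
                else:
                    out.append(Interval(scaffold, s, e))
            if ivs_a[i].end <= ivs_b[j].end:
                i += 1
            else:
                j += 1
    return out


def _homozygote_identity(
    genome_a: DiploidGenome, genome_b: DiploidGenome, iv: Interval
) -> float:
    """Fraction of jointly callable homozygous sites in ``iv`` where the
    two consensus genomes carry the same base.  NaN if none."""
    a = genome_a.as_bytes(iv.scaffold)[iv.start : iv.end]
    b = genome_b.as_bytes(iv.scaffold)[iv.start : iv.end]
    hom = np.isin(a, _HOM_BYTES) & np.isin(b, _HOM_BYTES)
    n = int(hom.sum())
    if n == 0:
        return float("nan")
    return float((a[hom] == b[hom]).sum() / n)


def ibd_fraction(
    a: RohCallSet,
    b: RohCallSet,
    genome_length: int,
    genomes: tuple[DiploidGenome, DiploidGenome] | None = None,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float:
    """Fraction of the genome in ROH shared IBD between two individuals.

    Overlaps shorter than ``min_overlap`` are dropped.  When ``genomes``
    are supplied, an overlap is kept only if the two individuals'
    homozygous calls agree at >= ``identity_threshold`` of jointly
    callable sites within it.
    """
    if genome_length <= 0:
        raise ValueError(f"genome_length must be > 0, got {genome_length}")
    shared = 0
    for iv in intersect_roh(a, b):
        if iv.length < min_overlap:
            continue
        if genomes is not None:
            ident = _homozygote_identity(genomes[0], genomes[1], iv)
            if np.isnan(ident) or ident < identity_threshold:
                continue
        shared += iv.length
    return shared / genome_length


@dataclass
class IbdMatrix:
    """Symmetric matrix of pairwise IBD-ROH genome fractions; the
    diagonal is each individual's F_ROH."""

    individuals: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match individual count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("IBD matrix must be symmetric")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("IBD fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individuals, columns=self.individuals)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.individuals):
            for j, b in enumerate(self.individuals):
                if j > i:
                    rows.append({"id_a": a, "id_b": b, "fraction": self.values[i, j]})
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("# pairwise fraction of genome in IBD-shared ROH\n")
            self.to_frame().to_csv(fh, sep="\t", float_format="%.6g")


def ibd_matrix(
    callsets: list[RohCallSet],
    genome_length: int,
    genomes: list[DiploidGenome] | None = None,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> IbdMatrix:
    """All pairwise IBD-ROH fractions, symmetric by construction.

    Diagonal entries use the individual's own tracts with no overlap or
    identity filtering, i.e. F_ROH over the same denominator.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two individuals")
    n = len(callsets)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = callsets[i].total_length / genome_length
        for j in range(i + 1, n):
            pair_genomes = (genomes[i], genomes[j]) if genomes is not None else None
            values[i, j] = values[j, i] = ibd_fraction(
                callsets[i],
                callsets[j],
                genome_length,
                genomes=pair_genomes,
                identity_threshold=identity_threshold,
                min_overlap=min_overlap,
            )
    return IbdMatrix(
        individuals=[c.individual_id for c in callsets],
        values=values,
    )
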