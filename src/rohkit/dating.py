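"""Dating ROH tracts in generations and summarizing per-individual inbreeding.

An autozygous tract of length L Mb reflects a haplotype that survived
2g meioses (g up each parental lineage to the common ancestor) without
recombining, so its expected length ties tract size to coalescence time:

    g = 100 / (2 r L)

with r the recombination rate in cM/Mb and g the number of generations
back to the shared ancestor.  At the felid rate r = 1.1 cM/Mb this puts
the classic length classes at >15.2 Mb (ancestor <3 generations back,
close inbreeding), 9.1 Mb (5 generations) and <5.7 Mb (>8 generations,
historically small populations).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roh_hmm import RohCallSet

DEFAULT_RATE_CM_PER_MB = 1.1
#: Histogram bin edges in Mb: the 2 Mb call floor plus the lengths implied
#: by common ancestors 8, 5 and 3 generations back at r = 1.1 cM/Mb.
DEFAULT_BIN_EDGES_MB = (2.0, 5.7, 9.1, 15.2, float("inf"))


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


def tract_generations(length_mb, r: float = DEFAULT_RATE_CM_PER_MB):
    """Generations since the parental common ancestor implied by a tract
    of ``length_mb`` Mb: g = 100 / (2 r L).  Accepts scalars or arrays."""
    arr = np.asarray(length_mb, dtype=float)
    if (arr <= 0).any():
        raise ValueError(f"tract length must be > 0 Mb, got {length_mb}")
    _check_positive(r=r)
    out = 100.0 / (2.0 * r * arr)
    return float(out) if np.isscalar(length_mb) else out


def generations_to_length(g, r: float = DEFAULT_RATE_CM_PER_MB):
    """Expected tract length in Mb for a common ancestor ``g``
    generations back: L = 100 / (2 r g).  Exact inverse of
    :func:`tract_generations`."""
    arr = np.asarray(g, dtype=float)
    if (arr <= 0).any():
        raise ValueError(f"generations must be > 0, got {g}")
    _check_positive(r=r)
    out = 100.0 / (2.0 * r * arr)
    return float(out) if np.isscalar(g) else out


@dataclass
class RohSummary:
    """Per-individual ROH summary: F_ROH, tract count and a length
    histogram over generation-derived bins."""

    individual_id: str
    f_roh: float
    bin_edges_mb: tuple[float, ...]
    histogram: np.ndarray
    n_tracts: int
    total_roh_bp: int
    genome_length: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, count in enumerate(self.histogram):
            lo = self.bin_edges_mb[i]
            hi = self.bin_edges_mb[i + 1]
            rows.append(
                {
                    "individual": self.individual_id,
                    "bin_lo_mb": lo,
                    "bin_hi_mb": hi,
                    "count": int(count),
                }
            )
        return pd.DataFrame(rows)

    def modal_bin(self) -> tuple[float, float]:
        """(lo, hi) Mb edges of the most populated length bin."""
        i = int(np.argmax(self.histogram))
        return (self.bin_edges_mb[i], self.bin_edges_mb[i + 1])


def summarize(
    callset: RohCallSet,
    genome_length: int,
    bin_edges_mb: tuple[float, ...] = DEFAULT_BIN_EDGES_MB,
) -> RohSummary:
    """Summarize a call set: F_ROH (fraction of the analysis universe in
    ROH) and the tract-length histogram.

    ``genome_length`` is the total length of the scaffolds included in
    the analysis (the denominator of F_ROH), not the full assembly.
    """
    total = callset.total_length
    if genome_length < total:
        raise ValueError(
            f"genome_length {genome_length} smaller than total ROH length {total}"
        )
    edges = np.asarray(bin_edges_mb, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    lengths = callset.lengths_mb()
    hist, _ = np.histogram(lengths, bins=edges)
    return RohSummary(
        individual_id=callset.individual_id,
        f_roh=total / genome_length,
        bin_edges_mb=tuple(edges),
        histogram=hist,
        n_tracts=len(callset.tracts),
        total_roh_bp=total,
        genome_length=genome_length,
    )


def summary_table(summaries: list[RohSummary]) -> pd.DataFrame:
    """Long-format summary TSV content across individuals."""
    return pd.DataFrame(
        {
            "individual": [s.individual_id for s in summaries],
            "f_roh": [s.f_roh for s in summaries],
            "n_tracts": [s.n_tracts for s in summaries],
            "total_roh_bp": [s.total_roh_bp for s in summaries],
            "genome_length": [s.genome_length for s in summaries],
        }
    )


def write_summary(summaries: list[RohSummary], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# per-individual ROH summary\n")
        summary_table(summaries).to_csv(fh, sep="\t", index=False, float_format="%.6g")
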