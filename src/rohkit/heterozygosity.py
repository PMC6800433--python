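"""Windowed and genome-wide heterozygosity from IUPAC consensus genomes.

Heterozygosity is the density of IUPAC ambiguity codes per callable
(non-N) site.  Scaffolds are tiled with fixed, non-overlapping windows;
the resulting per-window heterozygote counts with callable-site
exposures are the observation sequence for the ROH HMM.  Non-overlapping
windows keep those observations conditionally independent given the
hidden state, which the HMM assumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import DiploidGenome, _HET_BYTES, _N_BYTE

DEFAULT_WINDOW = 100_000
#: Windows with callable fraction below this are flagged missing: masked
#: deserts would otherwise mimic homozygosity.
MIN_CALLABLE_FRAC = 0.2


@dataclass
class HetWindowTrack:
    """Per-window heterozygote counts with callable-site exposures.

    ``windows`` has columns ``scaffold, start, end, het_count, callable``
    and tiles each scaffold in order without overlap (the last window of
    a scaffold may be short).  ``missing`` marks windows whose callable
    fraction falls below ``min_callable_frac``; the HMM treats their
    emissions as missing data.
    """

    window_size: int
    windows: pd.DataFrame
    min_callable_frac: float = MIN_CALLABLE_FRAC
    individual_id: str = ""

    def __post_init__(self) -> None:
        k = self.windows["het_count"].to_numpy()
        n = self.windows["callable"].to_numpy()
        w = (self.windows["end"] - self.windows["start"]).to_numpy()
        if ((k < 0) | (k > n) | (n > w)).any():
            raise ValueError("window counts violate 0 <= het_count <= callable <= width")

    @property
    def missing(self) -> np.ndarray:
        width = (self.windows["end"] - self.windows["start"]).to_numpy()
        return self.windows["callable"].to_numpy() < self.min_callable_frac * width

    def rates(self) -> np.ndarray:
        """Per-window het rate k/n; NaN where no callable sites."""
        k = self.windows["het_count"].to_numpy(dtype=float)
        n = self.windows["callable"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, k / n, np.nan)

    def per_scaffold(self):
        """Yield (scaffold, k, n, missing) arrays in file order."""
        miss = self.missing
        for name, grp in self.windows.groupby("scaffold", sort=False):
            idx = grp.index.to_numpy()
            yield (
                name,
                grp["het_count"].to_numpy(),
                grp["callable"].to_numpy(),
                miss[idx],
            )

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = self.windows.copy()
        df["rate"] = self.rates()
        with open(path, "w") as fh:
            fh.write(f"# window_size={self.window_size}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, individual_id: str = "") -> "HetWindowTrack":
        window_size = DEFAULT_WINDOW
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#") and "window_size=" in first:
                window_size = int(first.split("window_size=")[1].strip())
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", comment="#")
        df = df[["scaffold", "start", "end", "het_count", "callable"]]
        return cls(window_size=window_size, windows=df, individual_id=individual_id)


def _scaffold_counts(seq_bytes: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    L = len(seq_bytes)
    edges = np.arange(0, L, w)
    is_het = np.isin(seq_bytes, _HET_BYTES)
    callable_ = seq_bytes != _N_BYTE
    k = np.add.reduceat(is_het.astype(np.int64), edges)
    n = np.add.reduceat(callable_.astype(np.int64), edges)
    return k, n


def window_het(genome: DiploidGenome, w: int = DEFAULT_WINDOW) -> HetWindowTrack:
    """Count heterozygous and callable sites in non-overlapping windows."""
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    frames = []
    for name in genome.scaffold_names:
        arr = genome.as_bytes(name)
        k, n = _scaffold_counts(arr, w)
        starts = np.arange(0, len(arr), w)
        ends = np.minimum(starts + w, len(arr))
        frames.append(
            pd.DataFrame(
                {"scaffold": name, "start": starts, "end": ends, "het_count": k, "callable": n}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return HetWindowTrack(window_size=w, windows=df, individual_id=genome.individual_id)


def genome_het(genome: DiploidGenome) -> float:
    """Genome-wide heterozygosity: total het codes / total non-N sites."""
    total_k = 0
    total_n = 0
    for name in genome.scaffold_names:
        arr = genome.as_bytes(name)
        total_k += int(np.isin(arr, _HET_BYTES).sum())
        total_n += int((arr != _N_BYTE).sum())
    if total_n == 0:
        raise ValueError("no callable sites: cannot compute heterozygosity")
    return total_k / total_n
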