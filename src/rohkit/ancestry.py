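"""Three-state local-ancestry HMM over ancestry-diagnostic sites.

Given two source-population panels, a *diagnostic site* is a position at
which every panel-A genome is homozygous for one base and every panel-B
genome homozygous for a different base.  A diploid query genome is then
segmented into pure-A, pure-B and MIXED (one haplotype from each source)
ancestry along each scaffold: state A expects the homozygous A allele at
a diagnostic site, state B the homozygous B allele, and MIXED the
heterozygous IUPAC code, each with a per-site error probability eps
spread over the other outcomes.  Transition probabilities decay with
inter-site physical distance d as exp(-tau * d), tau being on the order
of (generations since admixture) x (recombination rate per bp).

ROH are labelled by the ancestry state covering the majority of their
length.  Because autozygosity requires the maternal and paternal
lineages to coalesce *after* any admixture event, genuine ROH can only
be pure-A or pure-B; a MIXED-majority ROH indicates a calling artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roh_hmm import RohCallSet
from .seqio import BASES, DiploidGenome, IUPAC_HET, Interval

STATES = ("A", "B", "MIXED")
_HOM_SET = set(BASES)

# Observation codes at a diagnostic site
_OBS_HOM_A, _OBS_HOM_B, _OBS_HET, _OBS_OTHER = 0, 1, 2, 3


@dataclass(frozen=True)
class AncestryParams:
    """eps: per-site genotyping/assignment error; tau: per-bp ancestry
    switch rate.  The default tau corresponds to an admixture event
    roughly 8 generations back at 1.1 cM/Mb (~2 expected switch
    opportunities per 10 Mb for the diploid state)."""

    eps: float = 0.01
    tau: float = 2e-7

    def __post_init__(self) -> None:
        if not 0 < self.eps < 0.5:
            raise ValueError(f"eps must be in (0, 0.5), got {self.eps}")
        if not 0 < self.tau < 1:
            raise ValueError(f"tau must be in (0, 1), got {self.tau}")


@dataclass
class DiagnosticSiteSet:
    """Ancestry-diagnostic sites: per site the scaffold, 0-based
    position, and the bases fixed in panels A and B."""

    sites: pd.DataFrame  # columns: scaffold, pos, allele_A, allele_B

    def __post_init__(self) -> None:
        if len(self.sites) and (self.sites["allele_A"] == self.sites["allele_B"]).any():
            raise ValueError("diagnostic alleles must differ between populations")
        if self.sites.duplicated(subset=["scaffold", "pos"]).any():
            raise ValueError("duplicate diagnostic site positions")

    def __len__(self) -> int:
        return len(self.sites)

    def for_scaffold(self, scaffold: str) -> pd.DataFrame:
        df = self.sites[self.sites["scaffold"] == scaffold]
        return df.sort_values("pos").reset_index(drop=True)


def select_diagnostic_sites(
    panel_a: list[DiploidGenome], panel_b: list[DiploidGenome]
) -> DiagnosticSiteSet:
    """Find sites fixed for different alleles between two panels.

    A site qualifies when every panel-A genome is homozygous for one
    base, every panel-B genome is homozygous for a different base, and
    no genome carries N (or a het code) there.
    """
    if not panel_a or not panel_b:
        raise ValueError("both panels must contain at least one genome")
    scaffolds = panel_a[0].scaffold_names
    hom_bytes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    frames = []
    for scaffold in scaffolds:
        arrs_a = [g.as_bytes(scaffold) for g in panel_a]
        arrs_b = [g.as_bytes(scaffold) for g in panel_b]
        base_a = arrs_a[0]
        fixed_a = np.isin(base_a, hom_bytes)
        for arr in arrs_a[1:]:
            fixed_a &= arr == base_a
        base_b = arrs_b[0]
        fixed_b = np.isin(base_b, hom_bytes)
        for arr in arrs_b[1:]:
            fixed_b &= arr == base_b
        diag = fixed_a & fixed_b & (base_a != base_b)
        pos = np.nonzero(diag)[0]
        if len(pos):
            frames.append(
                pd.DataFrame(
                    {
                        "scaffold": scaffold,
                        "pos": pos,
                        "allele_A": [chr(c) for c in base_a[pos]],
                        "allele_B": [chr(c) for c in base_b[pos]],
                    }
                )
            )
    sites = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["scaffold", "pos", "allele_A", "allele_B"])
    )
    return DiagnosticSiteSet(sites=sites)


@dataclass
class AncestrySegmentation:
    """Genome partition into labelled ancestry tracts.

    ``segments`` tile every analyzed scaffold; ``fractions`` give the
    genome proportion per label and sum to one.
    """

    segments: list[tuple[Interval, str]]
    fractions: dict[str, float]

    def label_at(self, scaffold: str, pos: int) -> str | None:
        for iv, lab in self.segments:
            if iv.scaffold == scaffold and iv.start <= pos < iv.end:
                return lab
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": [iv.scaffold for iv, _ in self.segments],
                "start": [iv.start for iv, _ in self.segments],
                "end": [iv.end for iv, _ in self.segments],
                "label": [lab for _, lab in self.segments],
            }
        )


def _observations(genome: DiploidGenome, sites: pd.DataFrame) -> np.ndarray:
    obs = np.full(len(sites), _OBS_OTHER, dtype=np.int8)
    seq = genome.scaffolds[sites["scaffold"].iloc[0]] if len(sites) else ""
    for i, row in enumerate(sites.itertuples(index=False)):
        ch = seq[row.pos]
        if ch == row.allele_A:
            obs[i] = _OBS_HOM_A
        elif ch == row.allele_B:
            obs[i] = _OBS_HOM_B
        elif ch in IUPAC_HET and IUPAC_HET[ch] == frozenset((row.allele_A, row.allele_B)):
            obs[i] = _OBS_HET
        # anything else (N, third allele, other het) stays OTHER/missing
    return obs


def _log_emissions(obs: np.ndarray, eps: float) -> np.ndarray:
    """(n_sites, 3) log emission matrix; OTHER observations are treated
    as missing (log-likelihood 0 in every state)."""
    e = np.empty((4, 3))
    for s, expected in enumerate((_OBS_HOM_A, _OBS_HOM_B, _OBS_HET)):
        probs = np.full(3, eps / 2.0)
        probs[expected] = 1.0 - eps
        e[:3, s] = np.log(probs)
    e[_OBS_OTHER, :] = 0.0
    return e[obs]


def decode_ancestry(
    genome: DiploidGenome,
    sites: DiagnosticSiteSet,
    params: AncestryParams | None = None,
    min_sites: int = 10,
) -> AncestrySegmentation:
    """Viterbi ancestry segmentation of a diploid genome.

    Scaffolds with at least one diagnostic site are analyzed; segment
    boundaries fall at the midpoint between adjacent sites assigned
    different states, and the first/last segments extend to the scaffold
    ends.  Requires ``min_sites`` diagnostic sites overall.
    """
    params = params or AncestryParams()
    usable = sites.sites[sites.sites["scaffold"].isin(genome.scaffold_names)]
    if len(usable) < min_sites:
        raise ValueError(
            f"need >= {min_sites} diagnostic sites on analyzed scaffolds, got {len(usable)}"
        )
    segments: list[tuple[Interval, str]] = []
    totals: dict[str, int] = {s: 0 for s in STATES}
    for scaffold in genome.scaffold_names:
        df = sites.for_scaffold(scaffold)
        if df.empty:
            continue
        L = genome.length(scaffold)
        obs = _observations(genome, df)
        logB = _log_emissions(obs, params.eps)
        pos = df["pos"].to_numpy()
        path = _viterbi_distance(logB, pos, params.tau)
        # states -> segments with midpoint boundaries
        bounds = [0]
        labels = [STATES[path[0]]]
        for i in range(1, len(path)):
            if path[i] != path[i - 1]:
                bounds.append(int((pos[i - 1] + pos[i]) // 2) + 1)
                labels.append(STATES[path[i]])
        bounds.append(L)
        for s, e, lab in zip(bounds[:-1], bounds[1:], labels):
            segments.append((Interval(scaffold, s, e), lab))
            totals[lab] += e - s
    grand = sum(totals.values())
    fractions = {lab: totals[lab] / grand for lab in STATES}
    return AncestrySegmentation(segments=segments, fractions=fractions)


def _viterbi_distance(logB: np.ndarray, pos: np.ndarray, tau: float) -> np.ndarray:
    """Viterbi over 3 states with distance-dependent transitions:
    P(stay over gap d) = exp(-tau d), the remainder split evenly."""
    n = len(logB)
    score = logB[0] + np.log(1.0 / 3.0)
    back = np.zeros((n, 3), dtype=np.int8)
    for t in range(1, n):
        d = float(pos[t] - pos[t - 1])
        stay = np.exp(-tau * d)
        switch = (1.0 - stay) / 2.0
        lt = np.log(
            np.maximum(
                np.where(np.eye(3, dtype=bool), stay, switch), 1e-300
            )
        )
        cand = score[:, None] + lt
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(3)] + logB[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def classify_roh_ancestry(
    callset: RohCallSet, segmentation: AncestrySegmentation
) -> pd.DataFrame:
    """Label each ROH by the ancestry state covering the majority of its
    length (ties -> MIXED).  Returns a frame with one row per tract."""
    rows = []
    for iv in callset.tracts:
        cover = {s: 0 for s in STATES}
        for seg, lab in segmentation.segments:
            if seg.scaffold != iv.scaffold:
                continue
            ov = min(seg.end, iv.end) - max(seg.start, iv.start)
            if ov > 0:
                cover[lab] += ov
        best = max(cover.values())
        winners = [lab for lab, v in cover.items() if v == best]
        label = winners[0] if len(winners) == 1 else "MIXED"
        rows.append(
            {
                "scaffold": iv.scaffold,
                "start": iv.start,
                "end": iv.end,
                "length_mb": iv.length / 1e6,
                "ancestry": label,
            }
        )
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "length_mb", "ancestry"])
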