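"""Pedigree simulator with ground-truth autozygosity and ancestry tracts.

The generator emulates the ingredients of an inbreeding/admixture study:

* two diverged source populations (A and B) sharing a reference sequence,
  with standing variation at a configurable per-bp heterozygosity and
  fixed differences between the populations at a configurable density;
* explicit pedigrees containing inbreeding loops whose common ancestor
  sits a chosen number of generations back;
* meiosis with crossovers as a Poisson process at a stated cM/Mb rate
  (no interference, no de-novo mutation).

Haplotypes are propagated as *mosaics* — lists of ``(start, end, label)``
segments whose label identifies the founder haplotype copy they descend
from — so ground truth is exact: the focal individual is autozygous
wherever its two mosaics carry the same label, and each segment's
ancestry is the population of its founder.  Sequences are only rendered
(reference + variants + IUPAC coding) when requested, which keeps
truth-only replicates cheap.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import yaml

from .seqio import DiploidGenome, Interval, make_pseudodiploid, write_bed, write_iupac_fasta

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

# RNG stream tags (mixed into SeedSequence entropy so that every
# consumer of randomness has its own reproducible sub-stream).
_STREAM_REF = 0
_STREAM_POLY = 1
_STREAM_DIAG = 2
_STREAM_FOUNDER = 3
_STREAM_MEIOSIS = 4
_STREAM_PEDIGREE = 5


def _name_hash(name: str) -> int:
    return zlib.crc32(name.encode()) & 0xFFFFFFFF


class HapLabel(NamedTuple):
    """Identity of a founder haplotype copy (the unit of IBD)."""

    founder: str
    copy: int
    population: str


#: A haplotype mosaic over one scaffold: sorted, abutting segments
#: ``(start, end, HapLabel)`` tiling ``[0, L)``.
Mosaic = list[tuple[int, int, HapLabel]]


@dataclass(frozen=True)
class RecombinationModel:
    """Crossover model: a Poisson process at ``rate`` cM/Mb (default 1.1,
    the domestic-cat genome average used for felid ROH dating)."""

    rate: float = 1.1

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"recombination rate must be > 0, got {self.rate}")

    @property
    def per_bp(self) -> float:
        """Expected crossovers per bp per meiosis (1 cM = 0.01 crossovers)."""
        return self.rate * 1e-8


@dataclass(frozen=True)
class PopulationPanelSpec:
    """Founder-population model.

    ``het_rate`` is the expected per-bp heterozygosity of a non-inbred
    individual; standing polymorphic sites are therefore placed at rate
    ``2 * het_rate`` with allele frequency 0.5 in both populations (two
    independent haplotypes are heterozygous at half of those sites).
    ``fixed_diff_rate`` is the per-bp density of sites fixed for
    different alleles between populations A and B (ancestry-diagnostic
    sites).
    """

    scaffold_lengths: dict[str, int]
    het_rate: float = 1e-3
    fixed_diff_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.het_rate < 1:
            raise ValueError(f"het_rate must be in [0, 1), got {self.het_rate}")
        if not 0 <= self.fixed_diff_rate < 1:
            raise ValueError(f"fixed_diff_rate must be in [0, 1), got {self.fixed_diff_rate}")
        for name, L in self.scaffold_lengths.items():
            if L < 1:
                raise ValueError(f"scaffold {name!r} length must be >= 1, got {L}")


class FounderPool:
    """Lazy founder-haplotype pool over a shared reference.

    Variant positions and the reference itself are generated on first
    access per scaffold; founder allele draws are cached per haplotype
    copy.  Everything is a pure function of ``spec.seed``, the scaffold
    index and the founder name, so identical specs reproduce identical
    sequences regardless of evaluation order.
    """

    def __init__(self, spec: PopulationPanelSpec):
        self.spec = spec
        self._scaffold_index = {name: i for i, name in enumerate(spec.scaffold_lengths)}
        self._ref: dict[str, np.ndarray] = {}
        self._poly: dict[str, tuple[np.ndarray, np.ndarray]] = {}  # positions, alt codes
        self._diag: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._alleles: dict[tuple[str, int, str], np.ndarray] = {}

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return self.spec.scaffold_lengths

    def _rng(self, scaffold: str, stream: int, *extra: int) -> np.random.Generator:
        sidx = self._scaffold_index[scaffold]
        return np.random.default_rng(
            np.random.SeedSequence([self.spec.seed, sidx, stream, *extra])
        )

    def ref_codes(self, scaffold: str) -> np.ndarray:
        """Reference sequence as base codes 0..3 (A, C, G, T)."""
        if scaffold not in self._ref:
            L = self.spec.scaffold_lengths[scaffold]
            rng = self._rng(scaffold, _STREAM_REF)
            self._ref[scaffold] = rng.integers(0, 4, size=L, dtype=np.uint8)
        return self._ref[scaffold]

    @staticmethod
    def _poisson_positions(rng: np.random.Generator, rate: float, L: int) -> np.ndarray:
        n = rng.poisson(rate * L)
        if n == 0:
            return np.empty(0, dtype=np.int64)
        return np.unique(rng.integers(0, L, size=n))

    def polymorphic_sites(self, scaffold: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, alt base codes) of shared standing variation."""
        if scaffold not in self._poly:
            L = self.spec.scaffold_lengths[scaffold]
            rng = self._rng(scaffold, _STREAM_POLY)
            pos = self._poisson_positions(rng, 2.0 * self.spec.het_rate, L)
            shift = rng.integers(1, 4, size=pos.size, dtype=np.uint8)
            alt = (self.ref_codes(scaffold)[pos] + shift) % 4
            self._poly[scaffold] = (pos, alt.astype(np.uint8))
        return self._poly[scaffold]

    def diagnostic_sites(self, scaffold: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(positions, allele_A codes, allele_B codes) of fixed differences."""
        if scaffold not in self._diag:
            L = self.spec.scaffold_lengths[scaffold]
            rng = self._rng(scaffold, _STREAM_DIAG)
            pos = self._poisson_positions(rng, self.spec.fixed_diff_rate, L)
            poly_pos, _ = self.polymorphic_sites(scaffold)
            pos = pos[~np.isin(pos, poly_pos)]
            ref = self.ref_codes(scaffold)[pos]
            shift = rng.integers(1, 4, size=pos.size, dtype=np.uint8)
            alt = (ref + shift) % 4
            # population A carries the reference base, B the alternate
            self._diag[scaffold] = (pos, ref.astype(np.uint8), alt.astype(np.uint8))
        return self._diag[scaffold]

    def founder_alleles(self, label: HapLabel, scaffold: str) -> np.ndarray:
        """0/1 allele per polymorphic site for one founder haplotype copy."""
        key = (label.founder, label.copy, scaffold)
        if key not in self._alleles:
            pos, _ = self.polymorphic_sites(scaffold)
            rng = self._rng(
                scaffold, _STREAM_FOUNDER, _name_hash(label.founder), label.copy
            )
            self._alleles[key] = rng.integers(0, 2, size=pos.size, dtype=np.uint8)
        return self._alleles[key]

    def founder_mosaics(self, founder: str, population: str) -> tuple[dict, dict]:
        """Two whole-genome mosaics (one per haplotype copy) for a founder."""
        out = []
        for copy in (0, 1):
            label = HapLabel(founder, copy, population)
            out.append(
                {name: [(0, L, label)] for name, L in self.spec.scaffold_lengths.items()}
            )
        return out[0], out[1]

    def render_haplotype(self, scaffold: str, mosaic: Mosaic) -> np.ndarray:
        """Render a mosaic to an ASCII uint8 sequence array."""
        seq = _BASE_BYTES[self.ref_codes(scaffold)].copy()
        poly_pos, poly_alt = self.polymorphic_sites(scaffold)
        diag_pos, diag_a, diag_b = self.diagnostic_sites(scaffold)
        for start, end, label in mosaic:
            i0, i1 = np.searchsorted(poly_pos, (start, end))
            alleles = self.founder_alleles(label, scaffold)[i0:i1]
            carriers = poly_pos[i0:i1][alleles == 1]
            seq[carriers] = _BASE_BYTES[poly_alt[i0:i1][alleles == 1]]
            j0, j1 = np.searchsorted(diag_pos, (start, end))
            if label.population == "B":
                seq[diag_pos[j0:j1]] = _BASE_BYTES[diag_b[j0:j1]]
            # population A carries the reference base: nothing to apply
        return seq

    def render_diploid(
        self, individual_id: str, haplotypes: tuple[dict, dict]
    ) -> DiploidGenome:
        """Render a haplotype pair as an IUPAC-coded consensus genome."""
        scaffolds: dict[str, str] = {}
        for name in self.spec.scaffold_lengths:
            a = self.render_haplotype(name, haplotypes[0][name]).tobytes().decode()
            b = self.render_haplotype(name, haplotypes[1][name]).tobytes().decode()
            scaffolds[name] = make_pseudodiploid(a, b)
        return DiploidGenome(individual_id=individual_id, scaffolds=scaffolds)


def simulate_panels(spec: PopulationPanelSpec) -> FounderPool:
    """Create the founder haplotype pool for a panel specification."""
    return FounderPool(spec)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def meiosis(
    hap_pair: tuple[Mosaic, Mosaic],
    length: int,
    model: RecombinationModel,
    rng: np.random.Generator,
) -> tuple[Mosaic, np.ndarray]:
    """Form a gamete from a parent's haplotype pair on one scaffold.

    Crossover breakpoints are a Poisson process at ``model.per_bp`` per
    bp; the gamete alternates between the parental haplotypes at each
    breakpoint, starting from a uniformly chosen haplotype.  Returns the
    gamete mosaic and the breakpoint positions.
    """
    n = rng.poisson(model.per_bp * length)
    if n > 0:
        bps = np.unique(rng.integers(1, length, size=n))
    else:
        bps = np.empty(0, dtype=np.int64)
    which = int(rng.integers(2))
    edges = np.concatenate(([0], bps, [length]))
    gamete: Mosaic = []
    for i in range(len(edges) - 1):
        s, e = int(edges[i]), int(edges[i + 1])
        if e <= s:
            continue
        src = hap_pair[(which + i) % 2]
        for seg_s, seg_e, label in src:
            if seg_e <= s or seg_s >= e:
                continue
            gamete.append((max(seg_s, s), min(seg_e, e), label))
    # merge abutting segments with identical labels
    merged: Mosaic = []
    for seg in gamete:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged, bps


def _meiosis_genome(
    haplotypes: tuple[dict, dict],
    scaffold_lengths: dict[str, int],
    model: RecombinationModel,
    rng: np.random.Generator,
) -> dict:
    return {
        name: meiosis((haplotypes[0][name], haplotypes[1][name]), L, model, rng)[0]
        for name, L in scaffold_lengths.items()
    }


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeSpec:
    """A pedigree: founders with population labels, ordered matings, and
    the focal individual that will be rendered."""

    founders: dict[str, str]  # id -> population ("A" or "B")
    matings: tuple[tuple[str, str, str], ...]  # (sire, dam, child)
    focal_id: str

    def __post_init__(self) -> None:
        known = set(self.founders)
        for pop in self.founders.values():
            if pop not in ("A", "B"):
                raise ValueError(f"founder population must be 'A' or 'B', got {pop!r}")
        for sire, dam, child in self.matings:
            for parent in (sire, dam):
                if parent not in known:
                    raise ValueError(
                        f"parent {parent!r} of {child!r} is not defined before use"
                    )
            if child in known:
                raise ValueError(f"individual {child!r} defined twice")
            known.add(child)
        if self.focal_id not in known:
            raise ValueError(f"focal individual {self.focal_id!r} not in pedigree")


@dataclass
class TruthTracts:
    """Ground truth for one simulated individual.

    ``autozygous`` are the intervals where the two haplotypes descend
    from the same founder haplotype copy; ``truncated`` flags tracts cut
    off by a scaffold end (excluded from tract-length formula checks,
    whose renewal-process mean assumes unbounded chromosomes).
    ``ancestry`` gives, per haplotype, the population-labelled segments.
    """

    autozygous: list[Interval]
    truncated: list[bool]
    ancestry: tuple[list[tuple[Interval, str]], list[tuple[Interval, str]]]

    def autozygous_lengths(self, include_truncated: bool = True) -> np.ndarray:
        return np.array(
            [
                iv.length
                for iv, t in zip(self.autozygous, self.truncated)
                if include_truncated or not t
            ],
            dtype=float,
        )

    def diploid_ancestry(self) -> list[tuple[Interval, str]]:
        """Per-bp diploid ancestry: A, B, or MIXED (one haplotype each)."""
        by_scaffold: dict[str, list] = {}
        for hap in self.ancestry:
            for iv, pop in hap:
                by_scaffold.setdefault(iv.scaffold, []).append((iv, pop))
        out: list[tuple[Interval, str]] = []
        for scaffold in by_scaffold:
            h0 = [(iv, p) for iv, p in self.ancestry[0] if iv.scaffold == scaffold]
            h1 = [(iv, p) for iv, p in self.ancestry[1] if iv.scaffold == scaffold]
            pieces = _overlay(
                [(iv.start, iv.end, p) for iv, p in h0],
                [(iv.start, iv.end, p) for iv, p in h1],
            )
            run: list[tuple[int, int, str]] = []
            for s, e, p0, p1 in pieces:
                lab = p0 if p0 == p1 else "MIXED"
                if run and run[-1][2] == lab and run[-1][1] == s:
                    run[-1] = (run[-1][0], e, lab)
                else:
                    run.append((s, e, lab))
            out.extend((Interval(scaffold, s, e), lab) for s, e, lab in run)
        return out


def _overlay(m0, m1):
    """Refine two segment lists tiling the same range into common pieces."""
    out = []
    i = j = 0
    while i < len(m0) and j < len(m1):
        s = max(m0[i][0], m1[j][0])
        e = min(m0[i][1], m1[j][1])
        if e > s:
            out.append((s, e, m0[i][2], m1[j][2]))
        if m0[i][1] <= m1[j][1]:
            i += 1
        else:
            j += 1
    return out


def _truth_from_mosaics(
    haplotypes: tuple[dict, dict], scaffold_lengths: dict[str, int]
) -> TruthTracts:
    autozygous: list[Interval] = []
    truncated: list[bool] = []
    ancestry: tuple[list, list] = ([], [])
    for name, L in scaffold_lengths.items():
        pieces = _overlay(haplotypes[0][name], haplotypes[1][name])
        run_start = None
        prev_end = None
        for s, e, l0, l1 in pieces:
            if l0 == l1:
                if run_start is None:
                    run_start = s
                prev_end = e
            else:
                if run_start is not None:
                    autozygous.append(Interval(name, run_start, prev_end))
                    truncated.append(run_start == 0 or prev_end == L)
                    run_start = None
        if run_start is not None:
            autozygous.append(Interval(name, run_start, prev_end))
            truncated.append(run_start == 0 or prev_end == L)
        for h in (0, 1):
            merged: list[tuple[int, int, str]] = []
            for s, e, label in haplotypes[h][name]:
                pop = label.population
                if merged and merged[-1][2] == pop and merged[-1][1] == s:
                    merged[-1] = (merged[-1][0], e, pop)
                else:
                    merged.append((s, e, pop))
            ancestry[h].extend((Interval(name, s, e), pop) for s, e, pop in merged)
    return TruthTracts(autozygous=autozygous, truncated=truncated, ancestry=ancestry)


def simulate_pedigree(
    pedigree: PedigreeSpec,
    pool: FounderPool,
    model: RecombinationModel | None = None,
    seed: int = 0,
    render: bool = True,
) -> tuple[DiploidGenome | None, TruthTracts]:
    """Propagate haplotypes through a pedigree and return the focal
    individual (rendered as an IUPAC consensus unless ``render=False``)
    together with its ground-truth tracts.

    Each meiosis consumes its own counter-derived RNG sub-stream, so
    results are reproducible for a given ``seed`` independent of how the
    pool caches are warmed.
    """
    model = model or RecombinationModel()
    haps: dict[str, tuple[dict, dict]] = {}
    for fid, pop in pedigree.founders.items():
        haps[fid] = pool.founder_mosaics(fid, pop)
    counter = 0
    for sire, dam, child in pedigree.matings:
        gametes = []
        for parent in (sire, dam):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, _STREAM_MEIOSIS, counter])
            )
            counter += 1
            gametes.append(
                _meiosis_genome(haps[parent], pool.scaffold_lengths, model, rng)
            )
        haps[child] = (gametes[0], gametes[1])
    focal_haps = haps[pedigree.focal_id]
    truth = _truth_from_mosaics(focal_haps, pool.scaffold_lengths)
    genome = pool.render_diploid(pedigree.focal_id, focal_haps) if render else None
    return genome, truth


# ---------------------------------------------------------------------------
# Scenario builders
# ---------------------------------------------------------------------------

def isolated_inbred_pedigree(
    g: int, n_founders: int | None = None, seed: int = 0
) -> PedigreeSpec:
    """Pedigree whose inbreeding-loop common ancestor(s) sit exactly ``g``
    generations back from the focal individual.

    With ``n_founders=None`` a single half-sib chain loop is built (one
    common ancestor, inbreeding coefficient ``2**-(2g-1)``) — the clean
    setting for tract-length formula work.  With ``n_founders=K`` the
    focal's two parental lineages are independent descent trees rooted in
    the same K-founder generation (a population bottleneck g generations
    ago); every IBD path still spans exactly 2g meioses but the expected
    autozygous fraction rises to about ``1/(2K)``, which makes deep loops
    testable at desk scale.
    """
    if g < 1:
        raise ValueError(f"g must be >= 1, got {g}")
    if n_founders is None:
        if g == 1:
            return PedigreeSpec(
                founders={"F0": "A"}, matings=(("F0", "F0", "focal"),), focal_id="focal"
            )
        founders = {"ANC": "A"}
        matings: list[tuple[str, str, str]] = []
        tips = []
        for side in ("a", "b"):
            mate = f"M_{side}0"
            founders[mate] = "A"
            child = f"C_{side}0"
            matings.append(("ANC", mate, child))
            for i in range(1, g - 1):
                mate = f"M_{side}{i}"
                founders[mate] = "A"
                nxt = f"C_{side}{i}"
                matings.append((child, mate, nxt))
                child = nxt
            tips.append(child)
        matings.append((tips[0], tips[1], "focal"))
        return PedigreeSpec(founders=founders, matings=tuple(matings), focal_id="focal")
    if n_founders < 2:
        raise ValueError(f"n_founders must be >= 2, got {n_founders}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAM_PEDIGREE]))
    founders = {f"F{i}": "A" for i in range(n_founders)}
    matings = []
    count = [0]

    def build(depth: int) -> str:
        if depth == g:
            return f"F{int(rng.integers(n_founders))}"
        p1 = build(depth + 1)
        p2 = build(depth + 1)
        count[0] += 1
        child = f"I{count[0]}"
        matings.append((p1, p2, child))
        return child

    sire = build(1)
    dam = build(1)
    matings.append((sire, dam, "focal"))
    return PedigreeSpec(founders=founders, matings=tuple(matings), focal_id="focal")


def admixed_inbred_pedigree(g: int = 2) -> PedigreeSpec:
    """A population-B founder crossed into a population-A pedigree, with
    a half-sib inbreeding loop around the admixed ancestor ``g``
    generations above the focal individual."""
    if g < 1:
        raise ValueError(f"g must be >= 1, got {g}")
    founders = {"B0": "B", "A0": "A"}
    matings: list[tuple[str, str, str]] = [("B0", "A0", "HYB")]
    if g == 1:
        matings.append(("HYB", "HYB", "focal"))
        return PedigreeSpec(founders=founders, matings=tuple(matings), focal_id="focal")
    tips = []
    k = 1
    for side in ("a", "b"):
        founders[f"A{k}"] = "A"
        child = f"C_{side}0"
        matings.append(("HYB", f"A{k}", child))
        k += 1
        for i in range(1, g - 1):
            founders[f"A{k}"] = "A"
            nxt = f"C_{side}{i}"
            matings.append((child, f"A{k}", nxt))
            k += 1
            child = nxt
        tips.append(child)
    matings.append((tips[0], tips[1], "focal"))
    return PedigreeSpec(founders=founders, matings=tuple(matings), focal_id="focal")


SCENARIOS = ("isolated_inbred", "admixed_inbred")

_DEFAULT_SIZES = {
    "scaffold_lengths": {f"scaf{i+1}": 25_000_000 for i in range(4)},
    "het_rate": 1e-3,
    "fixed_diff_rate": 1e-4,
    "n_founders": None,
    "n_panel": 3,
}


@dataclass
class ScenarioBundle:
    """Everything one simulated scenario produced."""

    name: str
    g: int
    seed: int
    params: dict
    pedigree: PedigreeSpec
    pool: FounderPool
    focal: DiploidGenome | None
    truth: TruthTracts
    panels: dict[str, list[DiploidGenome]] = field(default_factory=dict)


def scenario(
    name: str,
    g: int,
    sizes: dict | None = None,
    seed: int = 0,
    model: RecombinationModel | None = None,
    outdir: str | os.PathLike | None = None,
    render: bool = True,
) -> ScenarioBundle:
    """Simulate a named study condition and optionally write its bundle.

    ``isolated_inbred`` builds an inbreeding loop whose common ancestor
    is ``g`` generations back within a single population;
    ``admixed_inbred`` crosses a population-B founder into an A pedigree
    and then inbreeds around the admixed ancestor.  ``sizes`` may
    override ``scaffold_lengths``, ``het_rate``, ``fixed_diff_rate``,
    ``n_founders`` (isolated only) and ``n_panel``.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    params = dict(_DEFAULT_SIZES)
    params.update(sizes or {})
    model = model or RecombinationModel()
    spec = PopulationPanelSpec(
        scaffold_lengths=dict(params["scaffold_lengths"]),
        het_rate=params["het_rate"],
        fixed_diff_rate=params["fixed_diff_rate"],
        seed=seed,
    )
    pool = simulate_panels(spec)
    if name == "isolated_inbred":
        pedigree = isolated_inbred_pedigree(g, n_founders=params["n_founders"], seed=seed)
    else:
        pedigree = admixed_inbred_pedigree(g)
    focal, truth = simulate_pedigree(pedigree, pool, model=model, seed=seed, render=render)
    panels: dict[str, list[DiploidGenome]] = {}
    if render and params["n_panel"]:
        pops = ("A", "B") if name == "admixed_inbred" else ("A",)
        for pop in pops:
            panels[pop] = [
                pool.render_diploid(
                    f"panel{pop}_{i}", pool.founder_mosaics(f"panel{pop}_{i}", pop)
                )
                for i in range(params["n_panel"])
            ]
    bundle = ScenarioBundle(
        name=name,
        g=g,
        seed=seed,
        params={**params, "r_cM_per_Mb": model.rate},
        pedigree=pedigree,
        pool=pool,
        focal=focal,
        truth=truth,
        panels=panels,
    )
    if outdir is not None:
        write_scenario(bundle, outdir)
    return bundle


def write_scenario(bundle: ScenarioBundle, outdir: str | os.PathLike) -> None:
    """Write a scenario bundle: focal/panel FASTAs, truth BEDs, parameter echo."""
    os.makedirs(outdir, exist_ok=True)
    outdir = os.fspath(outdir)
    if bundle.focal is not None:
        write_iupac_fasta(bundle.focal, os.path.join(outdir, "focal.fasta"))
    for pop, genomes in bundle.panels.items():
        for genome in genomes:
            write_iupac_fasta(
                genome, os.path.join(outdir, f"{genome.individual_id}.fasta")
            )
    write_bed(bundle.truth.autozygous, os.path.join(outdir, "truth_roh.bed"))
    for h in (0, 1):
        ivs = [iv for iv, _ in bundle.truth.ancestry[h]]
        labs = [pop for _, pop in bundle.truth.ancestry[h]]
        write_bed(ivs, os.path.join(outdir, f"truth_ancestry_hap{h}.bed"), labels=labs)
    echo = {
        "scenario": bundle.name,
        "g": bundle.g,
        "seed": bundle.seed,
        **{
            k: v
            for k, v in bundle.params.items()
            if k != "scaffold_lengths"
        },
        "scaffold_lengths": {k: int(v) for k, v in bundle.params["scaffold_lengths"].items()},
        "focal_id": bundle.pedigree.focal_id,
        "n_matings": len(bundle.pedigree.matings),
    }
    with open(os.path.join(outdir, "scenario.yaml"), "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False)


def expected_tract_length_mb(g: int, r_cm_per_mb: float = 1.1) -> float:
    """Renewal-process mean autozygous tract length (Mb) for a loop
    ancestor ``g`` generations back: L = 100 / (2 r g)."""
    return 100.0 / (2.0 * r_cm_per_mb * g)


def collect_truth_tract_lengths(
    g: int,
    n_tracts: int,
    scaffold_lengths: dict[str, int] | None = None,
    n_founders: int | None = None,
    model: RecombinationModel | None = None,
    seed: int = 0,
    max_replicates: int = 10_000,
) -> np.ndarray:
    """Accumulate non-truncated ground-truth autozygous tract lengths (bp)
    over replicate pedigree simulations until ``n_tracts`` are collected.

    Truth-only (no sequence rendering), so replicates are cheap.  The
    default scaffolds are long (1 Gb) relative to the tracts of interest:
    excluding end-truncated tracts under-samples long tracts, a bias of
    order (mean tract length)/(scaffold length) that long scaffolds make
    negligible.
    """
    scaffold_lengths = scaffold_lengths or {f"s{i}": 1_000_000_000 for i in range(4)}
    model = model or RecombinationModel()
    lengths: list[float] = []
    for rep in range(max_replicates):
        rep_seed = (seed * 100_003 + rep) % (2**31 - 1)
        spec = PopulationPanelSpec(
            scaffold_lengths=scaffold_lengths, het_rate=0.0, fixed_diff_rate=0.0,
            seed=rep_seed,
        )
        pool = simulate_panels(spec)
        pedigree = isolated_inbred_pedigree(g, n_founders=n_founders, seed=rep_seed)
        _, truth = simulate_pedigree(
            pedigree, pool, model=model, seed=rep_seed, render=False
        )
        lengths.extend(truth.autozygous_lengths(include_truncated=False))
        if len(lengths) >= n_tracts:
            break
    return np.asarray(lengths, dtype=float)
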