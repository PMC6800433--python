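# rohkit

Runs-of-homozygosity (ROH) analysis for conservation genomics: call ROH
from diploid consensus genomes with a hidden Markov model, date tracts
in generations, quantify how much ROH two individuals share identical by
descent (IBD), classify the ancestry of each tract in admixed genomes,
and date mitochondrial splits with a molecular clock. A built-in
pedigree/admixture simulator provides exact ground truth for every
stage.

## The problem

Small, isolated wildlife populations — think of fragmented puma
populations hemmed in by freeways and development — inbreed. When an
individual's maternal and paternal lineages coalesce in a recent common
ancestor, it inherits two copies of the same ancestral haplotype, and
the genome shows a long *run of homozygosity*. The length of such a
tract carries a date: a tract of length *L* Mb has survived 2*g*
meioses without recombining, so with recombination rate *r* (cM/Mb)

```
g = 100 / (2 r L)
```

generations separate the individual from the shared ancestor. At the
felid average *r* = 1.1 cM/Mb, tracts longer than 15.2 Mb imply close
inbreeding (a common ancestor under 3 generations back), while tracts
shorter than 5.7 Mb date to ancestors more than 8 generations back —
the signature of populations that were small in the historical past.
Whether two individuals' ROH *overlap and match* (are IBD) tells a
manager whether reconnecting populations would actually restore
diversity: tracts that are fixed in one population but absent in another
can be rescued by gene flow.

## What the package computes

- **`seqio`** — IUPAC consensus FASTA I/O (het sites coded R/Y/S/W/K/M,
  masked sites N), masked-consensus construction from a genotype table,
  X-chromosome pseudo-diploids, BED intervals.
- **`heterozygosity`** — per-window heterozygote counts with
  callable-site exposures; genome-wide heterozygosity.
- **`roh_hmm`** — two-state HMM (inbred/outbred) over window counts with
  Poisson-with-exposure emissions; Baum–Welch fitting, Viterbi +
  posterior decoding, tract extraction with a 2 Mb confidence floor.
- **`dating`** — g = 100/(2rL), its inverse, F_ROH, and tract-length
  histograms over generation-derived classes {2, 5.7, 9.1, 15.2, ∞} Mb.
- **`ibd`** — pairwise ROH intersection with an optional
  homozygote-identity filter; the pairwise IBD-sharing matrix.
- **`ancestry`** — ancestry-diagnostic site selection from two panels
  and a three-state (pure-A / pure-B / MIXED) HMM with
  distance-dependent transitions; per-ROH ancestry labels.
- **`mito`** — pairwise divergence of aligned mitogenomes and
  molecular-clock node dating (default 1.15% of sites per Myr).
- **`simulate`** — two diverged source populations, explicit pedigrees
  with inbreeding loops *g* generations deep, meiosis with Poisson
  crossovers at a stated cM/Mb rate, and exact truth tracts
  (autozygosity and ancestry) carried through every meiosis.

## Worked example

Simulate an individual whose parents share a common ancestor 3
generations back, then call and date its ROH:

```python
import rohkit as rk
from rohkit.heterozygosity import genome_het, window_het
from rohkit.roh_hmm import decode, extract_tracts, fit
from rohkit.dating import summarize, tract_generations

lengths = {f"scaf{i+1}": 25_000_000 for i in range(6)}
bundle = rk.scenario(
    "isolated_inbred", 3,
    sizes={"scaffold_lengths": lengths, "n_founders": 4, "n_panel": 0},
    seed=11,
)
print(f"genome-wide heterozygosity: {genome_het(bundle.focal):.2e} per bp")
track = window_het(bundle.focal)                       # 100 kb windows
params, _ = fit(track)                                 # Baum-Welch
calls = extract_tracts(decode(track, params), track)   # ROH > 2 Mb
summary = summarize(calls, genome_length=sum(lengths.values()))
print(f"called {summary.n_tracts} ROH, F_ROH = {summary.f_roh:.3f}")
for iv, g in zip(calls.tracts, tract_generations(calls.lengths_mb())):
    print(f"  {iv.scaffold}:{iv.start}-{iv.end}  {iv.length/1e6:.1f} Mb  ~{g:.1f} generations")
```

Output:

```
genome-wide heterozygosity: 8.70e-04 per bp
called 2 ROH, F_ROH = 0.127
  scaf1:9100000-25000000  15.9 Mb  ~2.9 generations
  scaf2:21700000-24900000  3.2 Mb  ~14.2 generations
```

The 15.9 Mb tract dates the parents' shared ancestor to ~3 generations
back, exactly the loop depth the simulator was given; the ground truth
for this seed contains 19.3 Mb of autozygous sequence, of which the
caller recovered the two tracts above the 2 Mb reporting floor.

The same stages are available from the shell:

```
rohkit simulate --scenario isolated_inbred --g 3 --seed 11 --out sim/
rohkit roh call --fasta sim/focal.fasta --out-prefix sim/focal
rohkit roh date --bed sim/focal.roh.bed --genome-length 100000000 --out sim/dated.tsv
```

## Documentation

See `docs/methods.md` for the models, their assumptions, the default
parameter choices, and known limitations.
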