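"""Sequence and interval I/O for diploid consensus genomes.

A diploid individual is represented as a single "consensus" sequence per
scaffold in which heterozygous sites carry the two-base IUPAC ambiguity
code (R, Y, S, W, K, M), homozygous sites carry the plain base, and
masked/failed sites carry N.  This is the standard input representation
for heterozygosity-based ROH callers.

Coordinates are 0-based half-open everywhere inside the package (BED
convention).  Genotype tables use 1-based positions (VCF convention) on
disk and are converted on load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

# Two-base IUPAC ambiguity codes.  Three/four-base codes (B, D, H, V) are
# deliberately rejected: only biallelic SNPs are representable.
IUPAC_HET: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
PAIR_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_HET.items()}

BASES = "ACGT"
HET_CODES = "RYSWKM"
ALPHABET = frozenset(BASES + HET_CODES + "N")

_HET_BYTES = np.frombuffer(HET_CODES.encode(), dtype=np.uint8)
_N_BYTE = ord("N")


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class Interval(NamedTuple):
    """A 0-based half-open genomic interval."""

    scaffold: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self) -> "Interval":
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        return self


@dataclass
class DiploidGenome:
    """Named scaffolds of IUPAC-coded diploid consensus sequence.

    Parameters
    ----------
    individual_id : str
        Sample identifier.
    scaffolds : dict[str, str]
        Ordered mapping of scaffold name to uppercase sequence over the
        11-letter alphabet {A, C, G, T, R, Y, S, W, K, M, N}.
    """

    individual_id: str
    scaffolds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.scaffolds.items():
            _validate_sequence(name, seq)

    @property
    def scaffold_names(self) -> list[str]:
        return list(self.scaffolds)

    def length(self, scaffold: str) -> int:
        return len(self.scaffolds[scaffold])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def as_bytes(self, scaffold: str) -> np.ndarray:
        """Scaffold sequence as a uint8 array (read-only view)."""
        arr = np.frombuffer(self.scaffolds[scaffold].encode(), dtype=np.uint8)
        return arr


def _validate_sequence(name: str, seq: str) -> None:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    legal = np.zeros(256, dtype=bool)
    legal[[ord(c) for c in ALPHABET]] = True
    bad = ~legal[arr]
    if bad.any():
        offset = int(np.argmax(bad))
        raise ValueError(
            f"illegal character {seq[offset]!r} in scaffold {name!r} "
            f"at offset {offset}"
        )


def read_iupac_fasta(path: str | os.PathLike, individual_id: str | None = None) -> DiploidGenome:
    """Read a diploid consensus FASTA.

    Lowercase (soft-masked) bases are uppercased, not masked.  Characters
    outside the 11-letter alphabet raise :class:`ValueError` naming the
    scaffold and offset; structural problems raise
    :class:`FastaParseError` naming the line.
    """
    path = os.fspath(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header, "
                        f"got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA")

    scaffolds: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in scaffolds:
            raise FastaParseError(f"{path}: duplicate scaffold name {record.id!r}")
        seq = str(record.seq).upper()
        _validate_sequence(record.id, seq)
        scaffolds[record.id] = seq
    if individual_id is None:
        individual_id = os.path.splitext(os.path.basename(path))[0]
    return DiploidGenome(individual_id=individual_id, scaffolds=scaffolds)


def write_iupac_fasta(genome: DiploidGenome, path: str | os.PathLike, width: int = 80) -> None:
    """Write a genome as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in genome.scaffolds.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Genotype tables and masked-consensus construction
# ---------------------------------------------------------------------------

GENOTYPE_STATES = ("hom_ref", "het", "hom_alt", "missing")


def read_genotype_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-separated genotype table.

    Expected header: ``scaffold pos genotype ref alt`` with 1-based
    positions and genotype in {hom_ref, het, hom_alt, missing}
    (hyphenated spellings accepted).  Positions are converted to 0-based
    on load and must be unique per scaffold.
    """
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "ref": str, "alt": str})
    required = {"scaffold", "pos", "genotype", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"genotype table missing columns {sorted(required - set(df.columns))}")
    df["genotype"] = df["genotype"].str.replace("-", "_", regex=False)
    bad = ~df["genotype"].isin(GENOTYPE_STATES)
    if bad.any():
        raise ValueError(f"unknown genotype value {df.loc[bad, 'genotype'].iloc[0]!r}")
    df["pos"] = df["pos"].astype(int) - 1  # to 0-based
    if df.duplicated(subset=["scaffold", "pos"]).any():
        raise ValueError("duplicate (scaffold, pos) rows in genotype table")
    return df


def het_code(a: str, b: str) -> str:
    """IUPAC code for the unordered heterozygous pair {a, b}."""
    key = frozenset((a.upper(), b.upper()))
    try:
        return PAIR_TO_CODE[key]
    except KeyError:
        raise ValueError(f"no biallelic IUPAC code for allele pair {a!r}/{b!r}") from None


def build_masked_fasta(
    reference: DiploidGenome,
    table: pd.DataFrame,
    failed_sites: Iterable[Interval] = (),
) -> DiploidGenome:
    """Build a masked diploid consensus from a haploid reference.

    Het genotypes become the IUPAC code of the two alleles, hom-alt the
    alternate base, missing genotypes and every position in
    ``failed_sites`` become N; all other positions copy the reference.
    Output scaffolds keep the reference lengths exactly.
    """
    out: dict[str, bytearray] = {
        name: bytearray(seq.encode()) for name, seq in reference.scaffolds.items()
    }
    for row in table.itertuples(index=False):
        if row.scaffold not in out:
            raise ValueError(f"genotype row names unknown scaffold {row.scaffold!r}")
        buf = out[row.scaffold]
        if not 0 <= row.pos < len(buf):
            raise ValueError(
                f"position {row.pos + 1} outside scaffold {row.scaffold!r} "
                f"(length {len(buf)})"
            )
        if row.genotype == "hom_ref":
            ch = row.ref.upper()
        elif row.genotype == "hom_alt":
            ch = row.alt.upper()
        elif row.genotype == "het":
            ch = het_code(row.ref, row.alt)
        else:  # missing
            ch = "N"
        if ch != "N" and ch not in ALPHABET:
            raise ValueError(f"allele {ch!r} is not a valid base at {row.scaffold}:{row.pos + 1}")
        buf[row.pos] = ord(ch)
    for iv in failed_sites:
        iv.validate()
        if iv.scaffold not in out:
            raise ValueError(f"failed-site interval names unknown scaffold {iv.scaffold!r}")
        buf = out[iv.scaffold]
        buf[iv.start : min(iv.end, len(buf))] = b"N" * (min(iv.end, len(buf)) - iv.start)
    return DiploidGenome(
        individual_id=reference.individual_id,
        scaffolds={name: buf.decode() for name, buf in out.items()},
    )


def make_pseudodiploid(hap_a: str, hap_b: str) -> str:
    """Merge two aligned haploid sequences into one diploid consensus.

    Per site: equal bases give that base, differing ACGT bases give their
    IUPAC heterozygous code, and N on either haplotype gives N.  Used for
    X-chromosome pseudo-diploids (two males' X haplotypes analysed as one
    synthetic diploid) and to render simulated individuals.
    """
    if len(hap_a) != len(hap_b):
        raise ValueError(
            f"haplotype length mismatch: {len(hap_a)} vs {len(hap_b)}"
        )
    a = np.frombuffer(hap_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(hap_b.upper().encode(), dtype=np.uint8)
    for name, arr, seq in (("first", a, hap_a), ("second", b, hap_b)):
        legal = np.zeros(256, dtype=bool)
        legal[[ord(c) for c in "ACGTN"]] = True
        bad = ~legal[arr]
        if bad.any():
            off = int(np.argmax(bad))
            raise ValueError(
                f"{name} haplotype has non-ACGTN character "
                f"{seq[off]!r} at offset {off}"
            )
    out = a.copy()
    either_n = (a == _N_BYTE) | (b == _N_BYTE)
    out[either_n] = _N_BYTE
    diff = (a != b) & ~either_n
    if diff.any():
        for i in np.nonzero(diff)[0]:
            out[i] = ord(het_code(chr(a[i]), chr(b[i])))
    return out.tobytes().decode()


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read a BED3+ file into a list of intervals (extra columns ignored)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            scaffold, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: end ({end}) must exceed start ({start})"
                )
            out.append(Interval(scaffold, start, end))
    return out


def write_bed(
    intervals: Iterable[Interval],
    path: str | os.PathLike,
    labels: Iterable[str] | None = None,
) -> None:
    """Write intervals as BED3 (or BED4 with ``labels``), sorted by scaffold then start."""
    rows = list(intervals)
    if labels is None:
        order = sorted(range(len(rows)), key=lambda i: (rows[i].scaffold, rows[i].start))
        with open(path, "w") as fh:
            for i in order:
                iv = rows[i]
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\n")
    else:
        labs = list(labels)
        if len(labs) != len(rows):
            raise ValueError("labels must match intervals one-to-one")
        order = sorted(range(len(rows)), key=lambda i: (rows[i].scaffold, rows[i].start))
        with open(path, "w") as fh:
            for i in order:
                iv = rows[i]
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{labs[i]}\n")
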