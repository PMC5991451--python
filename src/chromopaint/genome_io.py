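"""Mask-aware FASTA input and BED probe-file input/output.

A single coordinate convention is used throughout the package: 0-based,
half-open intervals, exactly as in the BED standard.  1-based coordinates
appear nowhere.

Repeat masking is consumed, never computed: lowercase (soft-masked) bases
and hard-masked ``N`` runs in the input assembly are both recorded in the
per-base mask of :class:`MaskedSequence`.  IUPAC ambiguity codes degrade to
``N`` (masked) rather than raising, since real assemblies contain them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "MaskedSequence",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
]

#: residues a MaskedSequence may contain after normalisation
CORE_ALPHABET = frozenset("ACGTN")

#: IUPAC one-letter ambiguity codes accepted on input (degraded to N)
_AMBIGUITY = frozenset("RYSWKMBDHVU")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN core alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class MaskedSequence:
    """A named nucleotide sequence plus per-base repeat-mask flags.

    ``residues`` is uppercase over ``{A, C, G, T, N}``; ``mask[i]`` is True
    for every base that was lowercase (soft-masked), ``N``, or an ambiguity
    code in the source FASTA.
    """

    name: str
    residues: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.residues):
            raise ValueError(
                f"{self.name}: mask length {len(self.mask)} != "
                f"sequence length {len(self.residues)}"
            )
        bad = set(self.residues) - CORE_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: non-core residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def window_is_clean(self, start: int, end: int) -> bool:
        """True if ``[start, end)`` contains no masked base and no N."""
        return not self.mask[start:end].any()


def _normalise_record(name: str, raw: str) -> MaskedSequence:
    """Uppercase, record lowercase/N/ambiguity as masked, reject garbage."""
    arr = np.frombuffer(raw.encode("ascii", errors="replace"), dtype=np.uint8).copy()
    lower = (arr >= ord("a")) & (arr <= ord("z"))
    arr[lower] -= 32  # uppercase in place
    mask = lower.copy()

    text = arr.tobytes().decode("ascii")
    allowed = CORE_ALPHABET | _AMBIGUITY
    bad = set(text) - allowed
    if bad:
        raise ValueError(
            f"record {name!r}: non-nucleotide characters {sorted(bad)!r}"
        )

    # ambiguity codes -> N, masked; N itself is always masked
    is_core = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    not_core = ~is_core
    arr[not_core] = ord("N")
    mask |= not_core
    return MaskedSequence(name=name, residues=arr.tobytes().decode("ascii"), mask=mask)


def read_fasta(path: Union[str, Path]) -> List[MaskedSequence]:
    """Read a (multi-)FASTA file into mask-aware sequences, in file order.

    Raises ``ValueError`` on an empty file, duplicate record names, or
    characters outside the IUPAC nucleotide alphabet (naming the record).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seen: set = set()
    out: List[MaskedSequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        out.append(_normalise_record(rec.id, str(rec.seq)))
    return out


def write_fasta(
    seqs: Iterable[MaskedSequence], path: Union[str, Path], width: int = 60
) -> None:
    """Write sequences restoring soft-masking (masked non-N bases lowercase)."""
    with open(path, "w", newline="\n") as fh:
        for seq in seqs:
            arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8).copy()
            to_lower = seq.mask & (arr != ord("N"))
            arr[to_lower] += 32
            text = arr.tobytes().decode("ascii")
            fh.write(f">{seq.name}\n")
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


def genome_by_name(seqs: Sequence[MaskedSequence], name: str) -> MaskedSequence:
    for seq in seqs:
        if seq.name == name:
            return seq
    raise KeyError(f"chromosome {name!r} not found in genome")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: Union[str, Path]) -> List[GenomicInterval]:
    """Parse a BED3+ file into 0-based half-open intervals.

    Comment / ``track`` / ``browser`` lines are skipped.  Malformed
    coordinates raise ``ValueError`` with the offending line number.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "+"
            intervals.append(GenomicInterval(cols[0], start, end, strand))
    return intervals


def _probe_records(probe_set) -> List[tuple]:
    """Normalise a ProbeSet (or iterable of probes) to BED6 record tuples."""
    probes = getattr(probe_set, "probes", probe_set)
    records = []
    for i, probe in enumerate(probes):
        iv = probe.interval
        dtm = getattr(getattr(probe, "profile", None), "dtm", None)
        if dtm is None:
            score = "0.00"
        elif np.isinf(dtm):
            score = "inf"
        else:
            score = f"{dtm:.2f}"
        name = f"{iv.chrom}:{iv.start}-{iv.end}"
        records.append((iv.chrom, iv.start, iv.end, name, score, "+"))
    return records


def write_bed(probe_set, path: Union[str, Path]) -> None:
    """Write a probe set as BED6 (score = dTm rounded to 2 decimals).

    The input must already be sorted by (chrom, start); unsorted input is a
    caller bug and raises ``ValueError``.
    """
    records = _probe_records(probe_set)
    keys = [(chrom, start) for chrom, start, *_ in records]
    if keys != sorted(keys):
        raise ValueError("probe set is not sorted by (chrom, start)")
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")
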