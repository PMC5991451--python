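"""Shared helpers: tiny genomes, independent window-matching oracles."""

from __future__ import annotations

import random

import numpy as np
import pytest

from chromopaint.genome_io import MaskedSequence

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def random_dna(seed: int, n: int, alphabet: str = "ACGT") -> str:
    rng = random.Random(seed)
    return "".join(rng.choice(alphabet) for _ in range(n))


def ms(name: str, residues: str) -> MaskedSequence:
    """MaskedSequence from a cased string: lowercase and N are masked."""
    mask = np.array([c.islower() or c.upper() == "N" for c in residues])
    return MaskedSequence(name=name, residues=residues.upper(), mask=mask)


def window_matches(a: str, b: str) -> int:
    """Ungapped match count; N never matches (independent oracle helper)."""
    return sum(1 for x, y in zip(a, b) if x == y and x != "N")


def brute_stems(seq: str, min_stem: int = 4, min_loop: int = 3):
    """Every ungapped hairpin stem (i, j, k) by direct triple enumeration."""
    n = len(seq)
    out = []
    for k in range(min_stem, n // 2 + 1):
        for i in range(0, n - k + 1):
            for j in range(i + k + min_loop, n - k + 1):
                if seq[j : j + k] == rc(seq[i : i + k]):
                    out.append((i, j, k))
    return out


@pytest.fixture
def two_chrom_genome():
    """Two unmasked 400 bp chromosomes (deterministic)."""
    return [ms("chrA", random_dna(11, 400)), ms("chrB", random_dna(12, 400))]
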