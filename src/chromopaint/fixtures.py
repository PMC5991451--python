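"""Seeded synthetic genomes with planted structure and ground-truth manifests.

Every stage of the probe-design pipeline can be exercised without any
download: fixtures carry planted repeat blocks (masked), planted exact or
near-identical duplications, and planted palindromic hairpin segments,
together with a JSON-serialisable manifest recording exactly what was
planted.  A single integer seed drives all randomness, so any failure
replays bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .genome_io import GenomicInterval, MaskedSequence, reverse_complement

__all__ = [
    "FixtureManifest",
    "PlantedDuplication",
    "PlantedHairpin",
    "generate_genome",
    "plant_repeat",
    "plant_duplication",
    "plant_hairpin",
    "random_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedDuplication:
    source: GenomicInterval
    target: GenomicInterval
    n_substitutions: int


@dataclass(frozen=True)
class PlantedHairpin:
    interval: GenomicInterval
    stem_len: int
    loop_len: int


@dataclass
class FixtureManifest:
    rng_seed: int
    planted_repeats: List[GenomicInterval] = field(default_factory=list)
    planted_duplications: List[PlantedDuplication] = field(default_factory=list)
    planted_hairpins: List[PlantedHairpin] = field(default_factory=list)
    expected_unique_sites: Optional[List[GenomicInterval]] = None

    def to_json(self, path: Union[str, Path]) -> None:
        def iv(x: GenomicInterval) -> dict:
            return {"chrom": x.chrom, "start": x.start, "end": x.end, "strand": x.strand}

        payload = {
            "rng_seed": self.rng_seed,
            "planted_repeats": [iv(r) for r in self.planted_repeats],
            "planted_duplications": [
                {"source": iv(d.source), "target": iv(d.target),
                 "n_substitutions": d.n_substitutions}
                for d in self.planted_duplications
            ],
            "planted_hairpins": [
                {"interval": iv(h.interval), "stem_len": h.stem_len,
                 "loop_len": h.loop_len}
                for h in self.planted_hairpins
            ],
            "expected_unique_sites": (
                None if self.expected_unique_sites is None
                else [iv(r) for r in self.expected_unique_sites]
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FixtureManifest":
        def iv(d: dict) -> GenomicInterval:
            return GenomicInterval(d["chrom"], d["start"], d["end"], d.get("strand", "+"))

        data = json.loads(Path(path).read_text())
        return cls(
            rng_seed=data["rng_seed"],
            planted_repeats=[iv(r) for r in data["planted_repeats"]],
            planted_duplications=[
                PlantedDuplication(iv(d["source"]), iv(d["target"]), d["n_substitutions"])
                for d in data["planted_duplications"]
            ],
            planted_hairpins=[
                PlantedHairpin(iv(h["interval"]), h["stem_len"], h["loop_len"])
                for h in data["planted_hairpins"]
            ],
            expected_unique_sites=(
                None if data["expected_unique_sites"] is None
                else [iv(r) for r in data["expected_unique_sites"]]
            ),
        )


def generate_genome(
    length: int, gc_fraction: float, seed: int, name: str = "chr1"
) -> MaskedSequence:
    """An i.i.d. random unmasked chromosome at the stated GC fraction."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    draws = rng.choice(4, size=length, p=[at, gc, gc, at])
    residues = _BASES[draws].tobytes().decode("ascii")
    return MaskedSequence(name=name, residues=residues, mask=np.zeros(length, bool))


def _replace(seq: MaskedSequence, start: int, text: str,
             mask_value: Optional[bool] = None) -> MaskedSequence:
    residues = seq.residues[:start] + text + seq.residues[start + len(text):]
    mask = seq.mask.copy()
    if mask_value is not None:
        mask[start : start + len(text)] = mask_value
    return MaskedSequence(name=seq.name, residues=residues, mask=mask)


def _with_chrom(genome: List[MaskedSequence], new: MaskedSequence) -> List[MaskedSequence]:
    return [new if s.name == new.name else s for s in genome]


def plant_repeat(
    genome: Sequence[MaskedSequence], region: GenomicInterval
) -> List[MaskedSequence]:
    """Mark ``region`` as repeat-masked (content unchanged)."""
    genome = list(genome)
    seq = _by_name(genome, region.chrom)
    mask = seq.mask.copy()
    mask[region.start : region.end] = True
    return _with_chrom(genome, MaskedSequence(seq.name, seq.residues, mask))


def _by_name(genome: Sequence[MaskedSequence], name: str) -> MaskedSequence:
    for s in genome:
        if s.name == name:
            return s
    raise KeyError(name)


def plant_duplication(
    genome: Sequence[MaskedSequence],
    source: GenomicInterval,
    target: GenomicInterval,
    n_substitutions: int,
    seed: int,
) -> List[MaskedSequence]:
    """Overwrite ``target`` with a copy of ``source`` carrying exactly
    ``n_substitutions`` substitutions at seeded positions (each substituted
    base differs from the copied base).  Source and target may live on
    different chromosomes but must not overlap."""
    if len(source) != len(target):
        raise ValueError("source and target must have equal length")
    if n_substitutions > len(source):
        raise ValueError("more substitutions than bases")
    if source.overlaps(target):
        raise ValueError("source and target overlap")
    genome = list(genome)
    src_seq = _by_name(genome, source.chrom)
    copy = np.frombuffer(
        src_seq.residues[source.start : source.end].encode("ascii"), dtype=np.uint8
    ).copy()
    rng = np.random.default_rng(seed)
    if n_substitutions:
        sites = rng.choice(len(copy), size=n_substitutions, replace=False)
        for pos in sites:
            code = np.where(_BASES == copy[pos])[0]
            choices = np.delete(np.arange(4), code)
            copy[pos] = _BASES[rng.choice(choices)]
    tgt_seq = _by_name(genome, target.chrom)
    return _with_chrom(
        genome, _replace(tgt_seq, target.start, copy.tobytes().decode("ascii"))
    )


def plant_hairpin(
    genome: Sequence[MaskedSequence],
    chrom: str,
    position: int,
    stem_len: int,
    loop_len: int,
    seed: int,
) -> List[MaskedSequence]:
    """Write STEM + random loop + revcomp(STEM) at ``position``.

    ``stem_len == 0`` leaves the genome unchanged.  The stem is drawn
    GC-rich so that oligos spanning it reliably fail the dTm screen."""
    genome = list(genome)
    if stem_len == 0:
        return genome
    rng = np.random.default_rng(seed)
    stem = "".join(
        "GC"[i] for i in rng.integers(0, 2, size=stem_len)
    )
    loop = "".join("ACGT"[i] for i in rng.integers(0, 4, size=loop_len))
    text = stem + loop + reverse_complement(stem)
    seq = _by_name(genome, chrom)
    if position + len(text) > len(seq):
        raise ValueError("hairpin does not fit at position")
    return _with_chrom(genome, _replace(seq, position, text))


def random_fixture(
    seed: int,
    length: int = 8000,
    n_chroms: int = 1,
    gc_fraction: float = 0.45,
    n_duplications: int = 2,
    substitution_choices: Sequence[int] = (0, 3, 6, 9),
    dup_len: int = 45,
    n_repeats: int = 1,
    repeat_len: int = 300,
    n_hairpins: int = 0,
    stem_len: int = 12,
    loop_len: int = 5,
) -> Tuple[List[MaskedSequence], FixtureManifest]:
    """A randomized fixture genome with planted structure and its manifest.

    Planted features are placed in disjoint slots so substitution counts in
    the manifest are exact and features never overwrite each other.
    """
    rng = np.random.default_rng(seed)
    genome = [
        generate_genome(length, gc_fraction, int(rng.integers(2**31)), name=f"chr{i+1}")
        for i in range(n_chroms)
    ]
    manifest = FixtureManifest(rng_seed=seed)

    # carve disjoint slots across the genome for planted features
    slot = max(dup_len, repeat_len, 2 * stem_len + loop_len) + 20
    slots: List[Tuple[str, int]] = []
    for s in genome:
        for start in range(10, len(s) - slot, slot):
            slots.append((s.name, start))
    order = rng.permutation(len(slots))
    cursor = 0

    def next_slot() -> Tuple[str, int]:
        nonlocal cursor
        if cursor >= len(order):
            raise ValueError("fixture too small for the requested features")
        chrom, start = slots[order[cursor]]
        cursor += 1
        return chrom, start

    for _ in range(n_repeats):
        chrom, start = next_slot()
        region = GenomicInterval(chrom, start, start + repeat_len)
        genome = plant_repeat(genome, region)
        manifest.planted_repeats.append(region)

    for _ in range(n_duplications):
        c1, s1 = next_slot()
        c2, s2 = next_slot()
        source = GenomicInterval(c1, s1, s1 + dup_len)
        target = GenomicInterval(c2, s2, s2 + dup_len)
        nsub = int(rng.choice(np.asarray(substitution_choices)))
        genome = plant_duplication(genome, source, target, nsub, int(rng.integers(2**31)))
        manifest.planted_duplications.append(PlantedDuplication(source, target, nsub))

    for _ in range(n_hairpins):
        chrom, start = next_slot()
        genome = plant_hairpin(genome, chrom, start, stem_len, loop_len,
                               int(rng.integers(2**31)))
        manifest.planted_hairpins.append(
            PlantedHairpin(
                GenomicInterval(chrom, start, start + 2 * stem_len + loop_len),
                stem_len, loop_len,
            )
        )
    return genome, manifest


# ---------------------------------------------------------------------------
# independent ground-truth prediction (targeted direct comparison)
# ---------------------------------------------------------------------------


def predicted_nonunique_starts(
    genome: Sequence[MaskedSequence],
    manifest: FixtureManifest,
    chrom: str,
    oligo_length: int,
    step: int,
    min_identity: float,
) -> set:
    """Window starts on ``chrom`` expected to fail the uniqueness screen.

    Computed by direct string comparison of each tiled window against the
    shifted copy implied by every planted duplication (both directions),
    plus a local minus-strand self-scan around planted hairpins — fully
    independent of the specificity module.  Random background cannot reach
    the identity threshold at the fixture sizes used (p ~ 1e-18 per
    window), so planted features are the only elimination source.
    """
    import math as _math

    need = int(_math.ceil(min_identity * oligo_length - 1e-9))
    by_name = {s.name: s for s in genome}
    text = by_name[chrom].residues
    bad: set = set()

    def window_matches(a: str, b: str) -> int:
        return sum(1 for x, y in zip(a, b) if x == y and x != "N")

    pairs = []
    for dup in manifest.planted_duplications:
        pairs.append((dup.source, dup.target))
        pairs.append((dup.target, dup.source))

    for start in range(0, len(text) - oligo_length + 1, step):
        window = text[start : start + oligo_length]
        end = start + oligo_length
        for here, there in pairs:
            if here.chrom != chrom or not (start < here.end and here.start < end):
                continue
            shift = there.start - here.start
            other = by_name[there.chrom].residues
            # scan a small offset band around the implied position
            for off in range(-oligo_length + 1, oligo_length):
                pos = start + shift + off
                if pos < 0 or pos + oligo_length > len(other):
                    continue
                if there.chrom == chrom and abs(pos - start) < oligo_length:
                    continue  # would overlap the window's own locus
                if window_matches(window, other[pos : pos + oligo_length]) >= need:
                    bad.add(start)
        for hp in manifest.planted_hairpins:
            if hp.interval.chrom != chrom:
                continue
            lo = max(0, hp.interval.start - 2 * oligo_length)
            hi = min(len(text) - oligo_length, hp.interval.end + oligo_length)
            rc = reverse_complement(window)
            for pos in range(lo, hi + 1):
                if window_matches(rc, text[pos : pos + oligo_length]) >= need:
                    bad.add(start)
    return bad
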