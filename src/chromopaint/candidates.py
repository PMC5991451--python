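"""Candidate oligo generation: fixed-length tiling and repeat-mask filtering.

Candidates are tiled on the forward strand only; the specificity search
considers both strands, so one canonical representation per window is
enough.  A single masked or ambiguous base anywhere in a window disqualifies
the whole candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Set

import numpy as np

from .genome_io import GenomicInterval, MaskedSequence

__all__ = ["CandidateOligo", "PipelineConfig", "tile", "mask_filter"]


@dataclass
class CandidateOligo:
    """A fixed-length genomic window flowing through the filter stages."""

    interval: GenomicInterval
    sequence: str
    stage_flags: Set[str] = field(default_factory=set)
    profile: Optional[object] = None  # ThermoProfile, attached by the pipeline

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError("sequence length does not match interval width")

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class PipelineConfig:
    """All tunable pipeline constants, with the published defaults.

    ``homology_threshold`` is an inclusive lower bound on ungapped identity
    (0.75 over 45 nt means >= 34 matching bases disqualifies a second
    locus); ``dtm_min`` is a strict lower bound (dTm must exceed it).
    """

    oligo_length: int = 45
    step: int = 5
    homology_threshold: float = 0.75
    dtm_min: float = 10.0
    density_per_kb: float = 2.0
    target_count: Optional[int] = None
    rng_seed: int = 0
    # specificity search knobs
    seed_k: int = 9
    seed_mismatches: int = 1
    exact: bool = False
    # thermodynamic screen knobs
    min_stem: int = 4
    min_loop: int = 3
    monovalent_cation: float = 0.05
    strand_conc: float = 0.25e-6
    # density basis: "total" chromosome length or "unmasked" length
    density_basis: str = "total"

    def __post_init__(self) -> None:
        if self.oligo_length < 1:
            raise ValueError("oligo_length must be >= 1")
        if not (0 < self.step <= self.oligo_length):
            raise ValueError("require 0 < step <= oligo_length")
        if not (0 < self.homology_threshold <= 1):
            raise ValueError("require 0 < homology_threshold <= 1")
        if self.density_per_kb <= 0:
            raise ValueError("density_per_kb must be > 0")
        if self.density_basis not in ("total", "unmasked"):
            raise ValueError("density_basis must be 'total' or 'unmasked'")
        if self.target_count is not None and self.target_count < 1:
            raise ValueError("target_count must be >= 1")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def tile(seq: MaskedSequence, oligo_length: int, step: int) -> List[CandidateOligo]:
    """Tile ``seq`` into windows of ``oligo_length`` every ``step`` bases.

    Starts run 0, step, 2*step, ... up to ``len(seq) - oligo_length``
    inclusive; a sequence shorter than one window yields an empty list.
    No mask filtering happens here.
    """
    if oligo_length < 1 or step < 1:
        raise ValueError("oligo_length and step must be >= 1")
    n = len(seq)
    out: List[CandidateOligo] = []
    for start in range(0, n - oligo_length + 1, step):
        end = start + oligo_length
        out.append(
            CandidateOligo(
                interval=GenomicInterval(seq.name, start, end),
                sequence=seq.residues[start:end],
                stage_flags={"tiled"},
            )
        )
    return out


def mask_filter(
    candidates: List[CandidateOligo], seq: MaskedSequence
) -> List[CandidateOligo]:
    """Drop every candidate whose window touches a masked base or an N.

    The mask already covers N and ambiguity bases (see genome_io), so a
    single prefix-sum over the mask answers every window query.
    """
    bad = np.concatenate([[0], np.cumsum(seq.mask.astype(np.int64))])
    kept = []
    for cand in candidates:
        if bad[cand.end] - bad[cand.start] == 0:
            cand.stage_flags.add("mask_pass")
            kept.append(cand)
    return kept
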