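"""Density-controlled, non-overlapping final probe selection.

The chromosome is partitioned into fixed-width bins (1000 / density bp);
each bin contributes at most one probe — the eligible candidate with the
highest dTm (ties: smallest start) whose window does not overlap the
previously selected probe.  Bins with no eligible candidate are recorded as
shortfall.  An optional target count is enforced by even thinning in
genomic order, which preserves uniform coverage and needs no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .candidates import CandidateOligo

__all__ = ["ProbeSet", "select_by_density", "build_stage_report", "STAGES"]

#: canonical pipeline stage order for reports
STAGES = ["tiled", "mask_filter", "uniqueness_filter", "dtm_filter", "selected"]


@dataclass
class ProbeSet:
    """The ordered, non-overlapping final selection plus provenance counts."""

    probes: List[CandidateOligo]
    bin_width: float
    shortfall_bins: List[int] = field(default_factory=list)
    stage_report: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = -1
        prev_chrom = None
        for probe in self.probes:
            iv = probe.interval
            if iv.chrom == prev_chrom and iv.start < prev_end:
                raise ValueError(f"overlapping probes at {iv}")
            if iv.chrom == prev_chrom and iv.start < 0:
                raise ValueError("unsorted probes")
            prev_end, prev_chrom = iv.end, iv.chrom

    def __len__(self) -> int:
        return len(self.probes)


def select_by_density(
    candidates: List[CandidateOligo],
    chrom_length: int,
    density_per_kb: float,
    target_count: Optional[int] = None,
    density_basis: str = "total",
    unmasked_length: Optional[int] = None,
) -> ProbeSet:
    """Pick at most one probe per bin at the requested density.

    ``candidates`` must be sorted by start and fully filtered, each with a
    thermo profile attached.  With ``density_basis="unmasked"`` the bin
    width is stretched so the expected yield is density x unmasked-kb
    rather than density x total-kb.
    """
    if density_per_kb <= 0:
        raise ValueError("density_per_kb must be > 0")
    starts = [c.start for c in candidates]
    if starts != sorted(starts):
        raise ValueError("candidates must be sorted by start")

    bin_width = 1000.0 / density_per_kb
    if density_basis == "unmasked":
        if not unmasked_length:
            raise ValueError("unmasked_length required for density_basis='unmasked'")
        bin_width = chrom_length * 1000.0 / (density_per_kb * unmasked_length)
    oligo_len = len(candidates[0].sequence) if candidates else 0
    if candidates and bin_width < oligo_len:
        raise ValueError(
            f"bin width {bin_width:.1f} bp < oligo length {oligo_len} bp: "
            "a non-overlapping probe per bin is impossible at this density"
        )

    n_bins = max(1, math.ceil(chrom_length / bin_width)) if chrom_length > 0 else 0
    by_bin: Dict[int, List[CandidateOligo]] = {}
    for cand in candidates:
        if cand.profile is None:
            raise ValueError("candidate has no thermo profile attached")
        by_bin.setdefault(int(cand.start // bin_width), []).append(cand)

    selected: List[CandidateOligo] = []
    shortfall: List[int] = []
    prev_end = -1
    for b in range(n_bins):
        pool = by_bin.get(b, [])
        pool = sorted(pool, key=lambda c: (-c.profile.dtm, c.start))
        chosen = None
        for cand in pool:
            if cand.start >= prev_end:
                chosen = cand
                break
        if chosen is None:
            shortfall.append(b)
        else:
            chosen.stage_flags.add("selected")
            selected.append(chosen)
            prev_end = chosen.end

    if target_count is not None and len(selected) > target_count:
        idx = np.round(np.linspace(0, len(selected) - 1, target_count)).astype(int)
        selected = [selected[i] for i in sorted(set(int(i) for i in idx))]

    return ProbeSet(probes=selected, bin_width=bin_width, shortfall_bins=shortfall)


def build_stage_report(counts: Dict[str, int]) -> List[Tuple[str, int, int]]:
    """Rows of (stage, survivors, eliminated-at-this-stage), telescoping.

    Raises if any stage has more survivors than the one before it.
    """
    rows: List[Tuple[str, int, int]] = []
    prev: Optional[int] = None
    for stage in STAGES:
        if stage not in counts:
            continue
        n = counts[stage]
        eliminated = 0 if prev is None else prev - n
        if prev is not None and n > prev:
            raise ValueError(f"stage {stage} has {n} survivors > previous {prev}")
        rows.append((stage, n, eliminated))
        prev = n
    return rows
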