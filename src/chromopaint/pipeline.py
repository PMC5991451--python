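"""End-to-end probe design: tile -> mask -> uniqueness -> thermo -> select.

The run is deterministic: re-running with the same inputs and config
produces a byte-identical BED.  Every run serialises its effective config,
input digests and per-stage survivor counts as a RunRecord JSON next to
the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from . import __version__
from .candidates import CandidateOligo, PipelineConfig, mask_filter, tile
from .genome_io import MaskedSequence, genome_by_name, read_fasta, write_bed
from .selection import ProbeSet, build_stage_report, select_by_density
from .specificity import build_kmer_index, uniqueness_filter
from .thermo import ThermoModel, dtm_filter, thermo_profile

__all__ = ["RunRecord", "run_pipeline"]

log = logging.getLogger("chromopaint")


@dataclass
class RunRecord:
    config: Dict
    inputs: Dict[str, str]
    stage_counts: Dict[str, int]
    outputs: List[str] = field(default_factory=list)
    version: str = __version__

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_thermo_tsv(candidates: Sequence[CandidateOligo], path: Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("id\ttm\thairpin_tm\tdtm\n")
        for cand in candidates:
            p = cand.profile
            iv = cand.interval
            hp = "NA" if p.hairpin_tm is None else f"{p.hairpin_tm:.4f}"
            dtm = "inf" if p.dtm == float("inf") else f"{p.dtm:.4f}"
            fh.write(f"{iv.chrom}:{iv.start}-{iv.end}\t{p.tm:.4f}\t{hp}\t{dtm}\n")


def run_pipeline(
    genome: Union[str, Path, Sequence[MaskedSequence]],
    target_chrom: str,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> Tuple[ProbeSet, RunRecord]:
    """Design a chromosome-specific probe set.

    ``genome`` may be a FASTA path or an in-memory list of sequences; the
    uniqueness screen always runs against the whole genome (every
    chromosome, both strands), while tiling is restricted to
    ``target_chrom``.
    """
    config = config or PipelineConfig()
    t0 = time.time()

    inputs: Dict[str, str] = {}
    if isinstance(genome, (str, Path)):
        path = Path(genome)
        inputs[str(path)] = _sha256(path)
        seqs = read_fasta(path)
    else:
        seqs = list(genome)
        inputs["<in-memory>"] = hashlib.sha256(
            "".join(s.name + s.residues for s in seqs).encode()
        ).hexdigest()

    target = genome_by_name(seqs, target_chrom)
    counts: Dict[str, int] = {}

    cands = tile(target, config.oligo_length, config.step)
    counts["tiled"] = len(cands)
    log.info("tiled %d candidates on %s (%.2fs)", len(cands), target_chrom, time.time() - t0)

    cands = mask_filter(cands, target)
    counts["mask_filter"] = len(cands)
    log.info("mask filter kept %d", len(cands))

    if config.exact:
        cands = uniqueness_filter(
            cands, seqs, config.homology_threshold, exact=True
        )
    else:
        index = build_kmer_index(seqs, config.seed_k)
        cands = uniqueness_filter(
            cands,
            seqs,
            config.homology_threshold,
            index=index,
            seed_mismatches=config.seed_mismatches,
        )
    counts["uniqueness_filter"] = len(cands)
    log.info("uniqueness filter kept %d", len(cands))

    model = ThermoModel(
        monovalent_cation=config.monovalent_cation,
        strand_conc=config.strand_conc,
    )
    for cand in cands:
        cand.profile = thermo_profile(
            cand.sequence, model, min_stem=config.min_stem, min_loop=config.min_loop
        )
    profiled = list(cands)
    cands = dtm_filter(cands, config.dtm_min)
    counts["dtm_filter"] = len(cands)
    log.info("dTm filter kept %d", len(cands))

    probe_set = select_by_density(
        cands,
        chrom_length=len(target),
        density_per_kb=config.density_per_kb,
        target_count=config.target_count,
        density_basis=config.density_basis,
        unmasked_length=int((~target.mask).sum()),
    )
    counts["selected"] = len(probe_set)
    probe_set.stage_report = counts
    build_stage_report(counts)  # validates telescoping
    log.info(
        "selected %d probes (%d shortfall bins) in %.2fs",
        len(probe_set), len(probe_set.shortfall_bins), time.time() - t0,
    )

    record = RunRecord(config=config.to_dict(), inputs=inputs, stage_counts=counts)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: List[Path] = []
        try:
            bed = out_dir / "probes.bed"
            write_bed(probe_set, bed)
            written.append(bed)
            thermo_tsv = out_dir / "thermo.tsv"
            _write_thermo_tsv(profiled, thermo_tsv)
            written.append(thermo_tsv)
            report = out_dir / "stage_report.tsv"
            with open(report, "w", newline="\n") as fh:
                fh.write("stage\tsurvivors\teliminated\n")
                for stage, n, elim in build_stage_report(counts):
                    fh.write(f"{stage}\t{n}\t{elim}\n")
            written.append(report)
            record.outputs = [str(p) for p in written + [out_dir / "run_record.json"]]
            record.to_json(out_dir / "run_record.json")
        except Exception:
            for p in written:  # no partial outputs
                p.unlink(missing_ok=True)
            raise

    return probe_set, record
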