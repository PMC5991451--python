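"""Nearest-neighbor melting temperatures and the duplex-vs-hairpin screen.

Duplex Tm uses the unified nearest-neighbor parameter set (shipped as a TSV
data file) with a SantaLucia-style entropic salt correction and a
bimolecular concentration term.  The hairpin model is deliberately simple:
the melting temperature of the strongest ungapped Watson-Crick stem,
evaluated unimolecularly (no concentration term), with G.T wobbles not
counted as pairing.  An oligo with no stem at all has no hairpin Tm and its
dTm is treated as +infinity (always kept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genome_io import reverse_complement

__all__ = [
    "NO_HAIRPIN",
    "ThermoModel",
    "ThermoProfile",
    "melting_temperature",
    "hairpin_tm",
    "thermo_profile",
    "dtm_filter",
]

#: sentinel for "no complementary stem exists" (dTm treated as +inf)
NO_HAIRPIN = None

R_GAS = 1.9872  # cal/(mol*K)
_KELVIN = 273.15


def _load_table() -> Tuple[Dict[str, Tuple[float, float]], Dict[str, Tuple[float, float]], Tuple[float, float]]:
    stacks: Dict[str, Tuple[float, float]] = {}
    inits: Dict[str, Tuple[float, float]] = {}
    sym = (0.0, 0.0)
    text = resources.files("chromopaint.data").joinpath("nn_unified.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        kind, key, dh, ds = line.split("\t")
        entry = (float(dh), float(ds))
        if kind == "stack":
            stacks[key] = entry
        elif kind == "init":
            inits[key] = entry
        elif kind == "sym":
            sym = entry
    if len(stacks) != 16:
        raise RuntimeError("nearest-neighbor table must define all 16 stacks")
    return stacks, inits, sym


@dataclass
class ThermoModel:
    """Parameter table plus solution conditions for Tm prediction.

    ``monovalent_cation`` and ``strand_conc`` (total strand) are molar.
    """

    nn_stacks: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    nn_init: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    nn_sym: Tuple[float, float] = (0.0, -1.4)
    monovalent_cation: float = 0.05
    strand_conc: float = 0.25e-6
    symmetry_correction: bool = True

    def __post_init__(self) -> None:
        if not self.nn_stacks:
            self.nn_stacks, self.nn_init, self.nn_sym = _load_table()
        if len(self.nn_stacks) != 16:
            raise ValueError("all 16 dinucleotide stack entries are required")
        if self.monovalent_cation <= 0 or self.strand_conc <= 0:
            raise ValueError("concentrations must be > 0")


_DEFAULT_MODEL: Optional[ThermoModel] = None


def default_model() -> ThermoModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = ThermoModel()
    return _DEFAULT_MODEL


@dataclass(frozen=True)
class ThermoProfile:
    """Duplex Tm, hairpin Tm and their margin for one oligo (degrees C)."""

    tm: float
    hairpin_tm: Optional[float]
    dtm: float

    @classmethod
    def build(cls, tm: float, hairpin: Optional[float]) -> "ThermoProfile":
        dtm = math.inf if hairpin is NO_HAIRPIN else tm - hairpin
        return cls(tm=tm, hairpin_tm=hairpin, dtm=dtm)


def _is_self_complementary(seq: str) -> bool:
    return seq == reverse_complement(seq)


def melting_temperature(
    seq: str, model: Optional[ThermoModel] = None, unimolecular: bool = False
) -> float:
    """Nearest-neighbor duplex Tm of ``seq`` against its perfect complement.

    Tm = 1000*dH / (dS + dS_salt [+ R*ln(C_T/x)]) - 273.15, with the
    concentration term omitted in unimolecular mode (used for hairpin
    stems).  Deterministic to full floating precision for a fixed model.
    """
    model = model or default_model()
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    if set(seq) - set("ACGT"):
        raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")

    dh = 0.0
    ds = 0.0
    for base in (seq[0], seq[-1]):
        h, s = model.nn_init["GC" if base in "GC" else "AT"]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = model.nn_stacks[seq[i : i + 2]]
        dh += h
        ds += s

    selfcomp = _is_self_complementary(seq)
    if not unimolecular and model.symmetry_correction and selfcomp:
        dh += model.nn_sym[0]
        ds += model.nn_sym[1]

    ds_salt = 0.368 * (len(seq) - 1) * math.log(model.monovalent_cation)
    denom = ds + ds_salt
    if not unimolecular:
        x = 1.0 if selfcomp else 4.0
        denom += R_GAS * math.log(model.strand_conc / x)
    return 1000.0 * dh / denom - _KELVIN


_CODE = np.full(256, -1, dtype=np.int8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c


def hairpin_tm(
    seq: str,
    model: Optional[ThermoModel] = None,
    min_stem: int = 4,
    min_loop: int = 3,
) -> Optional[float]:
    """Tm of the strongest ungapped hairpin stem, or ``NO_HAIRPIN``.

    Every stem (i, j, k) with ``seq[j:j+k] == revcomp(seq[i:i+k])``, stem
    length ``k >= min_stem`` and loop ``j - (i + k) >= min_loop`` is scored
    as the unimolecular NN duplex Tm of the stem sequence; the maximum wins.

    Stems are enumerated along anti-diagonals of the Watson-Crick pairing
    matrix: a stem's base pairs (p, q) all satisfy p + q = const, so runs
    of consecutive complementary pairs on one anti-diagonal are exactly the
    maximal stems whose sub-stems need scoring.
    """
    model = model or default_model()
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_stem + min_loop:
        return NO_HAIRPIN
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")

    # complement iff codes sum to 3 (A<->T, C<->G); N never pairs
    best: Optional[float] = None
    comp = (codes[:, None] + codes[None, :]) == 3
    for s in range(2 * n - 1):  # anti-diagonal index: p + q == s
        p_lo = max(0, s - n + 1)
        p_hi = (s + 1) // 2  # p < q
        if p_hi <= p_lo:
            continue
        ps = np.arange(p_lo, p_hi)
        diag = comp[ps, s - ps]
        run = 0
        for t in range(len(ps)):
            run = run + 1 if diag[t] else 0
            if run < min_stem:
                continue
            p = int(ps[t])
            q = s - p
            if q - p - 1 < min_loop:
                continue  # innermost pair too close; outer stems were seen earlier
            for k in range(min_stem, run + 1):
                stem = seq[p - k + 1 : p + 1]
                tm = melting_temperature(stem, model, unimolecular=True)
                if best is None or tm > best:
                    best = tm
    return best


def thermo_profile(
    seq: str,
    model: Optional[ThermoModel] = None,
    min_stem: int = 4,
    min_loop: int = 3,
) -> ThermoProfile:
    model = model or default_model()
    tm = melting_temperature(seq, model)
    hp = hairpin_tm(seq, model, min_stem=min_stem, min_loop=min_loop)
    return ThermoProfile.build(tm, hp)


def dtm_filter(candidates: List, dtm_min: float) -> List:
    """Keep candidates with dTm strictly greater than ``dtm_min``.

    A candidate without any hairpin stem has dTm == +inf and is always
    kept; dTm exactly equal to the threshold is dropped.
    """
    kept = []
    for cand in candidates:
        if cand.profile is None:
            raise ValueError("candidate has no thermo profile attached")
        if cand.profile.dtm > dtm_min:
            cand.stage_flags.add("dtm_pass")
            kept.append(cand)
    return kept
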