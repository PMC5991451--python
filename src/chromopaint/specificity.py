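"""Genome-wide homology search and the two-or-more-loci uniqueness filter.

"Homology" here is ungapped full-length percent identity of the oligo
against a genomic window (matches / oligo_length), on either strand of any
chromosome; N always scores as a mismatch.  A candidate survives iff its
only qualifying locus is its own source.

Three search routes exist:

* :func:`brute_force_homology` — a pure-Python full scan; the reference
  semantics, used as an oracle on small inputs.
* exact mode — a vectorised full scan over all diagonals, mathematically
  identical to the brute force (validated against it in the test suite);
  usable as the production path via ``exact=True``.
* heuristic mode — seed-and-extend with mismatch-tolerant k-mer seeds and
  exact ungapped verification.  With the defaults (k=9, one mismatch
  tolerated per seed) the pigeonhole over five disjoint 9-mers of a 45-mer
  guarantees a firing seed for every window with at most 9 mismatches,
  i.e. every locus at >= 80% identity; below that, sensitivity is high but
  not guaranteed.  Verification is exact, so false positives never occur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .candidates import CandidateOligo
from .genome_io import GenomicInterval, MaskedSequence, reverse_complement

__all__ = [
    "HomologyHit",
    "KmerIndex",
    "build_kmer_index",
    "brute_force_homology",
    "find_homologous_loci",
    "uniqueness_filter",
    "matches_required",
]


class InternalConsistencyError(RuntimeError):
    """A candidate's own source locus was not recovered as a hit."""


_CODE = np.full(256, 4, dtype=np.int8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c


def encode(seq_or_masked: Union[str, MaskedSequence]) -> np.ndarray:
    """Encode residues as int8 (A=0, C=1, G=2, T=3, N=4), cached per object."""
    if isinstance(seq_or_masked, MaskedSequence):
        cached = getattr(seq_or_masked, "_codes", None)
        if cached is not None:
            return cached
        codes = _CODE[
            np.frombuffer(seq_or_masked.residues.encode("ascii"), dtype=np.uint8)
        ]
        object.__setattr__(seq_or_masked, "_codes", codes)
        return codes
    return _CODE[np.frombuffer(seq_or_masked.encode("ascii"), dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return np.where(codes == 4, 4, 3 - codes)[::-1].astype(np.int8)


def matches_required(min_identity: float, oligo_length: int) -> int:
    """Smallest match count m with m / oligo_length >= min_identity."""
    return int(math.ceil(min_identity * oligo_length - 1e-9))


@dataclass(frozen=True)
class HomologyHit:
    """One genomic locus matching an oligo at >= threshold identity."""

    interval: GenomicInterval
    identity: float
    is_source: bool = False


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------


class KmerIndex:
    """All-positions index of forward-strand k-mers of a genome.

    Backed by a sorted uint64 array with CSR-style position payloads so
    that thousands of seed queries resolve in one ``searchsorted`` call.
    K-mers containing N are never indexed.  Minus-strand search is done by
    querying the reverse complement of the oligo against this forward
    index, which is equivalent to indexing both strands.
    """

    def __init__(self, k: int, chrom_names: List[str], kmers: np.ndarray,
                 chrom_ids: np.ndarray, positions: np.ndarray):
        self.k = k
        self.chrom_names = chrom_names
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._chrom_ids = chrom_ids[order]
        self._positions = positions[order]

    @property
    def n_positions(self) -> int:
        return len(self._kmers)

    def lookup_with_query_ids(
        self, queries: np.ndarray
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(query index, chrom_id, position) for every occurrence of every query."""
        lo = np.searchsorted(self._kmers, queries, side="left")
        hi = np.searchsorted(self._kmers, queries, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, empty
        qid = np.repeat(np.arange(len(queries)), counts)
        # flat index ranges [lo_i, hi_i) expanded without a Python loop
        base = np.repeat(lo, counts)
        intra = np.arange(total) - np.repeat(
            np.concatenate([[0], np.cumsum(counts)[:-1]]), counts
        )
        idx = base + intra
        return qid, self._chrom_ids[idx].astype(np.int64), self._positions[idx].astype(np.int64)

    def lookup_batch(self, queries: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(chrom_id, position) arrays for all occurrences of all queries."""
        _, cids, poss = self.lookup_with_query_ids(queries)
        return cids, poss

    def occurrences(self, kmer: str, strand: str = "+") -> List[Tuple[str, int]]:
        """Positions of one k-mer (forward coordinates).  With strand '-',
        returns loci whose minus strand reads ``kmer``."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        query = kmer if strand == "+" else reverse_complement(kmer)
        codes = encode(query)
        if (codes == 4).any():
            return []
        val = np.uint64(0)
        for c in codes:
            val = val * np.uint64(4) + np.uint64(c)
        cids, poss = self.lookup_batch(np.array([val], dtype=np.uint64))
        return [(self.chrom_names[c], int(p)) for c, p in zip(cids, poss)]


def _kmer_ints(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(values, valid) for every k-window; valid=False where the window has N."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        vals = vals * np.uint64(4) + codes[j : j + m].astype(np.uint64)
    is_n = (codes == 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cs[k:] - cs[:-k]) == 0
    return vals, valid


def build_kmer_index(genome: Sequence[MaskedSequence], k: int) -> KmerIndex:
    """Index every N-free forward k-mer position of every chromosome."""
    if k < 1 or k > 31:
        raise ValueError("require 1 <= k <= 31")
    if all(len(seq) < k for seq in genome):
        raise ValueError(f"k={k} exceeds the length of every sequence")
    names = [seq.name for seq in genome]
    all_kmers, all_cids, all_pos = [], [], []
    for cid, seq in enumerate(genome):
        vals, valid = _kmer_ints(encode(seq), k)
        pos = np.nonzero(valid)[0]
        all_kmers.append(vals[pos])
        all_cids.append(np.full(len(pos), cid, dtype=np.int32))
        all_pos.append(pos.astype(np.int32))
    return KmerIndex(
        k,
        names,
        np.concatenate(all_kmers) if all_kmers else np.empty(0, np.uint64),
        np.concatenate(all_cids) if all_cids else np.empty(0, np.int32),
        np.concatenate(all_pos) if all_pos else np.empty(0, np.int32),
    )


# ---------------------------------------------------------------------------
# reference oracle: pure-Python full scan
# ---------------------------------------------------------------------------


def brute_force_homology(
    oligo: Union[str, CandidateOligo],
    genome: Sequence[MaskedSequence],
    min_identity: float,
    source: Optional[GenomicInterval] = None,
) -> List[HomologyHit]:
    """Full both-strand scan of every window; reference semantics, tests only.

    Emits every full-length window at >= ``min_identity`` ungapped identity
    (no locus merging).  Intentionally written with plain Python loops so
    it shares no code with the production paths.
    """
    if isinstance(oligo, CandidateOligo):
        source = source or oligo.interval
        seq = oligo.sequence
    else:
        seq = oligo
    m = len(seq)
    need = matches_required(min_identity, m)
    hits: List[HomologyHit] = []
    for chrom in genome:
        text = chrom.residues
        for strand in ("+", "-"):
            probe = seq if strand == "+" else reverse_complement(seq)
            for start in range(0, len(text) - m + 1):
                window = text[start : start + m]
                matches = 0
                for a, b in zip(probe, window):
                    if a == b and a != "N":
                        matches += 1
                if matches >= need:
                    iv = GenomicInterval(chrom.name, start, start + m, strand)
                    is_src = (
                        source is not None
                        and strand == "+"
                        and iv.overlaps(source)
                    )
                    hits.append(HomologyHit(iv, matches / m, is_src))
    return hits


# ---------------------------------------------------------------------------
# heuristic: mismatch-tolerant seeds + exact verification
# ---------------------------------------------------------------------------


def _seed_queries(codes: np.ndarray, k: int, mismatches: int) -> Tuple[np.ndarray, np.ndarray]:
    """All k-mer queries for one oligo orientation: (values, window offsets).

    With ``mismatches == 1`` every one-substitution neighbor of every
    k-mer is queried too, so any genomic k-mer within one mismatch of any
    oligo k-mer is guaranteed to seed.
    """
    vals, valid = _kmer_ints(codes, k)
    offs = np.nonzero(valid)[0]
    vals = vals[offs]
    if mismatches == 0 or len(vals) == 0:
        return vals, offs
    if mismatches != 1:
        raise ValueError("only 0 or 1 seed mismatches are supported")
    out_vals = [vals]
    out_offs = [offs]
    for p in range(k):
        weight = np.uint64(4) ** np.uint64(k - 1 - p)
        digit = (vals // weight) % np.uint64(4)
        for delta in (1, 2, 3):
            new_digit = (digit + np.uint64(delta)) % np.uint64(4)
            out_vals.append(vals + (new_digit - digit) * weight)
            out_offs.append(offs)
    return np.concatenate(out_vals), np.concatenate(out_offs)


def _verify_starts(
    probe_codes: np.ndarray, target_codes: np.ndarray, starts: np.ndarray
) -> np.ndarray:
    """Exact ungapped match counts of the probe at each window start."""
    m = len(probe_codes)
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64)
    windows = target_codes[starts[:, None] + np.arange(m)]
    eq = (windows == probe_codes) & (windows != 4) & (probe_codes != 4)
    return eq.sum(axis=1)


def _merge_hits(
    raw: List[Tuple[str, str, int, int]], m: int, source: Optional[GenomicInterval]
) -> List[HomologyHit]:
    """Chain overlapping same-chrom same-strand windows into loci (max identity)."""
    raw.sort(key=lambda r: (r[0], r[1], r[2]))
    loci: List[HomologyHit] = []
    i = 0
    while i < len(raw):
        chrom, strand, start, matches = raw[i]
        best_start, best_matches = start, matches
        end = start + m
        j = i + 1
        while j < len(raw) and raw[j][0] == chrom and raw[j][1] == strand and raw[j][2] < end:
            if raw[j][3] > best_matches:
                best_matches, best_start = raw[j][3], raw[j][2]
            end = max(end, raw[j][2] + m)
            j += 1
        iv = GenomicInterval(chrom, best_start, best_start + m, strand)
        is_src = source is not None and strand == "+" and iv.overlaps(source)
        loci.append(HomologyHit(iv, best_matches / m, is_src))
        i = j
    return loci


def find_homologous_loci(
    oligo: Union[str, CandidateOligo],
    genome: Sequence[MaskedSequence],
    index: KmerIndex,
    min_identity: float,
    seed_mismatches: int = 1,
    source: Optional[GenomicInterval] = None,
) -> List[HomologyHit]:
    """Seed-and-extend search for all loci matching the oligo at threshold.

    Offsets suggested by shared (mismatch-tolerant) k-mer seeds are verified
    by exact ungapped comparison over the full oligo length, then windows
    overlapping on the same chromosome and strand are merged into loci
    keeping the maximum identity.  No false positives are possible; see the
    module docstring for the sensitivity guarantee.
    """
    if isinstance(oligo, CandidateOligo):
        source = source or oligo.interval
        seq = oligo.sequence
    else:
        seq = oligo
    m = len(seq)
    need = matches_required(min_identity, m)
    fwd = encode(seq)
    rev = revcomp_codes(fwd)
    by_name = {s.name: s for s in genome}

    raw: List[Tuple[str, str, int, int]] = []
    for strand, probe in (("+", fwd), ("-", rev)):
        queries, offs = _seed_queries(probe, index.k, seed_mismatches)
        if len(queries) == 0:
            continue
        qids, cids, poss = index.lookup_with_query_ids(queries)
        if len(qids) == 0:
            continue
        window_starts = poss - offs[qids]
        for cid in np.unique(cids):
            name = index.chrom_names[cid]
            target = by_name[name]
            tcodes = encode(target)
            starts = np.unique(window_starts[cids == cid])
            starts = starts[(starts >= 0) & (starts <= len(target) - m)]
            counts = _verify_starts(probe, tcodes, starts)
            for s, c in zip(starts[counts >= need], counts[counts >= need]):
                raw.append((name, strand, int(s), int(c)))
    return _merge_hits(raw, m, source)


# ---------------------------------------------------------------------------
# exact vectorised full scan (production "--exact" path)
# ---------------------------------------------------------------------------


try:  # numba accelerates the exact full scan ~10x; numpy fallback is identical
    from numba import njit as _njit

    @_njit(cache=True)
    def _scan_diagonals(C, T, m, need, skip_own_overlap, elim):  # pragma: no cover
        lc = C.shape[0]
        lt = T.shape[0]
        for delta in range(-(lc - m), lt - m + 1):
            if skip_own_overlap and -m < delta < m:
                continue
            i0 = max(0, -delta)
            i1 = min(lc, lt - delta)
            if i1 - i0 < m:
                continue
            s = 0
            for t in range(m):
                a = C[i0 + t]
                b = T[i0 + delta + t]
                if a == b and a != 4:
                    s += 1
            if s >= need:
                elim[i0] = True
            for i in range(i0 + 1, i1 - m + 1):
                a = C[i - 1]
                b = T[i - 1 + delta]
                if a == b and a != 4:
                    s -= 1
                a = C[i + m - 1]
                b = T[i + m - 1 + delta]
                if a == b and a != 4:
                    s += 1
                if s >= need:
                    elim[i] = True

except ImportError:  # pragma: no cover
    _scan_diagonals = None


def _exact_offsource_mask(
    chrom: MaskedSequence,
    genome: Sequence[MaskedSequence],
    oligo_length: int,
    need: int,
    chunk: int = 256,
) -> np.ndarray:
    """Boolean array over every window start of ``chrom``: True if the window
    has a qualifying hit other than (overlapping) its own source locus.

    Scans every diagonal of chrom x target for both target orientations;
    identical semantics to brute_force_homology plus the source-collapse
    rule (plus-strand same-chrom hits overlapping the source by >= 1 bp do
    not count; any minus-strand hit does).  Diagonals are processed in
    chunks of a sliding alignment-matrix view to keep everything in numpy.
    """
    m = oligo_length
    C = encode(chrom)
    lc = len(C)
    n_starts = lc - m + 1
    elim = np.zeros(max(n_starts, 0), dtype=bool)
    if n_starts <= 0:
        return elim
    for target in genome:
        G = encode(target)
        lg = len(G)
        if lg < m:
            continue
        same = target.name == chrom.name
        for strand in ("+", "-"):
            T = G if strand == "+" else revcomp_codes(G)
            skip_own = strand == "+" and same
            if _scan_diagonals is not None:
                _scan_diagonals(
                    C, np.ascontiguousarray(T), m, need, skip_own, elim
                )
                continue
            # numpy fallback: chunked sliding alignment-matrix view
            T5 = np.where(T == 4, 5, T).astype(np.int8)  # N never matches N
            pad = np.full(lc - m, 6, dtype=np.int8)
            T_pad = np.concatenate([pad, T5, pad])
            # alignment row r puts C[0] against T_pad[r]; diagonal = r - (lc - m)
            view = np.lib.stride_tricks.sliding_window_view(T_pad, lc)
            n_rows = view.shape[0]
            for r0 in range(0, n_rows, chunk):
                rows = view[r0 : r0 + chunk]
                eq = rows == C
                cs = np.cumsum(eq, axis=1, dtype=np.int32)
                win = cs[:, m - 1 :].copy()
                win[:, 1:] -= cs[:, : n_starts - 1]
                qual = win >= need
                if skip_own:
                    deltas = np.arange(r0, r0 + rows.shape[0]) - (lc - m)
                    qual[np.abs(deltas) < m] = False  # own-source overlap
                elim |= qual.any(axis=0)
    return elim


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Concatenate arange(lo_i, hi_i) for all i; also return the owner index."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    owner = np.repeat(np.arange(len(lo)), counts)
    base = np.repeat(lo, counts)
    intra = np.arange(total) - np.repeat(
        np.concatenate([[0], np.cumsum(counts)[:-1]]), counts
    )
    return base + intra, owner


def _heuristic_orientation_mask(
    C: np.ndarray,
    starts: np.ndarray,
    genome: Sequence[MaskedSequence],
    index: KmerIndex,
    m: int,
    need: int,
    seed_mismatches: int,
    source_chrom: Optional[str],
) -> np.ndarray:
    """Elimination flags (aligned with ``starts``) for one probe orientation.

    All candidates are tiles of one substrate ``C``, so one set of
    chromosome-wide seed queries serves every candidate: a seed match of
    the k-mer at substrate position p to target position ``pos`` implies,
    for every candidate start s with s <= p <= s + m - k, the verification
    window ``pos - (p - s)``.  Verification is exact over the full oligo
    length.  ``source_chrom`` enables the own-locus collapse rule (used
    for the forward orientation only).
    """
    k = index.k
    elim = np.zeros(len(starts), dtype=bool)
    if len(starts) == 0:
        return elim
    queries, offs = _seed_queries(C, k, seed_mismatches)
    if len(queries) == 0:
        return elim
    qids, cids, poss = index.lookup_with_query_ids(queries)
    if len(qids) == 0:
        return elim
    p_arr = offs[qids]
    valid_c = C != 4
    for cid in np.unique(cids):
        name = index.chrom_names[cid]
        target = None
        for seq in genome:
            if seq.name == name:
                target = seq
                break
        T = encode(target)
        lt = len(T)
        if lt < m:
            continue
        sel = cids == cid
        P = p_arr[sel]
        delta = poss[sel] - P
        # candidate starts whose window covers the seed position
        lo = np.searchsorted(starts, P - (m - k))
        hi = np.searchsorted(starts, P, side="right")
        sidx, owner = _expand_ranges(lo, hi)
        if len(sidx) == 0:
            continue
        S = starts[sidx]
        D = S + delta[owner]
        ok = (D >= 0) & (D <= lt - m)
        if source_chrom is not None and name == source_chrom:
            ok &= np.abs(D - S) >= m  # own-source overlap does not count
        sidx, S, D = sidx[ok], S[ok], D[ok]
        if len(S) == 0:
            continue
        # dedupe (candidate, window) pairs, then verify exactly in chunks
        key = sidx.astype(np.int64) * (lt + 1) + D
        _, first = np.unique(key, return_index=True)
        sidx, S, D = sidx[first], S[first], D[first]
        span = np.arange(m)
        for c0 in range(0, len(S), 100_000):
            s_chunk = slice(c0, c0 + 100_000)
            wc = C[S[s_chunk, None] + span]
            wt = T[D[s_chunk, None] + span]
            matches = ((wc == wt) & (wc != 4) & (wt != 4)).sum(axis=1)
            hit = matches >= need
            elim[sidx[s_chunk][hit]] = True
    return elim


def _heuristic_offsource_mask(
    chrom: MaskedSequence,
    starts: np.ndarray,
    genome: Sequence[MaskedSequence],
    index: KmerIndex,
    m: int,
    need: int,
    seed_mismatches: int,
) -> np.ndarray:
    """Batched seed-and-extend elimination flags for tiled candidates."""
    C = encode(chrom)
    lc = len(C)
    fwd = _heuristic_orientation_mask(
        C, starts, genome, index, m, need, seed_mismatches, source_chrom=chrom.name
    )
    # minus strand: search the reverse complement of the substrate; the
    # candidate at start s is the rc-frame window at lc - s - m
    rc = revcomp_codes(C)
    rc_starts = lc - starts - m
    order = np.argsort(rc_starts)
    rev = _heuristic_orientation_mask(
        rc, rc_starts[order], genome, index, m, need, seed_mismatches, source_chrom=None
    )
    back = np.empty(len(starts), dtype=bool)
    back[order] = rev
    return fwd | back


def uniqueness_filter(
    candidates: List[CandidateOligo],
    genome: Sequence[MaskedSequence],
    min_identity: float,
    exact: bool = False,
    index: Optional[KmerIndex] = None,
    seed_k: int = 9,
    seed_mismatches: int = 1,
) -> List[CandidateOligo]:
    """Retain candidates matching exactly one genomic locus (their source).

    The source locus counts toward the two-or-more tally, so any second
    locus at >= ``min_identity`` — other chromosome, other position, or a
    minus-strand (near-palindromic) self hit — eliminates the candidate.
    """
    if not candidates:
        return []
    by_name = {s.name: s for s in genome}

    # internal consistency: each candidate must equal its genome slice
    for cand in candidates:
        src = by_name.get(cand.interval.chrom)
        if src is None or src.residues[cand.start : cand.end] != cand.sequence:
            raise InternalConsistencyError(
                f"candidate {cand.interval} does not match the genome"
            )

    kept: List[CandidateOligo] = []
    if exact:
        need_cache: Dict[Tuple[str, int], np.ndarray] = {}
        for cand in candidates:
            m = len(cand.sequence)
            key = (cand.interval.chrom, m)
            if key not in need_cache:
                need = matches_required(min_identity, m)
                need_cache[key] = _exact_offsource_mask(
                    by_name[cand.interval.chrom], genome, m, need
                )
            if not need_cache[key][cand.start]:
                cand.stage_flags.add("unique")
                kept.append(cand)
        return kept

    if index is None:
        index = build_kmer_index(genome, seed_k)
    by_chrom: Dict[str, List[CandidateOligo]] = {}
    for cand in candidates:
        by_chrom.setdefault(cand.interval.chrom, []).append(cand)
    kept_set: set = set()
    for name, group in by_chrom.items():
        group.sort(key=lambda c: c.start)
        starts = np.array([c.start for c in group], dtype=np.int64)
        m = len(group[0].sequence)
        if any(len(c.sequence) != m for c in group):
            raise ValueError("mixed oligo lengths in one uniqueness batch")
        need = matches_required(min_identity, m)
        elim = _heuristic_offsource_mask(
            by_name[name], starts, genome, index, m, need, seed_mismatches
        )
        for cand, out in zip(group, elim):
            if not out:
                kept_set.add(id(cand))
    for cand in candidates:  # preserve input order
        if id(cand) in kept_set:
            cand.stage_flags.add("unique")
            kept.append(cand)
    return kept
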