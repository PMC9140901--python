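"""Word-seeded, gapless match detection between DNA strings.

This is the search engine behind both dispersed-repeat detection (a molecule
against itself) and cross-genome homology (mitogenome vs plastid, genome vs
genome).  It mirrors the sensitivity regime of a short-word nucleotide BLAST
search — 7-mer seeding by default — but replaces E-value significance with
deterministic (length, identity) filters: seeds sharing a diagonal are
chained, chains are extended gaplessly with an X-drop rule, and the extended
segment is kept when it is at least ``min_len`` long at ``min_identity`` or
better.  Extension is ungapped, like classic BLASTn HSPs; near-identical
organelle repeats and transfers are well within its reach.

All coordinates here are 0-based on the (possibly doubled) input strings;
callers normalise back onto circular molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WORD_SIZE = 7
MAX_SEED_GAP = 40
#: minimum chain span before extension; overlapping word hits make raw seed
#: counts useless as a chance filter, span is what separates signal
MIN_CHAIN_SPAN_EXTRA = 5
XDROP = 12

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


@dataclass(frozen=True)
class GaplessMatch:
    """An ungapped match: A[a_start:a_start+length] ~ B[b_start:b_start+length]."""

    a_start: int
    b_start: int
    length: int
    mismatches: int

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.length


def encode(seq: str) -> np.ndarray:
    """2-bit codes; anything outside ACGT becomes 4 (never matches)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_table(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    if len(codes) < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    pows = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    vals = win.astype(np.int64) @ pows
    valid = (win != 4).all(axis=1)
    pos = np.flatnonzero(valid).astype(np.int64)
    return pos, vals[pos]


def _match_pairs(
    codes_a: np.ndarray, codes_b: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) with A[i:i+k] == B[j:j+k], via a sort-merge join."""
    pa, va = _kmer_table(codes_a, k)
    pb, vb = _kmer_table(codes_b, k)
    if len(pa) == 0 or len(pb) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    sb = np.argsort(vb, kind="stable")
    vb_s, pb_s = vb[sb], pb[sb]
    left = np.searchsorted(vb_s, va, "left")
    right = np.searchsorted(vb_s, va, "right")
    cnt = right - left
    keep = cnt > 0
    pa, left, cnt = pa[keep], left[keep], cnt[keep]
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ia = np.repeat(pa, cnt)
    starts = np.repeat(left, cnt)
    offs = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    ib = pb_s[starts + offs]
    return ia, ib


def _chains(
    ia: np.ndarray, ib: np.ndarray, k: int, max_gap: int, min_span: int
) -> list[tuple[int, int, int]]:
    """Group co-diagonal seeds into chains -> (a_start, a_end, diagonal).

    Chains shorter than ``min_span`` are discarded: a genuine repeat of
    ``min_len`` bp at high identity always produces a long chain (its exact
    runs share a diagonal, and ``max_gap`` bridges isolated mismatches),
    while chance word hits rarely extend a chain past a few extra bases.
    """
    if len(ia) == 0:
        return []
    diag = ib - ia
    order = np.lexsort((ia, diag))
    a, d = ia[order], diag[order]
    brk = np.flatnonzero((np.diff(d) != 0) | (np.diff(a) > max_gap))
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk, [len(a) - 1]))
    keep = (a[ends] + k - a[starts]) >= min_span
    return [
        (int(a[s]), int(a[e]) + k, int(d[s]))
        for s, e in zip(starts[keep], ends[keep])
    ]


def _xdrop_extend(
    ca: np.ndarray, cb: np.ndarray, a_s: int, a_e: int, d: int, exact: bool
) -> tuple[int, int]:
    """Extend [a_s, a_e) gaplessly in both directions along diagonal d."""
    la, lb = len(ca), len(cb)
    # left
    i, score, best, best_i = a_s - 1, 0, 0, a_s
    while i >= 0 and i + d >= 0:
        eq = ca[i] == cb[i + d] and ca[i] != 4
        if eq:
            score += 1
            if score > best:
                best, best_i = score, i
        else:
            if exact:
                break
            score -= 3
            if best - score > XDROP:
                break
        i -= 1
    a_s = best_i
    # right
    i, score, best, best_e = a_e, 0, 0, a_e
    while i < la and i + d < lb:
        eq = ca[i] == cb[i + d] and ca[i] != 4
        if eq:
            score += 1
            if score > best:
                best, best_e = score, i + 1
        else:
            if exact:
                break
            score -= 3
            if best - score > XDROP:
                break
        i += 1
    return a_s, best_e


def _segments_from_candidate(
    ca: np.ndarray,
    cb: np.ndarray,
    a_s: int,
    a_e: int,
    d: int,
    min_len: int,
    min_identity: float,
) -> list[GaplessMatch]:
    """Trim/split an extended candidate into reportable segments."""
    mm = (ca[a_s:a_e] != cb[a_s + d : a_e + d]) | (ca[a_s:a_e] == 4)
    # trim mismatching ends
    nz = np.flatnonzero(~mm)
    if len(nz) == 0:
        return []
    a_s2 = a_s + int(nz[0])
    a_e2 = a_s + int(nz[-1]) + 1
    mm = mm[nz[0] : nz[-1] + 1]
    out: list[GaplessMatch] = []

    def emit(s: int, e: int, m: np.ndarray) -> None:
        length = e - s
        if length < min_len:
            return
        n_mm = int(m.sum())
        if 1.0 - n_mm / length >= min_identity:
            out.append(GaplessMatch(s, s + d, length, n_mm))
            return
        # greedy end-trim: peel the outermost mismatch nearest an edge
        pos = np.flatnonzero(m)
        lo, hi = 0, length
        while hi - lo >= min_len:
            inside = pos[(pos >= lo) & (pos < hi)]
            n_mm = len(inside)
            if n_mm == 0 or 1.0 - n_mm / (hi - lo) >= min_identity:
                if hi - lo >= min_len:
                    out.append(GaplessMatch(s + lo, s + lo + d, hi - lo, n_mm))
                return
            if inside[0] - lo <= hi - 1 - inside[-1]:
                lo = int(inside[0]) + 1
            else:
                hi = int(inside[-1])

    if min_identity >= 0.999:
        # report each maximal exact run separately
        pos = np.flatnonzero(mm)
        bounds = np.concatenate(([-1], pos, [len(mm)]))
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            s, e = int(b0) + 1, int(b1)
            if e - s >= min_len:
                out.append(GaplessMatch(a_s2 + s, a_s2 + s + d, e - s, 0))
    else:
        emit(a_s2, a_e2, mm)
    return out


def gapless_matches(
    seq_a: str,
    seq_b: str,
    min_len: int,
    min_identity: float,
    word: int = WORD_SIZE,
    max_gap: int = MAX_SEED_GAP,
    exclude_main_diagonal: bool = False,
    only_positive_diagonal: bool = False,
) -> list[GaplessMatch]:
    """Seed, chain, extend and filter; the core search routine.

    ``exclude_main_diagonal``/``only_positive_diagonal`` support
    self-comparison, where the trivial A==A hit and the mirror image of each
    pair must be suppressed.
    """
    ca, cb = encode(seq_a), encode(seq_b)
    ia, ib = _match_pairs(ca, cb, word)
    if exclude_main_diagonal or only_positive_diagonal:
        keep = (ib - ia) > 0 if only_positive_diagonal else (ib != ia)
        ia, ib = ia[keep], ib[keep]
    exact = min_identity >= 0.999
    min_span = min(min_len, word + MIN_CHAIN_SPAN_EXTRA)
    seen: set[tuple[int, int, int]] = set()
    results: list[GaplessMatch] = []
    for a_s, a_e, d in _chains(ia, ib, word, max_gap, min_span):
        if a_e - a_s < word:
            continue
        ea_s, ea_e = _xdrop_extend(ca, cb, a_s, a_e, d, exact)
        if ea_e - ea_s < min_len:
            continue
        for seg in _segments_from_candidate(ca, cb, ea_s, ea_e, d, min_len, min_identity):
            key = (seg.a_start, seg.b_start, seg.length)
            if key not in seen:
                seen.add(key)
                results.append(seg)
    return _drop_contained(results)


def _drop_contained(segs: list[GaplessMatch]) -> list[GaplessMatch]:
    """Remove segments contained in a longer co-diagonal segment."""
    by_diag: dict[int, list[GaplessMatch]] = {}
    for s in segs:
        by_diag.setdefault(s.b_start - s.a_start, []).append(s)
    out: list[GaplessMatch] = []
    for group in by_diag.values():
        group.sort(key=lambda s: (s.a_start, -s.length))
        best_end = -1
        for s in group:
            if s.a_start + s.length <= best_end:
                continue
            out.append(s)
            best_end = max(best_end, s.a_start + s.length)
    out.sort(key=lambda s: (s.a_start, s.b_start))
    return out
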