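"""Repeat detection on circular molecules: SSRs, tandem arrays, dispersed pairs.

Three repeat classes, three detectors:

* **SSRs** (microsatellites): maximal perfect runs of a primitive 1--6 bp
  motif, at MISA-style per-unit minimum copy numbers (10/5/4/3/3/3 for
  mono- through hexanucleotide units).
* **Tandem arrays**: longer-period tandem repetitions scored like Tandem
  Repeats Finder (+2 per matching base against the array's own consensus,
  -7 per mismatch, -7 per indel), reported at alignment score >= 50 and
  period <= 500.  Detection is substitution-aware but ungapped.
* **Dispersed repeat pairs**: near-identical copies at distant loci, direct
  or inverted — the substrate of repeat-mediated recombination.  Found by
  7-mer seeding and gapless extension with (length >= 100 bp, identity >=
  90 %) filters in place of a BLAST E-value cut-off.

Circularity is handled by scanning the doubled sequence and normalising
records back onto [0, L).  Internally everything is 0-based half-open;
writers emit 1-based inclusive TSV plus half-open BED.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circular import CircularSequence, revcomp
from .intervals import round_half_up
from .seedextend import GaplessMatch, encode, gapless_matches

#: MISA-style minimum copy numbers per motif length.
DEFAULT_SSR_MINIMA: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRRecord:
    motif: str  # canonical: lexicographic minimum over rotations
    unit_length: int
    copy_number: int
    start: int  # 0-based half-open [start, end)
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TandemRepeatRecord:
    period: int
    copy_number: float
    consensus: str
    score: int
    start: int
    end: int


@dataclass(frozen=True)
class RepeatPair:
    id: str
    length: int
    copy1: tuple[int, int]  # (start, end) 0-based; end may exceed L when wrapping
    copy2: tuple[int, int]
    orientation: str  # direct | inverted
    identity: float


# ---------------------------------------------------------------------------
# SSRs


def _canonical_motif(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    u = len(motif)
    return not any(u % p == 0 and motif == motif[:p] * (u // p) for p in range(1, u))


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index ranges."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_ssrs(
    seq: CircularSequence,
    minima: Mapping[int, int] | None = None,
) -> list[SSRRecord]:
    """Maximal perfect microsatellite runs at or above the copy minima.

    N runs never form SSRs; motifs that are themselves periodic (e.g. "ATAT"
    as a tetranucleotide) are reported only at their primitive unit length;
    records nested inside a longer record are suppressed.
    """
    minima = dict(DEFAULT_SSR_MINIMA if minima is None else minima)
    if set(minima) < set(range(1, 7)):
        raise ValueError("minima must cover unit lengths 1..6")
    L = len(seq)
    s = seq.sequence * 2 if seq.is_circular else seq.sequence
    codes = encode(s)
    valid = codes != 4
    records: list[SSRRecord] = []
    for u in range(1, 7):
        if len(codes) <= u:
            continue
        eq = (codes[:-u] == codes[u:]) & valid[:-u] & valid[u:]
        for rs, re_ in _bool_runs(eq):
            total = (re_ - rs) + u  # bases under perfect periodicity
            copies = total // u
            if copies < minima[u]:
                continue
            if seq.is_circular and rs >= L:
                continue  # duplicate image in the doubled sequence
            motif = s[rs : rs + u]
            if not _is_primitive(motif):
                continue
            end = rs + min(copies * u, L if seq.is_circular else copies * u)
            copies = (end - rs) // u
            if copies < minima[u]:
                continue
            records.append(
                SSRRecord(
                    motif=_canonical_motif(motif),
                    unit_length=u,
                    copy_number=copies,
                    start=rs,
                    end=rs + copies * u,
                )
            )
    # suppress records nested inside a longer one
    records.sort(key=lambda r: (-(r.length), r.start, r.unit_length))
    kept: list[SSRRecord] = []
    for r in records:
        if any(k.start <= r.start and r.end <= k.end and k is not r for k in kept):
            continue
        kept.append(r)
    kept.sort(key=lambda r: (r.start, r.unit_length))
    return kept


# ---------------------------------------------------------------------------
# tandem repeats


def _merged_runs(mask: np.ndarray, merge_gap: int, min_run: int) -> list[tuple[int, int]]:
    """True-runs of ``mask``, bridged across gaps <= merge_gap, kept if >= min_run.

    Fully vectorised: on a random sequence most periods yield thousands of
    short runs that must be filtered before any per-run Python work.
    """
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    if len(starts) == 0:
        return []
    ends = np.flatnonzero(d == -1)
    gaps = starts[1:] - ends[:-1]
    new_group = np.concatenate(([True], gaps > merge_gap))
    gstarts = starts[new_group]
    bounds = np.flatnonzero(new_group)
    last = np.concatenate((bounds[1:] - 1, [len(ends) - 1]))
    gends = ends[last]
    keep = (gends - gstarts) >= min_run
    return list(zip(gstarts[keep].tolist(), gends[keep].tolist()))


def _consensus_score(
    s: str, start: int, end: int, period: int, match: int, mismatch: int
) -> tuple[str, int, np.ndarray]:
    """Majority consensus of the array's columns, score, per-base scores."""
    arr = np.frombuffer(s[start:end].encode("ascii"), dtype=np.uint8)
    n = len(arr)
    cons = np.empty(period, dtype=np.uint8)
    for c in range(period):
        col = arr[c::period]
        vals, counts = np.unique(col, return_counts=True)
        cons[c] = vals[np.argmax(counts)]
    tiled = np.tile(cons, n // period + 1)[:n]
    per_base = np.where(arr == tiled, match, -mismatch)
    return cons.tobytes().decode("ascii"), int(per_base.sum()), per_base


def _best_window(per_base: np.ndarray) -> tuple[int, int]:
    """Maximum-scoring contiguous window (vectorised Kadane)."""
    cum = np.concatenate(([0], np.cumsum(per_base)))
    pre_min = np.minimum.accumulate(cum[:-1])
    gains = cum[1:] - pre_min
    j = int(np.argmax(gains)) + 1
    i = int(np.argmin(cum[:j]))
    return i, j


def _trimmed_array(
    s: str, start: int, end: int, period: int, match: int, mismatch: int
) -> tuple[int, int, str, int]:
    """Trim array edges to the maximum-scoring window; re-phase the consensus."""
    for _ in range(2):
        if end - start < period:
            return start, start, "", -1
        cons, score, per_base = _consensus_score(s, start, end, period, match, mismatch)
        i, j = _best_window(per_base)
        if (i, j) == (0, end - start):
            break
        start, end = start + i, start + j
    if end - start < period:
        return start, start, "", -1
    cons, score, _ = _consensus_score(s, start, end, period, match, mismatch)
    return start, end, cons, score


def find_tandem_repeats(
    seq: CircularSequence,
    match: int = 2,
    mismatch: int = 7,
    indel: int = 7,
    min_score: int = 50,
    max_period: int = 500,
) -> list[TandemRepeatRecord]:
    """Tandem arrays with >= 2 copies scoring >= ``min_score`` vs their consensus.

    Scoring follows the Tandem Repeats Finder convention (+match per
    matching base over the whole array, -mismatch per mismatching base,
    -indel per indel); this detector considers substitution-type
    imperfections only, so the indel penalty never applies to a reported
    array.  Arrays whose best period exceeds ``max_period`` are excluded.
    """
    if min(match, mismatch, indel) <= 0:
        raise ValueError("scoring parameters must be positive")
    L = len(seq)
    s = seq.sequence * 2 if seq.is_circular else seq.sequence
    codes = encode(s)
    valid = codes != 4
    candidates: list[TandemRepeatRecord] = []
    for p in range(1, min(max_period, len(s) - 1) + 1):
        eq = (codes[:-p] == codes[p:]) & valid[:-p] & valid[p:]
        for rs, re_ in _merged_runs(eq, merge_gap=5, min_run=p):
            total = (re_ - rs) + p
            if seq.is_circular and rs >= L:
                continue
            end = rs + min(total, L if seq.is_circular else total)
            rs, end, cons, score = _trimmed_array(s, rs, end, p, match, mismatch)
            if score < min_score or end - rs < 2 * p:
                continue
            candidates.append(
                TandemRepeatRecord(
                    period=p,
                    copy_number=round((end - rs) / p, 1),
                    consensus=cons,
                    score=score,
                    start=rs,
                    end=end,
                )
            )
    # prefer higher score, then smaller period, among heavily overlapping calls
    candidates.sort(key=lambda r: (-r.score, r.period, r.start))
    kept: list[TandemRepeatRecord] = []
    for r in candidates:
        span = r.end - r.start
        clash = False
        for k in kept:
            ov = min(r.end, k.end) - max(r.start, k.start)
            if ov > 0 and ov >= 0.5 * span:
                clash = True
                break
        if not clash:
            kept.append(r)
    kept.sort(key=lambda r: (r.start, r.period))
    return kept


# ---------------------------------------------------------------------------
# dispersed repeat pairs


def _circle_overlap(iv1: tuple[int, int], iv2: tuple[int, int], L: int) -> bool:
    from .intervals import wrap_intervals

    arcs1 = wrap_intervals([iv1], L)
    arcs2 = wrap_intervals([iv2], L)
    return any(s1 < e2 and s2 < e1 for s1, e1 in arcs1 for s2, e2 in arcs2)


def find_dispersed_repeats(
    seq: CircularSequence,
    min_len: int = 100,
    min_identity: float = 0.9,
    word: int = 7,
) -> list[RepeatPair]:
    """Direct and inverted dispersed repeat pairs >= ``min_len`` bp.

    Pairs are symmetric (copy1 precedes copy2 by start), maximal under
    gapless extension, and never overlap themselves on the circle (tandem
    arrays are the tandem detector's business).  Results are ordered by
    length descending then position, and named R1, R2, ... in that order —
    the recombination module consumes them directly.
    """
    L = len(seq)
    if L < min_len:
        raise ValueError(f"sequence shorter ({L}) than min_len ({min_len})")
    s = seq.sequence * 2 if seq.is_circular else seq.sequence
    found: dict[tuple, RepeatPair] = {}

    def add(a_start: int, b_start: int, length: int, ident: float, orientation: str) -> None:
        if length > L:
            return
        s1, s2 = a_start % L, b_start % L
        iv1, iv2 = (s1, s1 + length), (s2, s2 + length)
        if iv1 == iv2:
            return  # self image through doubling
        if seq.is_circular and _circle_overlap(iv1, iv2, L):
            return
        if not seq.is_circular and iv1[0] < iv2[1] and iv2[0] < iv1[1]:
            return
        if iv2 < iv1:
            iv1, iv2 = iv2, iv1
        key = (iv1, iv2, orientation)
        if key not in found:
            found[key] = RepeatPair("", length, iv1, iv2, orientation, ident)

    for m in gapless_matches(
        s, s, min_len, min_identity, word=word, only_positive_diagonal=True
    ):
        add(m.a_start, m.b_start, m.length, round_half_up(m.identity * 100), "direct")

    s_rc = revcomp(s)
    for m in gapless_matches(s, s_rc, min_len, min_identity, word=word):
        b_on_fwd = len(s) - m.b_start - m.length
        add(m.a_start, b_on_fwd, m.length, round_half_up(m.identity * 100), "inverted")

    def iv_within(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
        if seq.is_circular:
            off = (inner[0] - outer[0]) % L
            return off + (inner[1] - inner[0]) <= outer[1] - outer[0]
        return outer[0] <= inner[0] and inner[1] <= outer[1]

    def contained(p: RepeatPair, q: RepeatPair) -> bool:
        if p.orientation != q.orientation:
            return False
        return (iv_within(p.copy1, q.copy1) and iv_within(p.copy2, q.copy2)) or (
            iv_within(p.copy1, q.copy2) and iv_within(p.copy2, q.copy1)
        )

    pairs = sorted(found.values(), key=lambda r: (-r.length, r.copy1, r.copy2))
    maximal: list[RepeatPair] = []
    for p in pairs:
        # a wrapped repeat leaves fragment images on other diagonals of the
        # doubled sequence; only maximal pairs are reported
        if any(contained(p, q) for q in maximal):
            continue
        maximal.append(p)
    return [
        RepeatPair(f"R{i + 1}", p.length, p.copy1, p.copy2, p.orientation, p.identity)
        for i, p in enumerate(maximal)
    ]


# ---------------------------------------------------------------------------
# writers (TSV 1-based inclusive; BED 0-based half-open)


def ssrs_to_frame(records: Sequence[SSRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": r.motif,
                "unit_length": r.unit_length,
                "copy_number": r.copy_number,
                "start": r.start + 1,
                "end": r.end,
                "length": r.length,
            }
            for r in records
        ],
        columns=["motif", "unit_length", "copy_number", "start", "end", "length"],
    )


def tandems_to_frame(records: Sequence[TandemRepeatRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "period": r.period,
                "copy_number": r.copy_number,
                "consensus": r.consensus,
                "score": r.score,
                "start": r.start + 1,
                "end": r.end,
            }
            for r in records
        ],
        columns=["period", "copy_number", "consensus", "score", "start", "end"],
    )


def repeat_pairs_to_frame(records: Sequence[RepeatPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "length": r.length,
                "orientation": r.orientation,
                "copy1_start": r.copy1[0] + 1,
                "copy1_end": r.copy1[1],
                "copy2_start": r.copy2[0] + 1,
                "copy2_end": r.copy2[1],
                "identity": r.identity,
            }
            for r in records
        ],
        columns=[
            "id",
            "length",
            "orientation",
            "copy1_start",
            "copy1_end",
            "copy2_start",
            "copy2_end",
            "identity",
        ],
    )


def repeat_pairs_to_bed(records: Sequence[RepeatPair], chrom: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            for i, (s, e) in enumerate((r.copy1, r.copy2), start=1):
                strand = "+" if (r.orientation == "direct" or i == 1) else "-"
                fh.write(f"{chrom}\t{s}\t{e}\t{r.id}.copy{i}\t0\t{strand}\n")
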