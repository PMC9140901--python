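"""Repeat-mediated recombination: conformations, read support, multipartite model.

A pair of dispersed repeat copies on a circular mitogenome is a substrate
for homologous recombination.  Crossing over between **direct** copies
splits the master circle into two subgenomic circles (each keeping one
repeat copy); between **inverted** copies it inverts the intervening
segment, conserving molecule length.  Which arrangement a long read
supports is decided at the repeat's junctions: a read is informative only
if it spans a repeat copy with alignable sequence in both flanks, because
the flank pairing (which upstream flank meets which downstream flank across
the repeat) is the only thing that distinguishes the conformations.

The workflow is:

1. :func:`enumerate_conformations` — build junction reference sequences
   (repeat copy plus ``flank`` bp on each side, default 1000) for the
   master arrangement and for the recombinant arrangement, together with
   the explicit alternative molecules produced by string surgery.
2. :func:`classify_reads` / :func:`classify_read` — label each long read
   ``master`` / ``alternative`` / ``uninformative`` by anchored alignment
   across the junctions.
3. :func:`support_table` — per-repeat counts and percentage support.
4. :func:`infer_multipartite` — the set of circles implied by the
   recombinationally active repeats.

Classification requires ``anchor`` aligned bases (default 100) in *both*
flanks at ``min_identity`` (default 0.85) and consistency with only one
conformation's junctions; reads contained in the repeat, or touching one
flank only, or consistent with both conformations, are uninformative.
Fractions are computed over informative reads only and rounded half-up to
two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .circular import CircularSequence, revcomp
from .intervals import percent, wrap_intervals
from .repeats import RepeatPair

DEFAULT_FLANK = 1000
DEFAULT_ANCHOR = 100
DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_ACTIVITY_THRESHOLD = 20.0

MASTER = "master"
ALTERNATIVE = "alternative"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class ConformationSet:
    """Junction references and explicit molecules for one repeat pair."""

    repeat: RepeatPair
    flank: int
    conformation_id: str
    master_junctions: tuple[str, str]
    alt_junctions: tuple[str, str]
    alt_circles: tuple[CircularSequence, ...]
    subcircle_sizes: tuple[int, ...]
    #: master-circle intervals (0-based, end may exceed L for wrap) of the
    #: segments carried by each alternative circle, for the multipartite model
    segment_intervals: tuple[tuple[int, int], ...]
    repeat_sequence: str = ""


@dataclass(frozen=True)
class ReadSupportRecord:
    repeat_id: str
    n_master: int
    n_alt: int
    n_uninformative: int
    frac_master: float | None
    frac_alt: float | None


@dataclass(frozen=True)
class SubCircle:
    size: int
    segments: tuple[tuple[int, int], ...]
    repeat_copy: tuple[int, int]


@dataclass(frozen=True)
class MultipartiteModel:
    master_length: int
    active: tuple[tuple[str, float], ...]  # (repeat id, frac_alt)
    circles: dict[str, tuple[SubCircle, ...]]  # per active direct repeat
    inversions: tuple[str, ...]  # active inverted repeats (length-conserving)
    inactive: tuple[tuple[str, float | None], ...]
    ambiguous: bool  # active repeats interleave; pairwise products only

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "master_length": self.master_length,
            "active": [{"repeat": r, "frac_alt": f} for r, f in self.active],
            "circles": {
                rid: [
                    {
                        "size": c.size,
                        "segments": [[s + 1, e] for s, e in c.segments],
                        "repeat_copy": [c.repeat_copy[0] + 1, c.repeat_copy[1]],
                    }
                    for c in circles
                ]
                for rid, circles in self.circles.items()
            },
            "inversions": list(self.inversions),
            "inactive": [{"repeat": r, "frac_alt": f} for r, f in self.inactive],
            "ambiguous": self.ambiguous,
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _copies_overlap(pair: RepeatPair, L: int) -> bool:
    arcs1 = wrap_intervals([pair.copy1], L)
    arcs2 = wrap_intervals([pair.copy2], L)
    return any(s1 < e2 and s2 < e1 for s1, e1 in arcs1 for s2, e2 in arcs2)


def enumerate_conformations(
    genome: CircularSequence,
    pair: RepeatPair,
    flank: int = DEFAULT_FLANK,
) -> ConformationSet:
    """Master and recombinant junction references for one repeat pair.

    For a direct pair with copies at ``[a1, b1)`` and ``[a2, b2)`` on a
    circle of length ``L``, the alternative conformation is two subgenomic
    circles ``[a1, a2)`` and ``[a2, a1)`` (sizes summing to ``L``), each
    retaining one repeat copy; the recombinant junctions are the
    flank-exchange products (upstream of one copy joined, across the
    repeat, to downstream of the other).  For an inverted pair it is a
    single circle of length ``L`` with the inter-repeat segment
    reverse-complemented.  All junction references are extracted from the
    explicitly constructed conformation molecules, so they are exact
    substrings of those molecules by construction.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    L = len(genome)
    rlen = pair.length
    if _copies_overlap(pair, L):
        raise ValueError(
            f"repeat copies {pair.copy1} and {pair.copy2} overlap; "
            "recombinational exchange is not well defined"
        )
    a1, a2 = pair.copy1[0] % L, pair.copy2[0] % L
    b1, b2 = a1 + rlen, a2 + rlen
    f_master = min(flank, (L - rlen) // 2)
    jm1 = genome.fetch(a1 - f_master, rlen + 2 * f_master)
    jm2 = genome.fetch(a2 - f_master, rlen + 2 * f_master)
    repeat_seq = genome.fetch(a1, rlen)
    cid = f"alt_{pair.id}" if pair.id else "alt"

    if pair.orientation == "direct":
        size_a = (a2 - a1) % L
        size_b = L - size_a
        circ_a = CircularSequence(f"{cid}_circleA", genome.fetch(a1, size_a))
        circ_b = CircularSequence(f"{cid}_circleB", genome.fetch(a2, size_b))
        fa = min(flank, (size_a - rlen) // 2)
        fb = min(flank, (size_b - rlen) // 2)
        if fa < 1 or fb < 1:
            raise ValueError("subcircle too small to carry junction flanks")
        ja = circ_a.fetch(-fa, rlen + 2 * fa)  # up2 + repeat + down1
        jb = circ_b.fetch(-fb, rlen + 2 * fb)  # up1 + repeat + down2
        return ConformationSet(
            repeat=pair,
            flank=f_master,
            conformation_id=cid,
            master_junctions=(jm1, jm2),
            alt_junctions=(ja, jb),
            alt_circles=(circ_a, circ_b),
            subcircle_sizes=(size_a, size_b),
            segment_intervals=((a1, a1 + size_a), (a2, a2 + size_b)),
            repeat_sequence=repeat_seq,
        )

    # inverted: reverse-complement the block spanning copy1..copy2 inclusive;
    # both copies stay in place, the inter-repeat segment flips
    rotated = genome.rotate(a1)
    block_len = (b2 - a1) % L
    if block_len == 0:
        block_len = L
    alt_seq = revcomp(rotated.sequence[:block_len]) + rotated.sequence[block_len:]
    alt_mol = CircularSequence(f"{cid}_inverted", alt_seq)
    # repeat copies in alt_mol coordinates: [0, rlen) and [block_len - rlen, block_len)
    f_alt = f_master
    j1 = alt_mol.fetch(-f_alt, rlen + 2 * f_alt)
    j2 = alt_mol.fetch(block_len - rlen - f_alt, rlen + 2 * f_alt)
    return ConformationSet(
        repeat=pair,
        flank=f_master,
        conformation_id=cid,
        master_junctions=(jm1, jm2),
        alt_junctions=(j1, j2),
        alt_circles=(alt_mol,),
        subcircle_sizes=(L,),
        segment_intervals=((a1, a1 + L),),
        repeat_sequence=repeat_seq,
    )


# ---------------------------------------------------------------------------
# read classification


class EdlibBackend:
    """Default alignment primitive: banded Myers bit-vector edit alignment."""

    def locate(self, query: str, target: str, max_dist: int) -> tuple[int, list[tuple[int, int]]]:
        """Best infix alignment of query in target -> (distance, locations)."""
        res = edlib.align(query, target, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            return -1, []
        return res["editDistance"], [(s, e) for s, e in res["locations"] if s is not None]

    def distance(self, query: str, target: str, max_dist: int) -> int:
        res = edlib.align(query, target, mode="HW", task="distance", k=max_dist)
        return res["editDistance"]


@dataclass(frozen=True)
class _JunctionContext:
    up: str
    down: str
    label: str


class ReadClassifier:
    """Classify long reads against one repeat's conformations.

    A read is assigned to a conformation iff, around a located occurrence
    of the repeat, the ``anchor``-bp upstream and downstream flank anchors
    of exactly one conformation's junctions align at ``min_identity`` or
    better.  Anything else — repeat not fully contained, one flank short,
    flank pairing matching both conformations — is uninformative.
    """

    def __init__(
        self,
        confs: ConformationSet,
        anchor: int = DEFAULT_ANCHOR,
        min_identity: float = DEFAULT_MIN_IDENTITY,
        backend: EdlibBackend | None = None,
    ) -> None:
        if anchor > confs.flank:
            raise ValueError(f"anchor ({anchor}) must not exceed flank ({confs.flank})")
        if anchor < 1:
            raise ValueError("anchor must be >= 1")
        self.confs = confs
        self.anchor = anchor
        self.min_identity = min_identity
        self.backend = backend or EdlibBackend()
        self.repeat_seq = confs.repeat_sequence
        rlen = len(self.repeat_seq)
        mid = rlen // 2
        probe_half = min(125, mid)
        self.probe = self.repeat_seq[mid - probe_half : mid + probe_half]
        self.contexts: list[_JunctionContext] = []
        F = confs.flank
        for junctions, label in (
            (confs.master_junctions, MASTER),
            (confs.alt_junctions, ALTERNATIVE),
        ):
            for j in junctions:
                up = j[F - anchor : F]
                down = j[F + rlen : F + rlen + anchor]
                self.contexts.append(_JunctionContext(up, down, label))
                self.contexts.append(_JunctionContext(revcomp(down), revcomp(up), label))

    def _flank_ok(self, anchor_seq: str, window: str) -> bool:
        if len(window) < len(anchor_seq):
            return False
        max_dist = int(len(anchor_seq) * (1 - self.min_identity))
        d = self.backend.distance(anchor_seq, window, max_dist)
        return d >= 0

    def classify(self, read: str) -> str:
        if not read:
            return UNINFORMATIVE
        rlen = len(self.repeat_seq)
        pad = max(10, self.anchor // 4)
        probe_k = int(len(self.probe) * 0.35)
        repeat_k = max(probe_k, int(rlen * (1 - self.min_identity) * 1.5))
        labels: set[str] = set()
        for oriented in (read, revcomp(read)):
            if len(oriented) < rlen + 2 * self.anchor:
                continue
            if self.backend.distance(self.probe, oriented, probe_k) < 0:
                continue
            dist, locs = self.backend.locate(self.repeat_seq, oriented, repeat_k)
            if dist < 0:
                continue
            for s, e in locs[:4]:
                left = oriented[max(0, s - self.anchor - pad) : s]
                right = oriented[e + 1 : e + 1 + self.anchor + pad]
                if len(left) < self.anchor or len(right) < self.anchor:
                    continue
                for ctx in self.contexts:
                    if self._flank_ok(ctx.up, left) and self._flank_ok(ctx.down, right):
                        labels.add(ctx.label)
        if labels == {MASTER}:
            return MASTER
        if labels == {ALTERNATIVE}:
            return ALTERNATIVE
        return UNINFORMATIVE


def classify_read(
    read: str,
    confs: ConformationSet,
    anchor: int = DEFAULT_ANCHOR,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    backend: EdlibBackend | None = None,
) -> str:
    """Label one read ``master`` / ``alternative`` / ``uninformative``."""
    return ReadClassifier(confs, anchor, min_identity, backend).classify(read)


def classify_reads(
    reads: Iterable[str],
    confs: ConformationSet,
    anchor: int = DEFAULT_ANCHOR,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    backend: EdlibBackend | None = None,
) -> list[str]:
    clf = ReadClassifier(confs, anchor, min_identity, backend)
    return [clf.classify(r) for r in reads]


# ---------------------------------------------------------------------------
# support table


def tally_labels(labels: Sequence[str]) -> tuple[int, int, int]:
    n_m = sum(1 for l in labels if l == MASTER)
    n_a = sum(1 for l in labels if l == ALTERNATIVE)
    return n_m, n_a, len(labels) - n_m - n_a


def support_record(
    repeat_id: str, n_master: int, n_alt: int, n_uninformative: int = 0
) -> ReadSupportRecord:
    if min(n_master, n_alt, n_uninformative) < 0:
        raise ValueError("counts must be non-negative")
    total = n_master + n_alt
    if total == 0:
        return ReadSupportRecord(repeat_id, n_master, n_alt, n_uninformative, None, None)
    return ReadSupportRecord(
        repeat_id,
        n_master,
        n_alt,
        n_uninformative,
        percent(n_master, total),
        percent(n_alt, total),
    )


def support_table(
    labels_by_repeat: Mapping[str, Sequence[str]],
    repeats: Sequence[RepeatPair] | None = None,
) -> list[ReadSupportRecord]:
    """Per-repeat support records, ordered by repeat length descending.

    ``labels_by_repeat`` maps repeat id to per-read labels (or to an
    ``(n_master, n_alt, n_uninformative)`` tuple of pre-tallied counts).
    When ``repeats`` is omitted, input order is kept.
    """
    order = list(labels_by_repeat)
    lengths = {}
    if repeats is not None:
        lengths = {p.id: p.length for p in repeats}
        order.sort(key=lambda rid: (-lengths.get(rid, 0), rid))
    records = []
    for rid in order:
        val = labels_by_repeat[rid]
        if len(val) == 3 and all(isinstance(v, int) for v in val):
            n_m, n_a, n_u = val  # type: ignore[misc]
        else:
            n_m, n_a, n_u = tally_labels(val)
        records.append(support_record(rid, n_m, n_a, n_u))
    return records


def support_to_frame(records: Sequence[ReadSupportRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "repeat": r.repeat_id,
                "n_master": r.n_master,
                "n_alt": r.n_alt,
                "n_uninformative": r.n_uninformative,
                "frac_master_percent": "NA" if r.frac_master is None else f"{r.frac_master:.2f}",
                "frac_alt_percent": "NA" if r.frac_alt is None else f"{r.frac_alt:.2f}",
            }
            for r in records
        ],
        columns=[
            "repeat",
            "n_master",
            "n_alt",
            "n_uninformative",
            "frac_master_percent",
            "frac_alt_percent",
        ],
    )


# ---------------------------------------------------------------------------
# multipartite model


def _interleave(p: RepeatPair, q: RepeatPair, L: int) -> bool:
    """True when the copies of p and q alternate around the circle."""
    marks = sorted(
        [(p.copy1[0] % L, "p"), (p.copy2[0] % L, "p"), (q.copy1[0] % L, "q"), (q.copy2[0] % L, "q")]
    )
    order = "".join(m for _, m in marks)
    return order in ("pqpq", "qpqp")


def infer_multipartite(
    support: Sequence[ReadSupportRecord],
    genome: CircularSequence,
    pairs: Sequence[RepeatPair],
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> MultipartiteModel:
    """The set of circles implied by recombinationally active repeats.

    A repeat is active when its alternative-conformation support fraction
    meets ``activity_threshold`` (percent).  Each active *direct* repeat is
    modelled independently (pairwise surgery): it contributes the two
    subgenomic circles whose sizes sum to the master length.  Active
    *inverted* repeats conserve length and are listed as inversions.  When
    the copies of two active repeats interleave, simultaneous recombination
    would yield products the pairwise model cannot represent; the model
    flags the ambiguity rather than resolving it.
    """
    by_id = {p.id: p for p in pairs}
    missing = [r.repeat_id for r in support if r.repeat_id not in by_id]
    if missing:
        raise ValueError(f"support records without matching repeat pair: {missing}")
    L = len(genome)
    active: list[tuple[str, float]] = []
    inactive: list[tuple[str, float | None]] = []
    for rec in support:
        if rec.frac_alt is not None and rec.frac_alt >= activity_threshold:
            active.append((rec.repeat_id, rec.frac_alt))
        else:
            inactive.append((rec.repeat_id, rec.frac_alt))

    circles: dict[str, tuple[SubCircle, ...]] = {}
    inversions: list[str] = []
    for rid, _frac in active:
        pair = by_id[rid]
        if pair.orientation == "inverted":
            inversions.append(rid)
            continue
        cs = enumerate_conformations(genome, pair, flank=1)
        (seg_a, seg_b) = cs.segment_intervals
        circles[rid] = (
            SubCircle(cs.subcircle_sizes[0], (seg_a,), pair.copy1),
            SubCircle(cs.subcircle_sizes[1], (seg_b,), pair.copy2),
        )

    active_pairs = [by_id[rid] for rid, _ in active]
    ambiguous = any(
        _interleave(p, q, L)
        for i, p in enumerate(active_pairs)
        for q in active_pairs[i + 1 :]
    )
    return MultipartiteModel(
        master_length=L,
        active=tuple(active),
        circles=circles,
        inversions=tuple(inversions),
        inactive=tuple(inactive),
        ambiguous=ambiguous,
    )


def segments_to_gff3(model: MultipartiteModel, chrom: str, path: str | Path) -> None:
    """Subgenomic-circle segments as GFF3 intervals on the master circle."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid in sorted(model.circles):
            for ci, circ in enumerate(model.circles[rid]):
                for s, e in circ.segments:
                    L = model.master_length
                    pieces = wrap_intervals([(s, e)], L) if e > L else [(s, e)]
                    for ps, pe in pieces:
                        fh.write(
                            f"{chrom}\tmitoforms\tsubgenomic_segment\t{ps + 1}\t{pe}\t.\t+\t.\t"
                            f"ID={rid}.circle{'AB'[ci]};circle_size={circ.size}\n"
                        )
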