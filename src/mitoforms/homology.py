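"""Pairwise shared DNA between genomes, and plastid-to-mitochondrion transfers.

Plant mitogenomes diverge structurally so fast that even congeneric species
may share only a fraction of their sequence; the statistic reported here is
the *shared-DNA fraction*: the percentage of each genome covered by the
union of its homologous segments with the other genome.  The same segment
machinery, run mitogenome-vs-plastid, identifies MTPTs (mitochondrial
plastid sequences) — chloroplast DNA integrated into the mitochondrial
genome, typically 10^2--10^3 bp per fragment.

Matching uses the 7-mer seeded gapless engine with (length >= 100 bp,
identity >= 90 %) filters in place of a BLAST E-value threshold; the
divergence from BLAST is recorded in every output header this module
writes.  Coverage is computed on overlap-merged intervals, percentages
against each genome's own length, rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .circular import CircularSequence, revcomp
from .intervals import covered_length, merge_intervals, percent, wrap_intervals
from .seedextend import gapless_matches

FILTER_NOTE = "filters: length>=min_len AND identity>=min_identity (in place of BLAST e-value)"


@dataclass(frozen=True)
class HomologySegment:
    query: tuple[int, int]  # (start, end) 0-based on A; end may exceed len(A) if wrapping
    subject: tuple[int, int]  # on B
    strand: str  # "+" | "-"
    identity: float  # percent
    length: int


@dataclass(frozen=True)
class SharedDNASummary:
    genome_a: str
    genome_b: str
    covered_a: int
    percent_a: float
    covered_b: int
    percent_b: float


@dataclass(frozen=True)
class MTPTRecord:
    mito: tuple[int, int]
    plastid: tuple[int, int]
    length: int
    identity: float


def _doubled(seq: CircularSequence) -> str:
    return seq.sequence * 2 if seq.is_circular else seq.sequence


def pairwise_homology(
    a: CircularSequence,
    b: CircularSequence,
    min_len: int = 100,
    min_identity: float = 0.9,
    word: int = 7,
) -> list[HomologySegment]:
    """Maximal gapless homologous segments between two molecules, both strands."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both sequences must be non-empty")
    la, lb = len(a), len(b)
    sa, sb = _doubled(a), _doubled(b)
    max_len = min(la, lb)
    seen: set[tuple] = set()
    segments: list[HomologySegment] = []

    def add(qs: int, ss: int, length: int, mismatches: int, strand: str) -> None:
        if length > max_len:
            # cap a full-wrap match at one molecule length
            length = max_len
        q = (qs % la, qs % la + length)
        s = (ss % lb, ss % lb + length)
        key = (q, s, strand)
        if key in seen:
            return
        seen.add(key)
        ident = percent(length - mismatches, length)
        segments.append(HomologySegment(q, s, strand, ident, length))

    for m in gapless_matches(sa, sb, min_len, min_identity, word=word):
        add(m.a_start, m.b_start, m.length, m.mismatches, "+")
    sb_rc = revcomp(sb)
    for m in gapless_matches(sa, sb_rc, min_len, min_identity, word=word):
        ss = len(sb) - m.b_start - m.length
        add(m.a_start, ss, m.length, m.mismatches, "-")
    segments.sort(key=lambda s: (s.query, s.subject, s.strand))
    return segments


def shared_fraction(
    segments: Sequence[HomologySegment],
    a_length: int,
    b_length: int,
    genome_a: str = "A",
    genome_b: str = "B",
) -> SharedDNASummary:
    """Union coverage of the segments on each genome, as bp and percent."""
    if a_length <= 0 or b_length <= 0:
        raise ValueError("genome lengths must be positive")
    cov_a = covered_length(wrap_intervals([s.query for s in segments], a_length)) if segments else 0
    cov_b = covered_length(wrap_intervals([s.subject for s in segments], b_length)) if segments else 0
    return SharedDNASummary(
        genome_a,
        genome_b,
        cov_a,
        percent(cov_a, a_length),
        cov_b,
        percent(cov_b, b_length),
    )


def find_mtpts(
    mito: CircularSequence,
    plastid: CircularSequence,
    min_len: int = 100,
    min_identity: float = 0.9,
) -> tuple[list[MTPTRecord], int, float, float]:
    """Plastid-derived fragments in the mitogenome.

    Returns the per-fragment records plus the total merged MTPT length on
    the mitogenome and the percentages of the mitochondrial and plastid
    genomes covered (overlap-merged on each molecule).
    """
    segments = pairwise_homology(mito, plastid, min_len=min_len, min_identity=min_identity)
    records = [
        MTPTRecord(s.query, s.subject, s.length, s.identity) for s in segments
    ]
    summary = shared_fraction(segments, len(mito), len(plastid), mito.id, plastid.id)
    return records, summary.covered_a, summary.percent_a, summary.percent_b


# ---------------------------------------------------------------------------
# writers


def segments_to_frame(segments: Sequence[HomologySegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_start": s.query[0] + 1,
                "query_end": s.query[1],
                "subject_start": s.subject[0] + 1,
                "subject_end": s.subject[1],
                "strand": s.strand,
                "length": s.length,
                "identity": s.identity,
            }
            for s in segments
        ],
        columns=[
            "query_start",
            "query_end",
            "subject_start",
            "subject_end",
            "strand",
            "length",
            "identity",
        ],
    )


def merged_bed(
    segments: Sequence[HomologySegment], side: str, chrom: str, length: int, path: str | Path
) -> None:
    ivs = [getattr(s, side) for s in segments]
    merged = merge_intervals(wrap_intervals(ivs, length)) if ivs else []
    with open(path, "w") as fh:
        fh.write(f"# {FILTER_NOTE}\n")
        for s, e in merged:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def link_table(
    segments: Sequence[HomologySegment], mol_a: str, mol_b: str, path: str | Path
) -> None:
    """Circos-style link table: molA start end molB start end (1-based)."""
    with open(path, "w") as fh:
        fh.write(f"# {FILTER_NOTE}\n")
        for s in segments:
            fh.write(
                f"{mol_a}\t{s.query[0] + 1}\t{s.query[1]}\t"
                f"{mol_b}\t{s.subject[0] + 1}\t{s.subject[1]}\n"
            )
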