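"""Descriptive genome statistics from sequence plus annotation.

Computes the summary a mitogenome paper's first results table reports:
molecule length, GC content, gene counts by feature type, coding and
RNA-gene base totals with genome fractions, intron counts, and a
functional-class table (respiratory complexes, cytochrome-c biogenesis,
ribosomal proteins, ...).

Definitions used here (and stated in every report):

* GC% = 100 * (G+C)/(A+C+G+T); ambiguous bases are excluded from the
  denominator; an all-N sequence has undefined GC.
* coding_bp is the length of the *union* of CDS intervals, so overlapping
  or dual-annotated genes are never double-counted and fractions cannot
  exceed 100 %.
* intron count = sum over genes of (exons - 1).

Annotation is read from GenBank flat files (Biopython) or GFF3 (gffutils);
the two routes yield identical statistics for equivalent annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .circular import CircularSequence
from .intervals import covered_length, percent

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES: list[tuple[str, str]] = [
    ("nad", "Complex I (NADH dehydrogenase)"),
    ("sdh", "Complex II (succinate dehydrogenase)"),
    ("cob", "Complex III (ubiquinol cytochrome c reductase)"),
    ("cox", "Complex IV (cytochrome c oxidase)"),
    ("atp", "Complex V (ATP synthase)"),
    ("ccm", "Cytochrome c biogenesis"),
    ("mttb", "SecY-independent transporter"),
    ("rps", "Ribosomal protein small subunit"),
    ("rpl", "Ribosomal protein large subunit"),
    ("matr", "Intron maturase"),
    ("rrn", "Ribosomal RNAs"),
    ("trn", "Transfer RNAs"),
]


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    feature_type: str  # CDS | tRNA | rRNA
    strand: str  # + | -
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, non-overlapping
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.feature_type not in ("CDS", "tRNA", "rRNA"):
            raise ValueError(f"unsupported feature type {self.feature_type!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple(sorted(self.exons))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}: {exons}")
        object.__setattr__(self, "exons", exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def functional_class(self) -> str:
        name = self.gene_id.lower()
        for prefix, cls in FUNCTIONAL_CLASSES:
            if name.startswith(prefix):
                return cls
        return "Other"


@dataclass(frozen=True)
class GenomeStats:
    length: int
    gc_percent: float | None
    n_protein_coding: int
    n_trna: int
    n_rrna: int
    coding_bp: int
    coding_percent: float
    noncoding_rna_bp: int
    noncoding_rna_percent: float
    genes_with_introns: tuple[str, ...]
    intron_count: int


def gc_content(seq: CircularSequence | str) -> float | None:
    """GC percentage (2 decimals); ``None`` when no unambiguous base exists."""
    s = seq.sequence if isinstance(seq, CircularSequence) else seq.upper()
    if not s:
        raise ValueError("empty sequence")
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        return None
    return percent(gc, denom)


# ---------------------------------------------------------------------------
# annotation parsing


def parse_genbank(path: str | Path) -> list[AnnotationRecord]:
    """CDS/tRNA/rRNA features of a GenBank flat file, exons from location parts."""
    from Bio import SeqIO

    records: list[AnnotationRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type not in ("CDS", "tRNA", "rRNA"):
                continue
            gene = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
            strand = "-" if feat.location.strand == -1 else "+"
            exons = tuple(
                (int(part.start), int(part.end)) for part in feat.location.parts
            )
            records.append(
                AnnotationRecord(
                    gene_id=gene,
                    feature_type=feat.type,
                    strand=strand,
                    exons=exons,
                    pseudo="pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers,
                )
            )
    return records


def parse_gff3(path: str | Path) -> list[AnnotationRecord]:
    """CDS/tRNA/rRNA features of a GFF3 file, grouped into genes by gene/Parent/ID."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    grouped: dict[tuple[str, str], dict] = {}
    for ftype in ("CDS", "tRNA", "rRNA"):
        for feat in db.features_of_type(ftype):
            attrs = feat.attributes
            gene = (
                attrs.get("gene", [None])[0]
                or attrs.get("Parent", [None])[0]
                or attrs.get("ID", ["?"])[0]
            )
            key = (gene, ftype)
            g = grouped.setdefault(
                key,
                {"strand": feat.strand if feat.strand in "+-" else "+", "exons": [],
                 "pseudo": "pseudo" in attrs or "pseudogene" in attrs},
            )
            g["exons"].append((feat.start - 1, feat.end))  # GFF3 is 1-based inclusive
    return [
        AnnotationRecord(
            gene_id=gene,
            feature_type=ftype,
            strand=g["strand"],
            exons=tuple(g["exons"]),
            pseudo=g["pseudo"],
        )
        for (gene, ftype), g in sorted(grouped.items())
    ]


def read_annotation(path: str | Path) -> list[AnnotationRecord]:
    text = Path(path).read_text()
    if text.startswith("LOCUS") or "\nFEATURES" in text[:2000]:
        return parse_genbank(path)
    return parse_gff3(path)


# ---------------------------------------------------------------------------
# summary


def summarize_annotation(
    records: Iterable[AnnotationRecord],
    genome: CircularSequence,
) -> tuple[GenomeStats, pd.DataFrame]:
    """Genome statistics plus a functional-class table.

    Records with any exon outside the genome are rejected and logged.
    ``coding_bp`` counts the union of CDS intervals; RNA-gene bp the union
    of tRNA/rRNA intervals.
    """
    L = len(genome)
    valid: list[AnnotationRecord] = []
    for r in records:
        if any(s < 0 or e > L for s, e in r.exons):
            logger.warning("annotation %s rejected: exons %s outside genome of %d bp",
                           r.gene_id, r.exons, L)
            continue
        valid.append(r)

    cds = [r for r in valid if r.feature_type == "CDS"]
    trna = [r for r in valid if r.feature_type == "tRNA"]
    rrna = [r for r in valid if r.feature_type == "rRNA"]
    coding_bp = covered_length([iv for r in cds for iv in r.exons])
    rna_bp = covered_length([iv for r in trna + rrna for iv in r.exons])
    multi = sorted({r.gene_id for r in valid if r.n_exons > 1})
    introns = sum(r.n_exons - 1 for r in valid)
    stats = GenomeStats(
        length=L,
        gc_percent=gc_content(genome),
        n_protein_coding=len({r.gene_id for r in cds}),
        n_trna=len(trna),
        n_rrna=len(rrna),
        coding_bp=coding_bp,
        coding_percent=percent(coding_bp, L),
        noncoding_rna_bp=rna_bp,
        noncoding_rna_percent=percent(rna_bp, L),
        genes_with_introns=tuple(multi),
        intron_count=introns,
    )

    rows = []
    classes = [cls for _, cls in FUNCTIONAL_CLASSES] + ["Other"]
    by_class: dict[str, list[AnnotationRecord]] = {c: [] for c in classes}
    for r in valid:
        by_class[r.functional_class].append(r)
    for cls in classes:
        members = by_class[cls]
        if not members:
            continue
        names = sorted(
            {r.gene_id + ("*" if r.pseudo else "") + ("#" if r.n_exons > 2 else "")
             for r in members}
        )
        rows.append({"functional_class": cls, "n_genes": len({r.gene_id for r in members}),
                     "genes": ", ".join(names)})
    table = pd.DataFrame(rows, columns=["functional_class", "n_genes", "genes"])
    return stats, table


def stats_to_frame(stats: GenomeStats) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "length_bp": stats.length,
                "gc_percent": "NA" if stats.gc_percent is None else stats.gc_percent,
                "n_protein_coding": stats.n_protein_coding,
                "n_trna": stats.n_trna,
                "n_rrna": stats.n_rrna,
                "coding_bp": stats.coding_bp,
                "coding_percent": stats.coding_percent,
                "noncoding_rna_bp": stats.noncoding_rna_bp,
                "noncoding_rna_percent": stats.noncoding_rna_percent,
                "intron_count": stats.intron_count,
                "genes_with_introns": ",".join(stats.genes_with_introns),
            }
        ]
    )
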