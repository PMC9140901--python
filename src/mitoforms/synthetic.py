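"""Synthetic circular mitogenomes with planted structure, and simulated long reads.

The generator emulates the situation the rest of the package analyses: a
circular mitochondrial master molecule of 10^5--4x10^5 bp carrying pairs of
near-identical dispersed repeats (direct or inverted), segments of plastid
origin shared verbatim with a companion plastid molecule, and a pool of
Nanopore-like long reads drawn from a stated mixture of the master circle
and its recombination products.  Every planted feature is echoed in a truth
table so downstream detectors can be scored against ground truth.

Background composition is i.i.d. with a specified GC fraction.  Read lengths
are log-normal (ultralong-library scale by default: reads must span
multi-kilobase repeats plus flanks to be informative at all); errors are
i.i.d. substitutions and single-base indels.  One integer seed per spec
makes all outputs byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .circular import CircularSequence, write_fasta
from .intervals import wrap_intervals

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default read-length distribution: log-normal with median 50 kb.  An
#: ultralong Nanopore library is the appropriate design when the goal is to
#: span repeats of several kb with anchoring flanks on both sides; at this
#: scale a few hundred of every thousand reads are informative for a 5 kb
#: repeat on a 200 kb circle.
DEFAULT_LENGTH_DISTRIBUTION = (math.log(50_000.0), 0.5)

MIN_READ_LENGTH = 200


@dataclass(frozen=True)
class RepeatPlant:
    """A pair of planted repeat copies: (length, start1, start2, orientation)."""

    length: int
    start1: int
    start2: int
    orientation: str = "direct"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("repeat plant length must be positive")
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"orientation must be direct|inverted, got {self.orientation!r}")


@dataclass(frozen=True)
class MtptPlant:
    """A planted plastid-derived segment: (length, mito_start)."""

    length: int
    mito_start: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("MTPT plant length must be positive")


@dataclass(frozen=True)
class SimGenomeSpec:
    genome_length: int
    repeat_plants: tuple[RepeatPlant, ...] = ()
    mtpt_plants: tuple[MtptPlant, ...] = ()
    plastid_length: int = 154_000
    gc: float = 0.4554
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.plastid_length <= 0:
            raise ValueError("molecule lengths must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("GC fraction must lie in [0, 1]")
        object.__setattr__(self, "repeat_plants", tuple(self.repeat_plants))
        object.__setattr__(self, "mtpt_plants", tuple(self.mtpt_plants))


@dataclass(frozen=True)
class ReadSimSpec:
    conformation_weights: dict[str, float]
    n_reads: int
    length_distribution: tuple[float, float] = DEFAULT_LENGTH_DISTRIBUTION
    substitution_rate: float = 0.03
    insertion_rate: float = 0.01
    deletion_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        total = sum(self.conformation_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"conformation weights must sum to 1, got {total}")
        for name, rate in (
            ("substitution_rate", self.substitution_rate),
            ("insertion_rate", self.insertion_rate),
            ("deletion_rate", self.deletion_rate),
        ):
            if not 0.0 <= rate <= 0.2:
                raise ValueError(f"{name} must lie in [0, 0.2]")


@dataclass(frozen=True)
class PlantRecord:
    """Ground-truth record of one planted feature (0-based half-open starts)."""

    kind: str  # "repeat" | "mtpt"
    name: str
    length: int
    mito_start: int
    mito_start2: int | None = None  # second repeat copy
    orientation: str | None = None
    plastid_start: int | None = None


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    sequence: str
    true_conformation: str
    true_origin: tuple[str, int, str]  # (molecule id, start, strand)
    wrapped: bool = False


def _circle_arcs(start: int, length: int, L: int) -> list[tuple[int, int]]:
    return wrap_intervals([(start, start + length)], L)


def _check_no_overlap(spec: SimGenomeSpec) -> None:
    named: list[tuple[str, int, int]] = []
    L = spec.genome_length
    for i, rp in enumerate(spec.repeat_plants):
        for j, start in enumerate((rp.start1, rp.start2)):
            for s, e in _circle_arcs(start % L, rp.length, L):
                named.append((f"repeat{i + 1}.copy{j + 1}", s, e))
    for i, mp in enumerate(spec.mtpt_plants):
        for s, e in _circle_arcs(mp.mito_start % L, mp.length, L):
            named.append((f"mtpt{i + 1}", s, e))
    named.sort(key=lambda t: (t[1], t[2]))
    for (na, sa, ea), (nb, sb, eb) in zip(named, named[1:]):
        if sb < ea and na.split(".")[0] != nb.split(".")[0]:
            raise ValueError(
                f"planted intervals collide: {na} [{sa},{ea}) overlaps {nb} [{sb},{eb})"
            )
        if sb < ea and na.split(".")[0] == nb.split(".")[0]:
            raise ValueError(
                f"planted repeat copies overlap each other: {na} [{sa},{ea}) and {nb} [{sb},{eb})"
            )


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _positions(start: int, length: int, L: int) -> np.ndarray:
    return (np.arange(start, start + length) % L).astype(np.intp)


def build_genome(
    spec: SimGenomeSpec,
) -> tuple[CircularSequence, CircularSequence, list[PlantRecord]]:
    """Construct the mito and plastid molecules and the truth table.

    Repeat copy 2 is overwritten with copy 1's sequence (reverse complement
    for inverted plants), so planted identity is exact by construction.
    Each MTPT plant is copied verbatim from the mito molecule into the
    plastid molecule at an rng-chosen, non-overlapping plastid locus.
    """
    _check_no_overlap(spec)
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    mito = _random_codes(rng, L, spec.gc)
    plastid = _random_codes(rng, spec.plastid_length, spec.gc)

    truth: list[PlantRecord] = []
    for i, rp in enumerate(spec.repeat_plants):
        idx1 = _positions(rp.start1 % L, rp.length, L)
        idx2 = _positions(rp.start2 % L, rp.length, L)
        copy1 = mito[idx1]
        if rp.orientation == "direct":
            mito[idx2] = copy1
        else:
            mito[idx2] = (3 - copy1)[::-1]  # 2-bit complement is 3 - code
        truth.append(
            PlantRecord(
                kind="repeat",
                name=f"R{i + 1}",
                length=rp.length,
                mito_start=rp.start1 % L,
                mito_start2=rp.start2 % L,
                orientation=rp.orientation,
            )
        )

    # place MTPT segments on the plastid without overlap, deterministically
    taken: list[tuple[int, int]] = []
    for i, mp in enumerate(spec.mtpt_plants):
        idx_m = _positions(mp.mito_start % L, mp.length, L)
        for _ in range(1000):
            ps = int(rng.integers(0, spec.plastid_length - mp.length))
            if all(ps >= e or ps + mp.length <= s for s, e in taken):
                break
        else:
            raise ValueError("could not place MTPT plant on plastid without overlap")
        taken.append((ps, ps + mp.length))
        plastid[ps : ps + mp.length] = mito[idx_m]
        truth.append(
            PlantRecord(
                kind="mtpt",
                name=f"MTPT{i + 1}",
                length=mp.length,
                mito_start=mp.mito_start % L,
                plastid_start=ps,
            )
        )

    mito_seq = CircularSequence("mito_sim", _codes_to_str(mito))
    plastid_seq = CircularSequence("plastid_sim", _codes_to_str(plastid))
    return mito_seq, plastid_seq, truth


def _apply_errors(
    seq: str,
    rng: np.random.Generator,
    sub: float,
    ins: float,
    dele: float,
) -> str:
    """i.i.d. substitutions and single-base indels, vectorised."""
    if sub == ins == dele == 0.0:
        return seq
    code = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
    code = lut[code]
    n = len(code)
    if sub > 0:
        mask = rng.random(n) < sub
        k = int(mask.sum())
        if k:
            code[mask] = (code[mask] + rng.integers(1, 4, size=k)) % 4
    counts = np.ones(n, dtype=np.intp)
    if dele > 0:
        counts[rng.random(n) < dele] = 0
    ins_mask = np.zeros(n, dtype=bool)
    if ins > 0:
        ins_mask = rng.random(n) < ins
        counts[ins_mask] += 1
    out = np.repeat(code, counts)
    if ins_mask.any():
        cum = np.cumsum(counts)
        # inserted base sits immediately before the (possibly kept) original
        idx = cum[ins_mask] - counts[ins_mask]
        idx = idx[idx < len(out)]
        out[idx] = rng.integers(0, 4, size=len(idx))
    if len(out) == 0:
        out = rng.integers(0, 4, size=1).astype(np.uint8)
    return _codes_to_str(out.astype(np.uint8))


def simulate_reads(
    genome: CircularSequence,
    conformations: Sequence["object"],
    spec: ReadSimSpec,
) -> list[SimulatedRead]:
    """Draw long reads from a mixture of genome conformations.

    ``conformations`` is a sequence of :class:`~mitoforms.recombination.ConformationSet`
    objects (only their ``conformation_id`` and ``alt_circles`` are used);
    the id ``"master"`` always refers to ``genome`` itself.  Read origins are
    uniform on the chosen conformation's molecules (weighted by molecule
    length when a conformation comprises several circles), with circular
    wraparound; reads longer than their molecule are truncated to one full
    wrap and flagged.
    """
    molecules: dict[str, list[CircularSequence]] = {"master": [genome]}
    for cs in conformations:
        molecules[cs.conformation_id] = list(cs.alt_circles)
    for cid in spec.conformation_weights:
        if cid not in molecules:
            raise ValueError(f"conformation {cid!r} has no realizable molecule")

    rng = np.random.default_rng(spec.seed)
    conf_ids = sorted(spec.conformation_weights)
    weights = np.array([spec.conformation_weights[c] for c in conf_ids], dtype=float)
    weights = weights / weights.sum()
    mu, sigma = spec.length_distribution

    reads: list[SimulatedRead] = []
    for i in range(spec.n_reads):
        cid = conf_ids[int(rng.choice(len(conf_ids), p=weights))]
        mols = molecules[cid]
        lens = np.array([len(m) for m in mols], dtype=float)
        mol = mols[int(rng.choice(len(mols), p=lens / lens.sum()))]
        raw_len = int(round(float(rng.lognormal(mu, sigma))))
        length = max(MIN_READ_LENGTH, raw_len)
        wrapped = False
        if length > len(mol):
            length = len(mol)
            wrapped = True
        start = int(rng.integers(0, len(mol)))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = mol.fetch(start, length)
        if strand == "-":
            from .circular import revcomp

            frag = revcomp(frag)
        seq = _apply_errors(
            frag, rng, spec.substitution_rate, spec.insertion_rate, spec.deletion_rate
        )
        reads.append(
            SimulatedRead(
                id=f"read_{i:06d}",
                sequence=seq,
                true_conformation=cid,
                true_origin=(mol.id, start, strand),
                wrapped=wrapped,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# plain-text outputs


def write_truth_tsv(truth: Sequence[PlantRecord], path: str | Path) -> None:
    """Truth table with 1-based inclusive coordinates."""
    import pandas as pd

    rows = []
    for t in truth:
        rows.append(
            {
                "kind": t.kind,
                "name": t.name,
                "length": t.length,
                "mito_start": t.mito_start + 1,
                "mito_end": t.mito_start + t.length,
                "mito_start2": "" if t.mito_start2 is None else t.mito_start2 + 1,
                "mito_end2": "" if t.mito_start2 is None else t.mito_start2 + t.length,
                "orientation": t.orientation or "",
                "plastid_start": "" if t.plastid_start is None else t.plastid_start + 1,
                "plastid_end": "" if t.plastid_start is None else t.plastid_start + t.length,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_reads_fasta(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            mol, start, strand = r.true_origin
            fh.write(
                f">{r.id} conformation={r.true_conformation} origin={mol}:{start + 1}:{strand}"
                f"{' wrapped' if r.wrapped else ''}\n"
            )
            for off in range(0, len(r.sequence), 80):
                fh.write(r.sequence[off : off + 80] + "\n")


def write_spec_echo(spec: SimGenomeSpec, read_spec: ReadSimSpec | None, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# synthetic genome spec (seed {spec.seed})\n{spec!r}\n")
        if read_spec is not None:
            fh.write(f"# read simulation spec (seed {read_spec.seed})\n{read_spec!r}\n")
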