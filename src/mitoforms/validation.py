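"""Self-validation experiments on fully synthetic ground truth.

The central quantitative claim of the read-classification machinery is that
the alternative-conformation support fraction estimates the true mixture
proportion of conformations in the read pool.  `mixture_recovery_experiment`
measures exactly that: plant one direct repeat on a circle, simulate reads
from a known master/alternative mixture, classify, and compare the
estimated fraction with the planted weight.

The repeat pair is taken from the planted coordinates: this experiment
isolates classification recovery (detection has its own oracle-equivalence
checks and is exercised end-to-end by the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .recombination import ReadClassifier, enumerate_conformations, tally_labels
from .repeats import RepeatPair
from .synthetic import ReadSimSpec, RepeatPlant, SimGenomeSpec, build_genome, simulate_reads


@dataclass(frozen=True)
class RecoveryReplicate:
    weight: float  # planted alternative-conformation proportion
    estimate: float | None  # estimated alternative fraction, percent
    n_informative: int


def _derived_seed(base: int, *parts: int) -> int:
    ss = np.random.SeedSequence([base, *parts])
    return int(ss.generate_state(1)[0] % (2**31))


def mixture_recovery_experiment(
    weights: Sequence[float] = (0.05, 0.25, 0.5),
    n_replicates: int = 20,
    n_reads: int = 1000,
    genome_length: int = 200_000,
    repeat_length: int = 5_000,
    repeat_starts: tuple[int, int] = (10_000, 105_000),
    substitution_rate: float = 0.03,
    insertion_rate: float = 0.01,
    deletion_rate: float = 0.01,
    seed: int = 0,
    anchor: int = 100,
    min_identity: float = 0.85,
    flank: int = 1000,
) -> list[RecoveryReplicate]:
    """Estimate alternative-conformation fractions over seeded replicates.

    Each replicate builds a fresh genome (one planted direct repeat),
    simulates ``n_reads`` from the mixture ``{master: 1-w, alternative: w}``
    with the given error rates, classifies every read, and records the
    estimated alternative percentage over informative reads.
    """
    out: list[RecoveryReplicate] = []
    s1, s2 = repeat_starts
    for w in weights:
        for rep in range(n_replicates):
            gseed = _derived_seed(seed, int(round(w * 1000)), rep, 0)
            rseed = _derived_seed(seed, int(round(w * 1000)), rep, 1)
            spec = SimGenomeSpec(
                genome_length=genome_length,
                repeat_plants=(RepeatPlant(repeat_length, s1, s2, "direct"),),
                seed=gseed,
            )
            genome, _, _ = build_genome(spec)
            pair = RepeatPair(
                "R1", repeat_length, (s1, s1 + repeat_length), (s2, s2 + repeat_length),
                "direct", 100.0,
            )
            confs = enumerate_conformations(genome, pair, flank=flank)
            read_spec = ReadSimSpec(
                conformation_weights={"master": 1.0 - w, confs.conformation_id: w},
                n_reads=n_reads,
                substitution_rate=substitution_rate,
                insertion_rate=insertion_rate,
                deletion_rate=deletion_rate,
                seed=rseed,
            )
            reads = simulate_reads(genome, [confs], read_spec)
            clf = ReadClassifier(confs, anchor=anchor, min_identity=min_identity)
            n_m, n_a, _ = tally_labels([clf.classify(r.sequence) for r in reads])
            if n_m + n_a == 0:
                out.append(RecoveryReplicate(w, None, 0))
            else:
                out.append(RecoveryReplicate(w, 100.0 * n_a / (n_m + n_a), n_m + n_a))
    return out


def recovery_summary(
    replicates: Sequence[RecoveryReplicate], tolerance_points: float = 5.0
) -> dict[float, dict[str, float]]:
    """Per-weight fraction of replicates within ``tolerance_points`` of truth."""
    by_w: dict[float, list[RecoveryReplicate]] = {}
    for r in replicates:
        by_w.setdefault(r.weight, []).append(r)
    summary = {}
    for w, reps in sorted(by_w.items()):
        errs = [abs(r.estimate - 100.0 * w) for r in reps if r.estimate is not None]
        n_ok = sum(1 for e in errs if e <= tolerance_points)
        summary[w] = {
            "n_replicates": float(len(reps)),
            "fraction_within_tolerance": n_ok / len(reps) if reps else 0.0,
            "max_abs_error_points": max(errs) if errs else float("nan"),
            "mean_n_informative": float(np.mean([r.n_informative for r in reps])),
        }
    return summary
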