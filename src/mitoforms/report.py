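"""End-to-end pipeline driver and Markdown report rendering.

``run_pipeline`` takes a single YAML-style configuration (or an equivalent
dict), builds or loads the input molecules, and runs every stage in order:

    genome build -> repeat scan (SSR / tandem / dispersed) ->
    conformations -> read simulation -> read classification ->
    support table -> multipartite model -> homology & MTPT -> stats ->
    report.md

All stage outputs are plain text (FASTA / TSV / BED / GFF3 / JSON) with
stable ordering and fixed rounding, so a fixed seed reproduces every file
byte for byte.  Per-stage wall-clock timings go to the logger only, never
into output files.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import homology as hom
from . import recombination as rec
from . import repeats as rep
from . import stats as st
from . import synthetic as syn
from .circular import CircularSequence, read_fasta, write_fasta

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "genome": {
        "length": 150_000,
        "gc": 0.4554,
        "plastid_length": 120_000,
        "repeats": [
            {"length": 4000, "start1": 5000, "start2": 70_000, "orientation": "direct"},
            {"length": 300, "start1": 20_000, "start2": 110_000, "orientation": "direct"},
        ],
        "mtpts": [
            {"length": 115, "mito_start": 40_000},
            {"length": 500, "mito_start": 95_000},
            {"length": 887, "mito_start": 130_000},
        ],
    },
    "reads": {
        "n_reads": 300,
        "weights": {"master": 0.5, "alt_R1": 0.5},
        "substitution_rate": 0.03,
        "insertion_rate": 0.01,
        "deletion_rate": 0.01,
    },
    "repeat_scan": {"min_len": 100, "min_identity": 0.9},
    "classify": {"flank": 1000, "anchor": 100, "min_identity": 0.85},
    "multipartite": {"activity_threshold": 20.0},
}


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _merged(user: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (user or {}).items():
        if isinstance(v, Mapping) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, *exc):
        logger.info("stage %s: %.2f s", self.name, time.perf_counter() - self.t0)
        return False


def run_pipeline(
    config: Mapping[str, Any] | str | Path | None,
    outdir: str | Path,
) -> dict[str, Any]:
    """Run every stage on a synthetic fixture; returns in-memory results.

    ``config`` may be a mapping, a path to a YAML file, or ``None`` for the
    defaults.  Files are written under ``outdir``.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = _merged(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    results: dict[str, Any] = {"config": cfg}

    with _Stage("genome build"):
        g = cfg["genome"]
        spec = syn.SimGenomeSpec(
            genome_length=int(g["length"]),
            repeat_plants=tuple(
                syn.RepeatPlant(r["length"], r["start1"], r["start2"], r.get("orientation", "direct"))
                for r in g.get("repeats", [])
            ),
            mtpt_plants=tuple(
                syn.MtptPlant(m["length"], m["mito_start"]) for m in g.get("mtpts", [])
            ),
            plastid_length=int(g.get("plastid_length", 120_000)),
            gc=float(g.get("gc", 0.4554)),
            seed=seed,
        )
        mito, plastid, truth = syn.build_genome(spec)
        write_fasta([mito], out / "mito.fasta")
        write_fasta([plastid], out / "plastid.fasta")
        syn.write_truth_tsv(truth, out / "truth.tsv")
        results.update(mito=mito, plastid=plastid, truth=truth)

    with _Stage("repeat scan"):
        rs = cfg["repeat_scan"]
        ssrs = rep.find_ssrs(mito)
        tandems = rep.find_tandem_repeats(mito)
        pairs = rep.find_dispersed_repeats(
            mito, min_len=int(rs["min_len"]), min_identity=float(rs["min_identity"])
        )
        rep.ssrs_to_frame(ssrs).to_csv(out / "ssrs.tsv", sep="\t", index=False)
        rep.tandems_to_frame(tandems).to_csv(out / "tandems.tsv", sep="\t", index=False)
        rep.repeat_pairs_to_frame(pairs).to_csv(out / "repeat_pairs.tsv", sep="\t", index=False)
        rep.repeat_pairs_to_bed(pairs, mito.id, out / "repeat_pairs.bed")
        results.update(ssrs=ssrs, tandems=tandems, pairs=pairs)

    with _Stage("conformations"):
        cl = cfg["classify"]
        conf_sets = [
            rec.enumerate_conformations(mito, p, flank=int(cl["flank"])) for p in pairs
        ]
        with open(out / "junctions.fasta", "w") as fh:
            for cs in conf_sets:
                for tag, seqs in (("master", cs.master_junctions), ("alt", cs.alt_junctions)):
                    for i, s in enumerate(seqs, 1):
                        fh.write(f">{cs.repeat.id}_{tag}_junction{i}\n{s}\n")
        results["conformations"] = conf_sets

    with _Stage("read simulation"):
        rd = cfg["reads"]
        known = {"master"} | {cs.conformation_id for cs in conf_sets}
        weights = {k: float(v) for k, v in rd["weights"].items()}
        unknown = set(weights) - known
        if unknown:
            raise ValueError(f"read weights reference unknown conformations: {sorted(unknown)}")
        read_spec = syn.ReadSimSpec(
            conformation_weights=weights,
            n_reads=int(rd["n_reads"]),
            substitution_rate=float(rd.get("substitution_rate", 0.03)),
            insertion_rate=float(rd.get("insertion_rate", 0.01)),
            deletion_rate=float(rd.get("deletion_rate", 0.01)),
            seed=seed + 1,
        )
        reads = syn.simulate_reads(mito, conf_sets, read_spec)
        syn.write_reads_fasta(reads, out / "reads.fasta")
        syn.write_spec_echo(spec, read_spec, out / "sim_config.txt")
        results["reads"] = reads

    with _Stage("classification"):
        labels_by_repeat: dict[str, list[str]] = {}
        rows = []
        for cs in conf_sets:
            clf = rec.ReadClassifier(
                cs, anchor=int(cl["anchor"]), min_identity=float(cl["min_identity"])
            )
            labels = [clf.classify(r.sequence) for r in reads]
            labels_by_repeat[cs.repeat.id] = labels
            rows.extend(
                {"read": r.id, "repeat": cs.repeat.id, "label": lab}
                for r, lab in zip(reads, labels)
            )
        import pandas as pd

        pd.DataFrame(rows, columns=["read", "repeat", "label"]).to_csv(
            out / "read_classification.tsv", sep="\t", index=False
        )
        support = rec.support_table(labels_by_repeat, pairs)
        rec.support_to_frame(support).to_csv(out / "support.tsv", sep="\t", index=False)
        results["support"] = support

    with _Stage("multipartite"):
        model = rec.infer_multipartite(
            support, mito, pairs,
            activity_threshold=float(cfg["multipartite"]["activity_threshold"]),
        )
        model.to_json(out / "multipartite.json")
        rec.segments_to_gff3(model, mito.id, out / "multipartite_segments.gff3")
        results["multipartite"] = model

    with _Stage("homology & MTPT"):
        mtpts, total_bp, pct_mito, pct_plastid = hom.find_mtpts(mito, plastid)
        segments = hom.pairwise_homology(mito, plastid)
        hom.segments_to_frame(segments).to_csv(out / "mtpt_segments.tsv", sep="\t", index=False)
        hom.merged_bed(segments, "query", mito.id, len(mito), out / "mtpt_merged_mito.bed")
        hom.link_table(segments, mito.id, plastid.id, out / "mtpt_links.tsv")
        results.update(
            mtpts=mtpts, mtpt_total_bp=total_bp,
            mtpt_percent_mito=pct_mito, mtpt_percent_plastid=pct_plastid,
        )

    with _Stage("stats & report"):
        gc = st.gc_content(mito)
        results["gc_percent"] = gc
        render_report(results, out / "report.md")

    return results


def render_report(results: Mapping[str, Any], path: str | Path) -> None:
    """One Markdown report aggregating every stage's headline numbers."""
    mito: CircularSequence = results["mito"]
    lines = [
        "# mitoforms pipeline report",
        "",
        "## Genome",
        f"- molecule: `{mito.id}`, circular, {len(mito):,} bp",
        f"- GC content: {results['gc_percent']:.2f} %",
        "",
        "## Repeats",
        f"- SSRs: {len(results['ssrs'])}",
        f"- tandem arrays: {len(results['tandems'])}",
        f"- dispersed repeat pairs (>=100 bp): {len(results['pairs'])}",
        "",
        "| repeat | length | orientation | copy1 | copy2 | identity % |",
        "|---|---|---|---|---|---|",
    ]
    for p in results["pairs"]:
        lines.append(
            f"| {p.id} | {p.length} | {p.orientation} | "
            f"{p.copy1[0] + 1}-{p.copy1[1]} | {p.copy2[0] + 1}-{p.copy2[1]} | {p.identity} |"
        )
    lines += [
        "",
        "## Long-read conformation support",
        "",
        "| repeat | n_master | n_alt | n_uninformative | master % | alt % |",
        "|---|---|---|---|---|---|",
    ]
    for r in results["support"]:
        fm = "NA" if r.frac_master is None else f"{r.frac_master:.2f}"
        fa = "NA" if r.frac_alt is None else f"{r.frac_alt:.2f}"
        lines.append(
            f"| {r.repeat_id} | {r.n_master} | {r.n_alt} | {r.n_uninformative} | {fm} | {fa} |"
        )
    model = results["multipartite"]
    lines += ["", "## Multipartite model", f"- master circle: {model.master_length:,} bp"]
    for rid, frac in model.active:
        if rid in model.circles:
            sizes = ", ".join(f"{c.size:,} bp" for c in model.circles[rid])
            lines.append(f"- {rid} active ({frac:.2f} % alternative): subgenomic circles {sizes}")
        else:
            lines.append(f"- {rid} active ({frac:.2f} % alternative): inversion isomer")
    for rid, frac in model.inactive:
        shown = "NA" if frac is None else f"{frac:.2f} %"
        lines.append(f"- {rid} inactive (alternative support {shown})")
    if model.ambiguous:
        lines.append("- WARNING: active repeats interleave; pairwise products only")
    lines += [
        "",
        "## Plastid-derived sequence (MTPT)",
        f"- fragments: {len(results['mtpts'])}",
        f"- merged total: {results['mtpt_total_bp']:,} bp "
        f"({results['mtpt_percent_mito']:.2f} % of the mitogenome, "
        f"{results['mtpt_percent_plastid']:.2f} % of the plastid)",
        "",
    ]
    Path(path).write_text("\n".join(lines))
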