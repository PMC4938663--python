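"""End-to-end benchmark: simulate -> align -> place (per mode) -> evaluate.

One simulated library and one all-alignment map are shared by all placement
modes, so the comparison isolates the placement policy: alignment is
identical, only the per-read primary selection differs. Per-stage seeds are
derived deterministically from a single global seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align, evaluate, place, seqio, sim

DEFAULT_MODES = ("R", "U", "F", "N")


def derive_seeds(global_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds (< 2**31) from one global seed."""
    state = np.random.SeedSequence(global_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass
class RunConfig:
    genome: sim.SimGenomeConfig = field(default_factory=sim.default_benchmark_genome_config)
    library: sim.SimLibraryConfig = field(default_factory=sim.SimLibraryConfig)
    placement: place.PlacementConfig = field(default_factory=place.PlacementConfig)
    modes: tuple[str, ...] = DEFAULT_MODES
    outdir: str = "benchmark_out"
    seed: int = 0
    write_reads: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "genome" in raw:
            g = raw["genome"]
            if "repeat_families" in g:
                g["repeat_families"] = [tuple(x) for x in g["repeat_families"]]
            cfg.genome = sim.SimGenomeConfig(**g)
        if "library" in raw:
            cfg.library = sim.SimLibraryConfig(**raw["library"])
        if "placement" in raw:
            cfg.placement = place.PlacementConfig(**raw["placement"])
        for key in ("modes", "outdir", "seed", "write_reads"):
            if key in raw:
                setattr(cfg, key, tuple(raw[key]) if key == "modes" else raw[key])
        return cfg


def run_benchmark(config: RunConfig, log=print) -> dict[str, pd.DataFrame]:
    """Run the full loop and write all artifacts under ``config.outdir``.

    Returns {'combined': comparison table, 'per_mode': metrics by mode,
    'retention': retention curve, 'strand_bias': ratios by mode}.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seeds = derive_seeds(config.seed, 4 + len(config.modes))
    genome_cfg = sim.SimGenomeConfig(**{**asdict(config.genome), "rng_seed": seeds[0]})
    genome_cfg.repeat_families = [tuple(x) for x in genome_cfg.repeat_families]
    library_cfg = sim.SimLibraryConfig(**{**asdict(config.library), "rng_seed": seeds[1]})

    log(f"[sim] genome: {genome_cfg.n_references} reference(s) x "
        f"{genome_cfg.reference_length} nt, {genome_cfg.n_loci} loci, "
        f"{len(genome_cfg.repeat_families)} repeat families")
    simgen = sim.generate_genome(genome_cfg)
    seqio.write_fasta(simgen.references, outdir / "genome.fa")
    sim.write_loci_bed(simgen.loci, outdir / "loci.bed")
    sim.write_loci_tsv(simgen.loci, outdir / "loci.tsv")

    log(f"[sim] library: {library_cfg.n_reads} reads")
    library = sim.simulate_library(simgen.references, simgen.loci, library_cfg)
    if config.write_reads:
        library.write_fastq(outdir / "reads.fastq")
    library.write_truth(outdir / "truth.tsv")

    log("[align] indexing genome and enumerating all exact-match sites")
    index = align.GenomeIndex(simgen.references)
    groups = align.align_library(
        zip(library.read_ids, library.sequences), index, config.placement.max_sites
    )
    n_overflow = sum(g.overflow for g in groups)
    n_unaligned = sum(g.n == 0 for g in groups)
    log(f"[align] {len(groups)} reads: {n_unaligned} unaligned, "
        f"{n_overflow} overflow (> {config.placement.max_sites} sites)")
    align.write_all_alignment_sam(groups, index.ref_lengths, outdir / "alignments.sam")

    per_mode_rows = []
    strand_rows = []
    counts_log = {}
    for i, mode in enumerate(config.modes):
        pcfg = place.PlacementConfig(
            **{**asdict(config.placement), "mode": mode, "rng_seed": seeds[4 + i]}
        )
        decisions = place.place_library(groups, pcfg, index.ref_lengths)
        place.write_placed_sam(
            groups, decisions, index.ref_lengths, outdir / f"placed_{mode}.sam"
        )
        per_read = evaluate.evaluate_library(decisions, library.truth)
        table = evaluate.metrics_table(per_read)
        table.insert(0, "mode", mode)
        per_mode_rows.append(table)
        by_mmap = evaluate.metrics_by_mmap(per_read)
        by_mmap.insert(0, "mode", mode)
        by_mmap.to_csv(outdir / f"metrics_by_mmap_{mode}.tsv", sep="\t", index=False)
        strand_rows.append({"mode": mode, "top_bottom_ratio": evaluate.strand_bias(decisions)})
        n_suppressed = sum(d.status == place.SUPPRESSED for d in decisions)
        n_placed = sum(d.placed for d in decisions)
        counts_log[mode] = {
            "placed": n_placed,
            "suppressed": n_suppressed,
            "unmapped": len(decisions) - n_placed,
        }
        log(f"[place:{mode}] placed {n_placed}, suppressed {n_suppressed}")

    combined = pd.concat(per_mode_rows, ignore_index=True)
    combined.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    max_n = config.placement.max_sites
    retention = evaluate.retention_curve(groups, list(range(1, max_n + 1)))
    retention.to_csv(outdir / "retention.tsv", sep="\t", index=False)
    strand = pd.DataFrame(strand_rows)
    strand.to_csv(outdir / "strandbias.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "derived_seeds": seeds,
        "modes": list(config.modes),
        "genome_config": asdict(genome_cfg),
        "library_config": asdict(library_cfg),
        "placement_config": asdict(config.placement),
        "counts": {
            "reads": len(groups),
            "unaligned": int(n_unaligned),
            "overflow": int(n_overflow),
            "per_mode": counts_log,
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log(f"[done] wrote {outdir}/ in {manifest['elapsed_s']} s")
    return {
        "combined": combined,
        "retention": retention,
        "strand_bias": strand,
    }
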