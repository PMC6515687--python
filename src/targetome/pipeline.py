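"""Declarative pipeline: simulate -> quantify -> analyze with a JSON report."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from targetome import crosslink_sites as xl
from targetome import metagene, mirna_targetome, mirna_transcript_quant as mtq
from targetome import splice_proximity, splicing_pir
from targetome.synthetic_data import (
    SimulationConfig,
    generate_genome,
    simulate_clip_reads,
    simulate_rnaseq,
    simulate_small_rna,
    small_rna_tpm,
    write_reads,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "crosslink", "metagene", "mirna", "quant", "splice", "pir")

DEFAULTS = {
    "hairpin_flank": 100,
    "window_flank": 200,
    "region_bins": 100,
    "hairpin_bins": 30,
    "fold_min": 1.5,
    "tpm_min": 1.5,
    "min_reads": 5,
    "fpkm_min": 0.5,
    "min_libraries": 2,
    "splice_window": 200,
    "site_flank": 100,
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "targetome_run"
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    params: dict[str, float] = field(default_factory=lambda: dict(DEFAULTS))
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in ("seed", "outdir", "simulate")})
        for stage, on in raw.get("stages", {}).items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            cfg.stages[stage] = bool(on)
        for key, value in raw.get("params", {}).items():
            if key not in DEFAULTS:
                raise ValueError(f"unknown parameter {key!r}")
            cfg.params[key] = value
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run enabled stages in dependency order; returns the JSON summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {
        "seed": config.seed,
        "stages": dict(config.stages),
        "params": dict(config.params),
        "simulate": dict(config.simulate),
    }}
    p = config.params

    t0 = time.time()
    try:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulate)
        dataset = generate_genome(sim_cfg)
        paths = dataset.write(outdir / "simulated")
        clip_reads, _ = simulate_clip_reads(dataset)
        rnaseq = {c: simulate_rnaseq(dataset, c) for c in ("control", "knockdown")}
        small = {c: simulate_small_rna(dataset, c) for c in ("control", "knockdown")}
        write_reads(clip_reads, sim_cfg.chrom_lengths, outdir / "simulated" / "clip.sam")
        for c in rnaseq:
            write_reads(rnaseq[c], sim_cfg.chrom_lengths, outdir / "simulated" / f"rnaseq_{c}.sam")
        summary["simulate"] = {
            "n_clip_reads": len(clip_reads),
            "n_rnaseq_reads": {c: len(v) for c, v in rnaseq.items()},
            "n_small_rna_reads": {c: len(v) for c, v in small.items()},
            "n_transcripts": len(dataset.annotation.transcripts),
            "n_hairpins": len(dataset.hairpins),
            "files": {k: str(Path(v).relative_to(outdir)) for k, v in paths.items()},
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc
    logger.info("simulate: %.2fs", time.time() - t0)

    annotation, hairpins = dataset.annotation, dataset.hairpins
    genome = dataset.sequences
    sites = None

    if config.stages.get("crosslink", True):
        t0 = time.time()
        try:
            sites, site_summary = xl.extract_deletion_sites(clip_reads)
            profile = xl.base_composition_profile(sites, genome, flank=int(p["site_flank"]))
            _write_profile_tsv(profile, outdir / "site_composition.tsv")
            with open(outdir / "sites.bed", "w") as fh:
                for s in sites:
                    fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\tsite\t{s.residue_count}\t{s.strand}\n")
            summary["crosslink"] = {
                "n_sites": site_summary.n_sites,
                "n_residues": site_summary.n_residues,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("crosslink", exc) from exc
        logger.info("crosslink: %.2fs", time.time() - t0)

    if config.stages.get("metagene", True):
        t0 = time.time()
        try:
            dist = metagene.classify_read_regions(clip_reads, annotation)
            terciles = metagene.tercile_partition(
                {tid: t.utr3_length for tid, t in annotation.transcripts.items()}
            )
            profile = metagene.region_coverage_profile(
                clip_reads, annotation, list(annotation.transcripts), bins=int(p["region_bins"])
            )
            rep = metagene.interval_overlap_summary(
                clip_reads, [iv for iv, _ in dataset.repeats], [n for _, n in dataset.repeats]
            )
            summary["metagene"] = {
                "region_fractions": {lib: d.fractions for lib, d in dist.items()},
                "tercile_sizes": terciles.sizes,
                "repeat_overlap_fraction": rep.fraction,
                "profile_area": float(profile.depth.sum()),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("metagene", exc) from exc
        logger.info("metagene: %.2fs", time.time() - t0)

    if config.stages.get("mirna", True):
        t0 = time.time()
        try:
            pairs = mirna_targetome.collect_hairpin_reads(clip_reads, hairpins, flank=int(p["hairpin_flank"]))
            cats = mirna_targetome.classify_mirna_reads(pairs, flank=int(p["hairpin_flank"]))
            calls = mirna_targetome.call_mirna_forms(cats, min_reads=int(p["min_reads"]))
            profile = mirna_targetome.hairpin_meta_profile(
                clip_reads, hairpins, flank=int(p["window_flank"]), bins=int(p["hairpin_bins"])
            )
            lengths = [r.length for r in small["control"]]
            lp = mirna_targetome.small_rna_length_profile(lengths)
            summary["mirna"] = {
                "n_pairs": len(pairs),
                "forms": {m: sorted(c.forms) for m, c in calls.items()},
                "n_mature": sum("mature" in c.forms for c in calls.values()),
                "n_pre": sum("pre" in c.forms for c in calls.values()),
                "n_pri": sum("pri" in c.forms for c in calls.values()),
                "small_rna_21_25_share": lp.share(21, 25),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("mirna", exc) from exc
        logger.info("mirna: %.2fs", time.time() - t0)

    if config.stages.get("quant", True):
        t0 = time.time()
        try:
            dens = {
                c: mtq.mirna_window_density(rnaseq[c], hairpins, c, flank=int(p["window_flank"]))
                for c in ("control", "knockdown")
            }
            tcalls = mtq.differential_mirna_transcripts(
                dens["control"], dens["knockdown"], fold_min=p["fold_min"]
            )
            scalls = mtq.differential_mirna(
                small_rna_tpm(small["control"]),
                small_rna_tpm(small["knockdown"]),
                fold_min=p["fold_min"],
                tpm_min=p["tpm_min"],
            )
            origins = mtq.classify_mirna_origin(hairpins, annotation)
            summary["quant"] = {
                "transcript_calls": {m: c.call for m, c in tcalls.items()},
                "mature_calls": {m: c.call for m, c in scalls.items() if m != "_background"},
                "origins": origins,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("quant", exc) from exc
        logger.info("quant: %.2fs", time.time() - t0)

    if config.stages.get("splice", True):
        t0 = time.time()
        try:
            if sites is None:
                sites, _ = xl.extract_deletion_sites(clip_reads)
            h5, h3 = splice_proximity.map_crosslinks_to_splice_sites(
                sites, annotation, window=int(p["splice_window"])
            )
            summary["splice"] = {
                "n_5ss_sites": int(h5.site_counts.sum()),
                "n_3ss_sites": int(h3.site_counts.sum()),
                "mode_5ss": h5.mode_offset,
                "mode_3ss": h3.mode_offset,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("splice", exc) from exc
        logger.info("splice: %.2fs", time.time() - t0)

    if config.stages.get("pir", True):
        t0 = time.time()
        try:
            pir_out = {}
            for mid, intron in sorted(dataset.truth.mirtron_introns.items()):
                row = {}
                counts = {}
                for c in ("control", "knockdown"):
                    ret, exc_n = splicing_pir.count_isoform_evidence(rnaseq[c], intron)
                    counts[c] = (ret, exc_n)
                    row[c] = splicing_pir.compute_pir(ret, exc_n)
                row["transcript_change"] = splicing_pir.mirtron_transcript_change(
                    counts["control"], counts["knockdown"],
                    len(rnaseq["control"]), len(rnaseq["knockdown"]),
                )
                pir_out[mid] = row
            summary["pir"] = pir_out
        except Exception as exc:  # noqa: BLE001
            raise StageError("pir", exc) from exc
        logger.info("pir: %.2fs", time.time() - t0)

    report = outdir / "report.json"
    report.write_text(json.dumps(summary, indent=1, sort_keys=True, default=_jsonify))
    return summary


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(type(o))


def _write_profile_tsv(profile, path: Path) -> None:
    tracks = sorted(profile.values)
    with open(path, "w") as fh:
        fh.write("offset\t" + "\t".join(tracks) + "\n")
        for i, off in enumerate(profile.offsets):
            fh.write(str(int(off)) + "\t" + "\t".join(f"{profile.values[t][i]:.6g}" for t in tracks) + "\n")
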