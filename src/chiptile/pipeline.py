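"""End-to-end pipeline: simulate -> callpeaks -> annotate -> motif -> enrich
-> profile, with a YAML config, JSON-lines logging and a run manifest.

One global seed is expanded into fixed per-stage seeds so any stage can be
rerun independently yet reproducibly; the manifest records a config
snapshot, per-stage output digests and wall status, and is byte-stable
across reruns at a fixed seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import formats as fio
from . import gibbsmotif, peakcall, profiles, synthdata, tfbs

DEFAULT_CONFIG = {
    "seed": 0,
    "synth": {
        "n_chromosomes": 3,
        "chrom_length": 2_000_000,
        "gc_content": 0.41,
        "n_genes": 150,
        "probe_spacing": 100,
        "probe_length": 50,
        "n_true_peaks": 100,
        "peak_length_mean": 692,
        "enrich_mu": 2.0,
        "noise_sigma": 0.5,
        "motif_plant_rate": 0.55,
        "dhs_overlap_rate": 0.1344,
        "de_up": 26,
        "de_down": 47,
    },
    "peakcall": {
        "p_start": 90.0,
        "p_step": 1.0,
        "n_steps": 76,
        "min_probes": 4,
        "min_probes_all_above": 4,
        "window": 500,
        "fdr_max": 0.005,
        "n_permutations": 20,
        "hypmax_k": 12.0,
    },
    "annotate": {
        "promoter_window": 10_000,
        "tes_window": 10_000,
        "density_bin": 1_000_000,
        "correlation_bin": 100_000,
    },
    "motif": {
        "width": 12,
        "iterations": 5000,
        "presence_threshold": 0.8,
        "max_sequences": 500,
    },
    "tfbs": {
        "n_matrices": 20,
        "threshold": 0.85,
        "alpha": 0.0005,
        "n_controls": 10,
        "ctcf_pattern": "AG[GA][GT]GG[CAT][GAT][CG]",
    },
    "profiles": {
        "window": 10_000,
        "bin": 200,
        "fc_threshold": 1.5,
        "dhs_margin": 1000,
        "tertiles": [0.30, 0.40, 0.30],
    },
    "inputs": {},
}

# keys a config file must state explicitly (core analysis thresholds)
REQUIRED_KEYS = [
    ("peakcall", "fdr_max"),
    ("tfbs", "alpha"),
    ("profiles", "fc_threshold"),
]

_STAGE_SEED = {"simulate": 1, "callpeaks": 2, "motif": 3, "enrich": 4}


class ConfigError(ValueError):
    """Configuration file violates the pipeline schema."""


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return validate_config(user)


def validate_config(user: dict) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in user.items():
        if section == "seed":
            cfg["seed"] = int(values)
            continue
        if section not in cfg:
            raise ConfigError(f"unknown config section: {section}")
        if not isinstance(values, dict):
            raise ConfigError(f"section {section} must be a mapping")
        for key, v in values.items():
            if section != "inputs" and key not in cfg[section]:
                raise ConfigError(f"unknown config key: {section}.{key}")
            cfg[section][key] = v
    for section, key in REQUIRED_KEYS:
        if section not in user or key not in user[section]:
            raise ConfigError(f"config must state {section}.{key}")
    return cfg


def default_config_yaml() -> str:
    return yaml.safe_dump(DEFAULT_CONFIG, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 16 + _STAGE_SEED[stage]) % (2**31)


class _Log:
    def __init__(self, path: Path, echo=print):
        self.fh = open(path, "w")
        self.echo = echo

    def event(self, stage: str, status: str, **extra):
        rec = {"stage": stage, "status": status, **extra}
        self.fh.write(json.dumps(rec) + "\n")
        self.fh.flush()
        self.echo(f"[{stage}] {status}" + (f" {extra}" if extra else ""))

    def close(self):
        self.fh.close()


def run_all(config: dict, outdir, seed: int | None = None, echo=print) -> dict:
    """Execute the full pipeline and return (and write) the run manifest."""
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log", echo=echo)
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "stages": {},
    }

    def finish(stage: str, t0: float, files: list[Path]):
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {f.name: _sha256(f) for f in sorted(files)},
        }
        log.event(stage, "done", seconds=round(time.time() - t0, 2))

    try:
        # ------------------------------------------------------------ simulate
        t0 = time.time()
        inputs = cfg.get("inputs") or {}
        if inputs.get("probes"):
            log.event("simulate", "skipped (external inputs)")
            genome = fio.read_fasta(inputs["genome"]) if inputs.get("genome") else None
            genes = fio.read_gff_genes(inputs["genes"]) if inputs.get("genes") else []
            probe_path = Path(inputs["probes"])
            if probe_path.suffix == ".wig":
                tracks = fio.read_wig(probe_path)
            else:
                tracks = fio.read_probe_tsv(probe_path)
            expression = (
                fio.read_expression_tsv(inputs["expression"])
                if inputs.get("expression")
                else None
            )
            dhs = fio.read_bed(inputs["dhs"]) if inputs.get("dhs") else None
            study = None
            manifest["stages"]["simulate"] = {"status": "skipped", "outputs": {}}
        else:
            scfg = synthdata.SyntheticConfig(
                seed=_stage_seed(cfg["seed"], "simulate"), **cfg["synth"]
            )
            study = synthdata.generate_study(scfg)
            genome, genes = study.genome, study.genes
            tracks, expression, dhs = study.tracks, study.expression, study.dhs
            files = []
            fio.write_fasta(genome, out / "genome.fa")
            fio.write_gff_genes(genes, out / "genes.gff")
            fio.write_gene_table(genes, out / "genes.tsv")
            fio.write_wig(tracks, out / "probes.wig")
            fio.write_probe_tsv(tracks, out / "probes.tsv")
            fio.write_expression_tsv(expression, out / "expression.tsv")
            fio.write_bed(dhs, out / "dhs.bed")
            study.truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
            files = [
                out / n
                for n in (
                    "genome.fa", "genes.gff", "genes.tsv", "probes.wig",
                    "probes.tsv", "expression.tsv", "dhs.bed", "truth.tsv",
                )
            ]
            finish("simulate", t0, files)

        # ----------------------------------------------------------- callpeaks
        t0 = time.time()
        params = peakcall.PeakCallParams(
            seed=_stage_seed(cfg["seed"], "callpeaks"), **cfg["peakcall"]
        )
        all_peaks, peaks = peakcall.call_and_filter(tracks, params)
        fio.write_peaks_bed(peaks, out / "peaks.bed")
        fio.write_peaks_gff(all_peaks, out / "peaks_all.gff")
        finish("callpeaks", t0, [out / "peaks.bed", out / "peaks_all.gff"])

        # ------------------------------------------------------------ annotate
        t0 = time.time()
        acfg = cfg["annotate"]
        table = ann.annotate_peaks(
            peaks, genes, acfg["promoter_window"], acfg["tes_window"]
        )
        table.to_csv(out / "annotated.tsv", sep="\t", index=False)
        summary = ann.summarize_categories(
            peaks, genes, acfg["promoter_window"], acfg["tes_window"]
        )
        summary.to_csv(out / "category_summary.tsv", sep="\t", index=False)
        chrom_lens = {c: len(s) for c, s in genome.items()} if genome else {}
        dens = ann.density_track(peaks, chrom_lens, acfg["density_bin"])
        dens.to_csv(out / "density.tsv", sep="\t", index=False)
        corr = ann.gene_peak_density_correlation(
            peaks, genes, chrom_lens, acfg["correlation_bin"]
        )
        links, n_linked_peaks, n_linked_genes = ann.map_peaks_to_genes(
            peaks, genes, cfg["profiles"]["window"]
        )
        (out / "annotate_summary.json").write_text(
            json.dumps(
                {
                    "n_peaks": len(peaks),
                    "mean_peak_length": float(
                        np.mean([p.interval.length for p in peaks])
                    )
                    if peaks
                    else 0.0,
                    "gene_peak_density_correlation": corr,
                    "n_linked_peaks": n_linked_peaks,
                    "n_linked_genes": n_linked_genes,
                },
                indent=2,
                sort_keys=True,
            )
        )
        finish(
            "annotate",
            t0,
            [
                out / n
                for n in (
                    "annotated.tsv", "category_summary.tsv", "density.tsv",
                    "annotate_summary.json",
                )
            ],
        )

        # --------------------------------------------------------------- motif
        t0 = time.time()
        mcfg = cfg["motif"]
        seqs = synthdata.peak_sequences(genome, peaks) if genome else []
        seqs = [s for s in seqs if len(s) >= mcfg["width"]][: mcfg["max_sequences"]]
        if len(seqs) >= 2:
            model = gibbsmotif.gibbs_sample(
                seqs,
                width=mcfg["width"],
                iterations=mcfg["iterations"],
                seed=_stage_seed(cfg["seed"], "motif"),
            )
            fio.write_transfac_matrices([model.pwm], out / "motif.transfac")
            gibbsmotif.write_motif_report(model, out / "motif_report.tsv")
            frac, _ = gibbsmotif.fraction_with_motif(
                model.pwm, seqs, mcfg["presence_threshold"], model.background
            )
            (out / "motif_summary.json").write_text(
                json.dumps(
                    {
                        "consensus": model.pwm.consensus,
                        "score": model.score,
                        "information_bits": gibbsmotif.information_content(
                            model.pwm, model.background
                        ),
                        "fraction_with_motif": frac,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            finish(
                "motif",
                t0,
                [out / n for n in ("motif.transfac", "motif_report.tsv",
                                   "motif_summary.json")],
            )
        else:
            manifest["stages"]["motif"] = {"status": "skipped", "outputs": {}}
            log.event("motif", "skipped (not enough peak sequences)")

        # -------------------------------------------------------------- enrich
        t0 = time.time()
        tcfg = cfg["tfbs"]
        if genome and peaks:
            library = synthdata.random_pwm_library(
                tcfg["n_matrices"], seed=_stage_seed(cfg["seed"], "enrich")
            )
            library.append(
                synthdata.consensus_to_pwm(
                    synthdata.DEFAULT_MOTIF, pwm_id="planted_motif"
                )
            )
            control_sets = tfbs.sample_controls(
                peaks, genome, tcfg["n_controls"],
                seed=_stage_seed(cfg["seed"], "enrich"),
            )
            control_seq_sets = [
                synthdata.peak_sequences(genome, cs) for cs in control_sets
            ]
            records = tfbs.chi_square_enrichment(
                seqs or synthdata.peak_sequences(genome, peaks),
                control_seq_sets,
                library,
                threshold=tcfg["threshold"],
                alpha=tcfg["alpha"],
            )
            pd.DataFrame(
                [
                    {
                        "tf_id": r.tf_id,
                        "observed": r.observed_hits,
                        "expected": r.expected_hits,
                        "chi2": r.chi2,
                        "p": r.p,
                        "significant": r.significant,
                    }
                    for r in records
                ]
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            pattern = tfbs.ConsensusPattern(tcfg["ctcf_pattern"])
            counts, frac = tfbs.scan_consensus(
                synthdata.peak_sequences(genome, peaks), pattern
            )
            pd.DataFrame(
                {
                    "peak_index": range(len(counts)),
                    "ctcf_matches": counts,
                }
            ).to_csv(out / "ctcf.tsv", sep="\t", index=False)
            (out / "enrich_summary.json").write_text(
                json.dumps(
                    {
                        "n_significant": int(sum(r.significant for r in records)),
                        "ctcf_fraction": frac,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            finish(
                "enrich",
                t0,
                [out / n for n in ("enrichment.tsv", "ctcf.tsv",
                                   "enrich_summary.json")],
            )
        else:
            manifest["stages"]["enrich"] = {"status": "skipped", "outputs": {}}
            log.event("enrich", "skipped (no genome or no peaks)")

        # ------------------------------------------------------------- profile
        t0 = time.time()
        pcfg = cfg["profiles"]
        files = []
        if expression is not None:
            prof = profiles.expression_metaprofiles(
                peaks, genes, expression, pcfg["window"], pcfg["bin"],
                tuple(pcfg["tertiles"]),
            )
            prof.to_csv(out / "profiles.tsv", sep="\t", index=False)
            up, down = profiles.intersect_de_genes(
                links, expression, pcfg["fc_threshold"]
            )
            pd.DataFrame(
                {
                    "gene_id": up + down,
                    "direction": ["up"] * len(up) + ["down"] * len(down),
                }
            ).to_csv(out / "de_genes.tsv", sep="\t", index=False)
            files += [out / "profiles.tsv", out / "de_genes.tsv"]
        summary = {}
        if dhs is not None:
            frac, _ = profiles.dhs_cooccurrence(peaks, dhs, pcfg["dhs_margin"])
            summary["dhs_cooccurrence_percent"] = 100.0 * frac
        if expression is not None:
            summary["n_de_up"] = len(up)
            summary["n_de_down"] = len(down)
        (out / "profile_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        files.append(out / "profile_summary.json")
        finish("profile", t0, files)
    except Exception as exc:
        log.event("pipeline", "failed", error=str(exc))
        log.close()
        raise
    log.close()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
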