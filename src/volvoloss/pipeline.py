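"""End-to-end orchestration: synthetic data -> trends -> loss calls -> networks.

Each stage is runnable standalone through the library (or the CLI); the
orchestrator only sequences them and records a run manifest (config hash,
seeds, output paths and checksums).  All outputs are plain text (TSV / JSON /
FASTA / GFF3 / Newick) so runs are diffable; rerunning with the same seed
reproduces every data output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .network import SimulationConfig, run_ensemble
from .synteny import classify_losses
from .synthetic import (
    DEFAULT_DISTANCES,
    CountSynthConfig,
    GenomeSynthConfig,
    make_count_matrix,
    make_toy_genomes,
    make_tree,
)
from .trends import CountMatrix, classify_trends, distances_from_tree

__all__ = ["RunManifest", "run_full_pipeline", "load_config"]

_TOP_KEYS = {"seed", "out", "stages", "synthetic", "trends", "classify_loss", "simulate"}
_STAGES = ("synthetic", "trends", "classify_loss", "simulate")


@dataclasses.dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    inputs: dict[str, str]
    outputs: dict[str, dict[str, str]]  # stage -> {name: path}
    checksums: dict[str, str]  # path -> sha256
    started: str
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for stage in config.get("stages", []):
        if stage not in _STAGES:
            raise ValueError(f"unknown stage: {stage}")
    return config


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_full_pipeline(config_path, out_dir=None, seed: int | None = None) -> RunManifest:
    """Run the configured stages in dependency order and write a manifest.

    ``config_path`` is a YAML file validated against the known keys; any
    unknown key raises before any stage runs.
    """
    config_path = Path(config_path)
    config = load_config(config_path)
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir or config.get("out", "volvoloss_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", _STAGES))
    manifest = RunManifest(
        version=__version__,
        config_hash=_config_hash(config),
        seed=seed,
        inputs={str(config_path): _sha256(config_path)},
        outputs={},
        checksums={},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def record(stage: str, name: str, path: Path) -> None:
        manifest.outputs.setdefault(stage, {})[name] = str(path)
        manifest.checksums[str(path)] = _sha256(path)

    counts = truth_counts = tree = None
    toy = None

    if "synthetic" in stages:
        syn = config.get("synthetic", {}) or {}
        ccfg = CountSynthConfig(seed=seed, **(syn.get("counts", {}) or {}))
        counts, truth_counts = make_count_matrix(ccfg)
        tree = make_tree(ccfg.distances)
        counts.to_tsv(out / "counts.tsv")
        _write_tsv(truth_counts, out / "counts_truth.tsv")
        (out / "species_tree.nwk").write_text(tree + "\n")
        record("synthetic", "counts", out / "counts.tsv")
        record("synthetic", "counts_truth", out / "counts_truth.tsv")
        record("synthetic", "species_tree", out / "species_tree.nwk")
        gcfg = GenomeSynthConfig(seed=seed, **(syn.get("genomes", {}) or {}))
        toy = make_toy_genomes(gcfg)
        gdir = out / "genomes"
        gdir.mkdir(exist_ok=True)
        for sp, annot in toy["annotations"].items():
            annot.to_files(gdir / f"{sp}.fasta", gdir / f"{sp}.gff3", species=sp)
            record("synthetic", f"fasta_{sp}", gdir / f"{sp}.fasta")
            record("synthetic", f"gff3_{sp}", gdir / f"{sp}.gff3")
        toy["ortholog_table"].to_tsv(out / "orthologs.tsv")
        _write_tsv(toy["truth"], out / "genome_truth.tsv")
        record("synthetic", "orthologs", out / "orthologs.tsv")
        record("synthetic", "genome_truth", out / "genome_truth.tsv")

    if "trends" in stages:
        if counts is None:
            tcfg = config.get("trends", {}) or {}
            counts = CountMatrix.from_tsv(tcfg["counts"])
            tree = Path(tcfg["tree"]).read_text()
        distances = distances_from_tree(tree, counts.species)
        multiplier = float((config.get("trends", {}) or {}).get("multiplier", 1.5))
        trend = classify_trends(counts, distances, multiplier=multiplier)
        _write_tsv(trend.to_frame(), out / "rates.tsv")
        _write_tsv(pd.DataFrame([trend.summary()]), out / "trends_summary.tsv")
        record("trends", "rates", out / "rates.tsv")
        record("trends", "summary", out / "trends_summary.tsv")

    if "classify_loss" in stages:
        if toy is None:
            raise ValueError("classify_loss stage requires the synthetic stage")
        lcfg = config.get("classify_loss", {}) or {}
        anchor = toy["config"].anchor_species
        target_distances = {
            s: DEFAULT_DISTANCES.get(s, 0.1)
            for s in toy["config"].species
            if s != anchor
        }
        target_tree = make_tree(target_distances)
        res = classify_losses(
            anchor,
            toy["annotations"],
            toy["ortholog_table"],
            sorted(set(toy["groups"].values())),
            species_tree=target_tree,
            window=int(lcfg.get("window", 5)),
            threshold=float(lcfg.get("evalue", 1e-5)),
        )
        _write_tsv(res["calls_table"], out / "calls.tsv")
        _write_tsv(res["per_species"], out / "loss_per_species.tsv", index=True)
        _write_tsv(res["patterns"], out / "loss_patterns.tsv")
        _write_tsv(res["clusters"], out / "loss_clusters.tsv", index=True)
        _write_tsv(res["bin_histogram"], out / "loss_bins.tsv")
        record("classify_loss", "calls", out / "calls.tsv")
        record("classify_loss", "patterns", out / "loss_patterns.tsv")
        record("classify_loss", "per_species", out / "loss_per_species.tsv")
        record("classify_loss", "clusters", out / "loss_clusters.tsv")
        record("classify_loss", "bins", out / "loss_bins.tsv")
        if "chisq_loss_type" in res:
            (out / "chisq.json").write_text(
                json.dumps(res["chisq_loss_type"], indent=2, sort_keys=True) + "\n"
            )
            record("classify_loss", "chisq", out / "chisq.json")

    if "simulate" in stages:
        scfg = dict(config.get("simulate", {}) or {})
        modes = scfg.pop("modes", ["deletion", "duplication"])
        if "k_values" in scfg:
            scfg["k_values"] = tuple(scfg["k_values"])
        sim = SimulationConfig(seed=seed, **scfg)
        rows = []
        for mode in modes:
            rows.extend(r.as_dict() for r in run_ensemble(sim, mode))
        _write_tsv(pd.DataFrame(rows), out / "simulate.tsv")
        record("simulate", "results", out / "simulate.tsv")

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest
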