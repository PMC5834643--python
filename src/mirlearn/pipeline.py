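"""End-to-end orchestration: simulate -> process -> quantify -> detest ->
target -> qpcr, as a configured, logged, checksummed run.

A run is described by one YAML config (all paths, module parameters and the
mandatory rng_seed); executing it produces per-stage outputs under the run
directory plus a machine-readable manifest recording the config hash and a
SHA-256 checksum of every output, so that deterministic stages are
byte-reproducible under a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .diffexpr import call_differential, write_results
from .qpcr import quantities_frame, read_ct_table, summarize_groups
from .quantify import (
    CountTable,
    build_count_table,
    map_reads,
    normalize_cpm,
    read_hairpin_references,
    write_hairpin_references,
)
from .reads import process_library, read_fastq, size_histogram, write_fastq
from .simulate import (
    MIR137_NAME,
    SimulationConfig,
    generate_hairpin_set,
    generate_library,
    generate_qpcr_table,
    generate_target_utr,
)
from .targets import SeedSpec, predict_targets

logger = logging.getLogger("mirlearn")

STAGES = ("simulate", "process", "quantify", "detest", "target", "qpcr")
#: stage -> stage whose outputs it consumes
STAGE_DEPS = {
    "process": "simulate",
    "quantify": "process",
    "detest": "quantify",
    "target": "simulate",
    "qpcr": "simulate",
}


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    run_id: str
    rng_seed: int
    outdir: Path
    n_mirnas: int = 100
    library_depths: dict[str, int] = field(
        default_factory=lambda: {"naive": 100_000, "1h": 100_000, "6h": 100_000}
    )
    planted_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    max_error_rate: float = 0.1
    min_len: int = 15
    min_qual: int = 20
    max_mismatches: int = 0
    alpha: float = 0.01
    sidedness: str = "two_sided"
    pairs: list[tuple[str, str]] = field(default_factory=list)
    seed_start: int = 2
    seed_end: int = 8
    flank: int = 70
    utr_flank_len: int = 60
    qpcr_fold_changes: dict[str, float] = field(default_factory=lambda: {"1h": 1.5, "6h": 1.0})
    qpcr_noise_sd: float = 0.2
    qpcr_replicates: int = 10

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            rng_seed=self.rng_seed,
            n_mirnas=self.n_mirnas,
            library_depths=dict(self.library_depths),
            planted_effects=dict(self.planted_effects),
            adapter3p=self.adapter,
        )

    def seed_spec(self) -> SeedSpec:
        return SeedSpec(self.seed_start, self.seed_end)

    def comparison_pairs(self) -> list[tuple[str, str]]:
        if self.pairs:
            return self.pairs
        ref = "naive" if "naive" in self.library_depths else sorted(self.library_depths)[0]
        return [(ref, lib) for lib in self.library_depths if lib != ref]


def validate_config(raw: str) -> tuple[RunConfig | None, list[str]]:
    """Parse + validate YAML config text; all violations reported at once."""
    errors: list[str] = []
    try:
        data = yaml.safe_load(raw) or {}
    except yaml.YAMLError as e:
        return None, [f"config: invalid YAML: {e}"]
    if not isinstance(data, dict):
        return None, ["config: top level must be a mapping"]

    def get(key, default=None, required=False):
        if required and key not in data:
            errors.append(f"{key}: required field missing")
        return data.get(key, default)

    run_id = get("run_id", required=True)
    rng_seed = get("rng_seed", required=True)
    outdir = get("outdir", "mirlearn_run")
    if rng_seed is not None and not isinstance(rng_seed, int):
        errors.append("rng_seed: must be an integer")

    kwargs: dict = {}
    for key in (
        "n_mirnas", "library_depths", "adapter", "max_error_rate", "min_len",
        "min_qual", "max_mismatches", "alpha", "sidedness", "seed_start",
        "seed_end", "flank", "utr_flank_len", "qpcr_fold_changes",
        "qpcr_noise_sd", "qpcr_replicates",
    ):
        if key in data:
            kwargs[key] = data[key]
    if "planted_effects" in data:
        kwargs["planted_effects"] = {
            m: (v[0], float(v[1])) for m, v in data["planted_effects"].items()
        }
    if "pairs" in data:
        kwargs["pairs"] = [tuple(p) for p in data["pairs"]]

    alpha = kwargs.get("alpha", 0.01)
    if not (isinstance(alpha, (int, float)) and 0 < alpha < 1):
        errors.append("alpha: must be in (0,1)")
    err = kwargs.get("max_error_rate", 0.1)
    if not (isinstance(err, (int, float)) and 0 <= err < 0.5):
        errors.append("max_error_rate: must be in [0, 0.5)")
    ss, se = kwargs.get("seed_start", 2), kwargs.get("seed_end", 8)
    if not (isinstance(ss, int) and isinstance(se, int) and 1 <= ss < se):
        errors.append("seed spec: must satisfy 1 <= start < end")
    elif se - ss + 1 not in (6, 7, 8):
        errors.append("seed spec: length must be 6-8 nt")
    if kwargs.get("sidedness", "two_sided") not in ("two_sided", "greater", "less"):
        errors.append("sidedness: must be two_sided, greater or less")
    depths = kwargs.get("library_depths", {"naive": 1, "1h": 1, "6h": 1})
    if not (isinstance(depths, dict) and all(isinstance(v, int) and v >= 0 for v in depths.values())):
        errors.append("library_depths: must map library id -> non-negative integer")

    if errors:
        return None, errors
    try:
        cfg = RunConfig(run_id=str(run_id), rng_seed=int(rng_seed), outdir=Path(outdir), **kwargs)
    except (TypeError, ValueError) as e:
        return None, [f"config: {e}"]
    return cfg, []


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Checksummed record of a (partial) pipeline run."""

    run_id: str
    config_hash: str
    version: str
    stages: dict[str, dict[str, str]] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, outputs: Iterable[Path]) -> None:
        self.stages[stage] = {p.name: _sha256(p) for p in outputs}
        self.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def save(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "run_id": self.run_id,
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "stages": self.stages,
                    "timestamps": self.timestamps,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(path.read_text())
        return cls(d["run_id"], d["config_hash"], d["version"], d["stages"], d["timestamps"])


class StageError(RuntimeError):
    pass


class DependencyError(StageError):
    """An input produced by an earlier, un-run stage is missing."""


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing input {path.name!r}: run the {producer!r} stage first"
        )
    return path


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> RunManifest:
    """Execute the requested stages in dependency order.

    Stages not requested are not re-run; their outputs, if present from an
    earlier run, are consumed as-is after a checksum comparison against the
    saved manifest (a mismatch aborts rather than silently overwriting).
    """
    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    requested = [s for s in STAGES if s in requested]

    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in sorted(vars(config).items())}, sort_keys=True
        ).encode()
    ).hexdigest()
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        if manifest.config_hash != config_hash:
            manifest = RunManifest(config.run_id, config_hash, __version__)
        else:
            _check_stale(manifest, out, requested)
    else:
        manifest = RunManifest(config.run_id, config_hash, __version__)

    libs = sorted(config.library_depths)
    sim_cfg = config.simulation_config()

    for stage in requested:
        logger.info("stage %s: starting", stage)
        try:
            if stage == "simulate":
                outputs = _stage_simulate(config, sim_cfg, out, libs)
            elif stage == "process":
                outputs = _stage_process(config, out, libs)
            elif stage == "quantify":
                outputs = _stage_quantify(config, out, libs)
            elif stage == "detest":
                outputs = _stage_detest(config, out)
            elif stage == "target":
                outputs = _stage_target(config, out)
            else:
                outputs = _stage_qpcr(config, out)
        except DependencyError:
            raise
        except Exception as e:
            raise StageError(f"stage {stage!r} failed: {e}") from e
        manifest.record(stage, outputs)
        manifest.save(manifest_path)
        logger.info("stage %s: done (%d outputs)", stage, len(outputs))
    return manifest


def _check_stale(manifest: RunManifest, out: Path, requested: Sequence[str]) -> None:
    for stage, files in manifest.stages.items():
        if stage in requested:
            continue  # will be recomputed
        for name, digest in files.items():
            p = out / name
            if p.exists() and _sha256(p) != digest:
                raise StageError(
                    f"stale checksum for {name!r} (stage {stage!r}); "
                    "remove the file or re-run the stage"
                )


# -- individual stages ------------------------------------------------------


def _stage_simulate(config: RunConfig, sim_cfg, out: Path, libs: list[str]) -> list[Path]:
    hairpins = generate_hairpin_set(sim_cfg)
    fa, tsv = out / "hairpins.fasta", out / "hairpins.tsv"
    write_hairpin_references(hairpins, fa, tsv)
    outputs = [fa, tsv]
    truth = {}
    for lib in libs:
        sim = generate_library(sim_cfg, hairpins, lib)
        p = out / f"{lib}.fastq"
        write_fastq(sim.reads, p)
        outputs.append(p)
        truth[lib] = sim.true_counts
    tdf = pd.DataFrame(truth)
    tdf.index.name = "mirna"
    truth_path = out / "truth_counts.tsv"
    tdf.to_csv(truth_path, sep="\t")
    outputs.append(truth_path)

    mir137 = next(h for h in hairpins if h.name == MIR137_NAME)
    planted = generate_target_utr(
        mir137.mature_seq, config.utr_flank_len, sim_cfg.rng_seed, spec=config.seed_spec()
    )
    utr_fa = out / "utr.fasta"
    utr_fa.write_text(f">synthetic_creb2_3utr planted={MIR137_NAME}\n{planted.utr}\n")
    site_tsv = out / "utr_site.tsv"
    pd.DataFrame(
        [(MIR137_NAME, planted.seed_start, planted.seed_end, planted.site_start, planted.site_end, planted.n_wobbles)],
        columns=["mirna", "seed_start", "seed_end", "site_start", "site_end", "n_wobbles"],
    ).to_csv(site_tsv, sep="\t", index=False)
    outputs += [utr_fa, site_tsv]

    qt = generate_qpcr_table(
        config.qpcr_fold_changes,
        config.qpcr_noise_sd,
        sim_cfg.rng_seed,
        n_replicates=config.qpcr_replicates,
    )
    qpcr_path = out / "qpcr_ct.tsv"
    qt.to_csv(qpcr_path, sep="\t", index=False)
    outputs.append(qpcr_path)
    return outputs


def _stage_process(config: RunConfig, out: Path, libs: list[str]) -> list[Path]:
    outputs = []
    for lib in libs:
        raw = _require(out / f"{lib}.fastq", "simulate")
        kept, tally = process_library(
            read_fastq(raw),
            config.adapter,
            max_error_rate=config.max_error_rate,
            min_len=config.min_len,
            min_q=config.min_qual,
        )
        trimmed = out / f"{lib}.trimmed.fastq"
        write_fastq(kept, trimmed)
        tally_path = out / f"{lib}.tally.tsv"
        pd.Series(tally.as_dict()).rename("count").to_csv(tally_path, sep="\t", index_label="reason")
        hist = size_histogram(kept)
        hist_path = out / f"{lib}.size_hist.tsv"
        pd.Series(hist.counts_by_length).rename("count").to_csv(hist_path, sep="\t", index_label="length")
        outputs += [trimmed, tally_path, hist_path]
    return outputs


def _stage_quantify(config: RunConfig, out: Path, libs: list[str]) -> list[Path]:
    hairpins = read_hairpin_references(
        _require(out / "hairpins.fasta", "simulate"), _require(out / "hairpins.tsv", "simulate")
    )
    assignments = {}
    for lib in libs:
        trimmed = _require(out / f"{lib}.trimmed.fastq", "process")
        assignments[lib] = map_reads(read_fastq(trimmed), hairpins, config.max_mismatches)
    table = build_count_table(assignments, [h.name for h in hairpins], libs)
    counts_path = out / "counts.tsv"
    table.to_tsv(counts_path)
    cpm_path = out / "cpm.tsv"
    normalize_cpm(table).to_csv(cpm_path, sep="\t", index_label="mirna", float_format="%.4f")
    return [counts_path, cpm_path]


def _stage_detest(config: RunConfig, out: Path) -> list[Path]:
    table = CountTable.from_tsv(_require(out / "counts.tsv", "quantify"))
    outputs = []
    for lib1, lib2 in config.comparison_pairs():
        results = call_differential(table, (lib1, lib2), config.alpha, config.sidedness)
        p = out / f"detest_{lib1}_vs_{lib2}.tsv"
        write_results(results, p)
        outputs.append(p)
    return outputs


def _stage_target(config: RunConfig, out: Path) -> list[Path]:
    from Bio import SeqIO

    utr_fa = _require(out / "utr.fasta", "simulate")
    hairpins = read_hairpin_references(
        _require(out / "hairpins.fasta", "simulate"), _require(out / "hairpins.tsv", "simulate")
    )
    mir137 = next(h for h in hairpins if h.name == MIR137_NAME)
    rec = next(SeqIO.parse(str(utr_fa), "fasta"))
    scores = predict_targets(
        mir137.mature_seq, str(rec.seq), config.seed_spec(), flank=config.flank
    )
    p = out / "target_scores.tsv"
    pd.DataFrame(
        [
            (
                MIR137_NAME,
                rec.id,
                s.site.utr_start,
                s.site.utr_end,
                s.site.n_wobbles_3prime,
                s.dG_duplex,
                s.dG_open,
                s.ddG,
            )
            for s in scores
        ],
        columns=["mirna", "utr", "utr_start", "utr_end", "n_wobbles", "dG_duplex", "dG_open", "ddG"],
    ).to_csv(p, sep="\t", index=False, float_format="%.3f")
    return [p]


def _stage_qpcr(config: RunConfig, out: Path) -> list[Path]:
    measurements = read_ct_table(_require(out / "qpcr_ct.tsv", "simulate"))
    qdf = quantities_frame(measurements)
    p1 = out / "qpcr_quantities.tsv"
    qdf.to_csv(p1, sep="\t", index=False, float_format="%.5f")
    groups = summarize_groups(measurements)
    p2 = out / "qpcr_groups.tsv"
    pd.DataFrame(
        [(g.group, g.n, g.mean, g.sem) for g in groups],
        columns=["group", "n", "mean_relative_quantity", "sem"],
    ).to_csv(p2, sep="\t", index=False, float_format="%.5f")
    return [p1, p2]
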