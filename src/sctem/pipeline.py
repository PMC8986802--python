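"""End-to-end orchestration: simulate -> demux -> align -> estimate ->
bootstrap -> correlate, with a checksummed output manifest.

Configuration is a YAML document with a versioned schema; reruns with
identical config and seeds reproduce identical checksums.  Stage
failures abort with the stage name; partial outputs are moved to a
``quarantine`` subdirectory so a clean rerun is unambiguous.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demux as demux_mod
from . import integrate, io, methylation, reference, simulate
from .errors import ConfigurationError

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Run configuration; defaults give a small demo run."""

    out_dir: str = "sctem_out"
    seed: int = 1
    # simulation stage (optional; skipped when fastq inputs are given)
    simulate: bool = True
    consensus_length: int = 300
    cpg_density: float = 0.08
    n_te_copies: int = 2000
    divergence: float = 0.05
    n_cells: int = 8
    n_read_pairs: int = 5000
    true_methylation: list = field(default_factory=lambda: [0.865])
    amp_bias: float = 0.1
    conversion_failure: float = 0.007
    inappropriate_conversion: float = 0.005
    seq_error: float = 0.001
    # external inputs (used when simulate is false)
    genome_fasta: str | None = None
    annotations_bed: str | None = None
    plate_sheet: str | None = None
    fastq_r1: str | None = None
    fastq_r2: str | None = None
    counts_tsv: str | None = None
    # thresholds
    te_site_threshold: int = 1000
    max_mismatch: int = 1
    trim5: int = 10
    trim3: int = 10
    max_mismatch_rate: float = 0.1
    bootstrap_depths: list = field(
        default_factory=lambda: [1000, 2500, 5000])
    bootstrap_reps: int = 20
    run_bootstrap: bool = False
    fdr_threshold: float = 0.05
    schema_version: int = CONFIG_SCHEMA_VERSION

    def validate(self) -> None:
        if self.te_site_threshold < 0 or self.max_mismatch < 0:
            raise ConfigurationError("thresholds must be nonnegative")
        for attr in ("genome_fasta", "annotations_bed", "plate_sheet",
                     "fastq_r1", "fastq_r2", "counts_tsv"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{attr} path does not exist: {p}")
        if not self.simulate and (self.fastq_r1 is None
                                  or self.fastq_r2 is None):
            raise ConfigurationError(
                "fastq inputs required when simulation is disabled")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        version = data.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported config schema version {version}")
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the manifest dict (also written).

    Output layout under ``out_dir``: pooled FASTQ + truth table (when
    simulating), per-cell .cov files, summary.tsv, bootstrap.tsv
    (optional), correlation.tsv (when counts provided or simulated).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        manifest: dict = {"stages": [], "outputs": {}}

        # ---- reference ------------------------------------------------
        stage = "reference"
        if config.genome_fasta:
            genome = io.read_fasta(config.genome_fasta)
            annots = io.read_bed(config.annotations_bed)
            plate = io.read_plate(config.plate_sheet)
        else:
            cons = reference.build_consensus(
                config.consensus_length, config.cpg_density, config.seed)
            genome, annots = reference.synth_genome(
                cons, config.n_te_copies, config.divergence,
                seed=config.seed + 1)
            plate = reference.design_plate(cons, 96, seed=config.seed + 2)
            io.write_fasta(genome, out / "genome.fa")
            io.write_bed(annots, out / "annotations.bed")
            io.write_plate(plate, out / "plate.tsv")
        manifest["stages"].append(stage)

        # ---- simulate -------------------------------------------------
        truths = {}
        if config.simulate:
            stage = "simulate"
            levels = config.true_methylation
            well_list = list(plate.wells)
            params = [
                simulate.CellSimParams(
                    cell_id=f"cell{i:03d}",
                    well_id=well_list[i],
                    true_methylation=levels[i % len(levels)],
                    conversion_failure=config.conversion_failure,
                    inappropriate_conversion=config.inappropriate_conversion,
                    amp_bias=config.amp_bias,
                    n_read_pairs=config.n_read_pairs,
                    seq_error=config.seq_error,
                    seed=simulate.derive_cell_seed(config.seed, i),
                )
                for i in range(config.n_cells)
            ]
            pooled, truth_table, truths = simulate.simulate_plate(
                genome, annots, plate, params, seed=config.seed)
            io.write_fastq_pairs(pooled, out / "pool_R1.fastq.gz",
                                 out / "pool_R2.fastq.gz")
            truth_table.to_csv(out / "truth.tsv", sep="\t", index=False)
            manifest["stages"].append(stage)
        else:
            pooled = io.read_fastq_pairs(config.fastq_r1, config.fastq_r2)

        # ---- demux ----------------------------------------------------
        stage = "demux"
        by_well, report = demux_mod.demultiplex(
            pooled, plate, max_mismatch=config.max_mismatch)
        report.to_frame().to_csv(out / "demux_report.tsv", sep="\t",
                                 index=False)
        manifest["stages"].append(stage)
        manifest["demux"] = {"total": report.total,
                             "unassigned": report.unassigned,
                             "ambiguous": report.ambiguous}

        # ---- align + methylation per well -----------------------------
        stage = "align"
        ref = methylation.BisulfiteReference(genome)
        summaries = []
        covs: dict[str, pd.DataFrame] = {}
        calls_by_cell: dict[str, pd.DataFrame] = {}
        well_to_cell = ({p.well_id: p.cell_id for p in params}
                        if config.simulate else {})
        for wid, well_pairs in sorted(by_well.items()):
            if not well_pairs:
                continue
            cell_id = well_to_cell.get(wid, wid)
            trimmed, _ = demux_mod.trim_all(well_pairs, config.trim5,
                                            config.trim3)
            aligned = methylation.align_pairs(
                trimmed, ref, max_mismatch_rate=config.max_mismatch_rate)
            calls = methylation.extract_methylation(aligned, trimmed, ref)
            cov = methylation.cov_from_calls(calls, ref)
            chg, chh, _flag = methylation.conversion_qc(calls)
            cm = methylation.cell_methylation(
                cov, annots, config.te_site_threshold, cell_id=cell_id,
                chg_rate=chg, chh_rate=chh, n_aligned_reads=len(aligned))
            summaries.append(cm)
            covs[cell_id] = cov
            calls_by_cell[cell_id] = calls
            io.write_cov(cov, out / f"{cell_id}.cov")
        io.write_summary_tsv(summaries, out / "summary.tsv")
        manifest["stages"].append(stage)

        # ---- bootstrap (optional) -------------------------------------
        if config.run_bootstrap and calls_by_cell:
            stage = "bootstrap"
            rows = []
            for cell_id, calls in calls_by_cell.items():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    table, _ = methylation.bootstrap_stability(
                        calls, config.bootstrap_depths,
                        config.bootstrap_reps, seed=config.seed)
                table.insert(0, "cell_id", cell_id)
                rows.append(table)
            pd.concat(rows, ignore_index=True).to_csv(
                out / "bootstrap.tsv", sep="\t", index=False)
            manifest["stages"].append(stage)

        # ---- correlate -------------------------------------------------
        counts = None
        if config.counts_tsv:
            counts = io.read_counts_tsv(config.counts_tsv)
        elif config.simulate and truths:
            counts = simulate.simulate_expression(
                n_genes=300, n_tes=50,
                cells=[(c.cell_id, c.true_methylation)
                       for c in truths.values()],
                planted=[(0, 1, 4.0), (1, -1, 4.0)],
                seed=config.seed + 3)
            io.write_counts_tsv(counts, out / "counts.tsv")
        if counts is not None:
            stage = "correlate"
            summary_df = pd.DataFrame(
                [(c.cell_id, c.mean_site_methylation, c.qc_pass)
                 for c in summaries],
                columns=["cell_id", "meth", "qc_pass"])
            passing = summary_df[summary_df["qc_pass"]]
            if len(passing) >= 3:
                meth = passing.set_index("cell_id")["meth"]
                min_reads, min_cells = integrate.FILTER_PRESETS["standard"]
                # the inclusion rule presumes a plate-scale experiment;
                # cap the cell threshold at the cells actually present
                min_cells = min(min_cells, counts.shape[1])
                filt = integrate.filter_features(counts, min_reads,
                                                 min_cells)
                norm = integrate.normalize_expression(filt)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    results = integrate.correlate_methylation_expression(
                        meth, norm)
                integrate.results_frame(results).to_csv(
                    out / "correlation.tsv", sep="\t", index=False)
                integrate.export_ranked_genes(
                    results, counts, config.fdr_threshold,
                    out / "significant_genes.txt",
                    out / "background_genes.txt")
                manifest["stages"].append(stage)
            else:
                warnings.warn("fewer than 3 QC-passing cells; "
                              "correlation skipped")

        # ---- manifest --------------------------------------------------
        stage = "manifest"
        for p in sorted(out.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest["outputs"][p.name] = _sha256(p)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        quarantine = out / "quarantine"
        quarantine.mkdir(exist_ok=True)
        for p in list(out.iterdir()):
            if p.is_file():
                shutil.move(str(p), quarantine / p.name)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc
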