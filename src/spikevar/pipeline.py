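"""End-to-end pipeline: QC -> normalization -> technical model ->
variance decomposition -> stochastic-ASE test.

A single global seed is fanned out to per-stage child seeds by fixed
offsets, so each stage is individually re-runnable; the manifest written at
the end (inputs, parameter echo, seed, stage outputs) fully determines a
bit-identical reproduction.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as svio
from . import normalization as norm
from .ase import StochasticASETest, monoallelic_summary, ratio_profile
from .datatypes import CountMatrix
from .decomposition import VarianceDecomposer, summarize_frac_bio_by_expression
from .qc import CellFilterParams, filter_cells, write_filter_summary
from .technical import TechnicalNoiseModel

STAGE_SEED_OFFSETS = {
    "qc": 0,
    "normalize": 1,
    "fit_technical": 2,
    "decompose": 3,
    "ase": 4,
}


@dataclass
class RunConfig:
    """Pipeline configuration; mirrors the YAML config file layout."""

    counts: str = ""
    spikein_reference: str = ""
    cell_qc: str | None = None
    alleles: str | None = None
    outdir: str = "spikevar_out"
    seed: int = 0
    spikein_pattern: str = "ERCC-"
    # qc thresholds
    min_spikein_transcripts: float = 500
    min_endogenous_transcripts: float = 10_000
    min_exon_reads: float = 500_000
    min_exon_fraction: float = 0.5
    max_mito_fraction: float = 0.10
    # model
    gamma_floor: float = 0.01
    fit_method: str = "matching"
    efficiency_source: str = "empirical_resample"
    # decomposition
    n_boot: int = 100
    # ase test
    n_sim: int = 10_000
    n_pseudo_cells: int | None = None
    alpha: float = 0.001
    min_cells: int = 1
    ase_level: str = "gene"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}
        for key, value in payload.items():
            if isinstance(value, dict):  # sections are flattened
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def cell_filter_params(self) -> CellFilterParams:
        return CellFilterParams(
            min_spikein_transcripts=self.min_spikein_transcripts,
            min_endogenous_transcripts=self.min_endogenous_transcripts,
            min_exon_reads=self.min_exon_reads,
            min_exon_fraction=self.min_exon_fraction,
            max_mito_fraction=self.max_mito_fraction,
        )


@dataclass
class PipelineResult:
    exit_status: int
    manifest: dict
    outputs: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow and write all stage outputs + manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    artifacts: dict[str, str] = {}

    def log(stage: str, message: str) -> None:
        log_lines.append(f"[{stage}] {message}")

    stage = "load"
    try:
        matrix = svio.load_count_matrix(
            config.counts, spikein_pattern=config.spikein_pattern
        )
        reference = svio.load_spikein_reference(config.spikein_reference)
        qc_table = svio.load_cell_qc(config.cell_qc) if config.cell_qc else None
        log(stage, f"{matrix.counts.shape[0]} genes x {matrix.n_cells} cells")

        stage = "qc"
        result = filter_cells(matrix, qc_table, config.cell_filter_params())
        path = outdir / "cell_filter.tsv"
        write_filter_summary(result, path)
        artifacts["cell_filter"] = str(path)
        log(stage, f"cells kept {result.n_kept} / {matrix.n_cells}")
        if result.n_kept < 3:
            raise ValueError("fewer than 3 cells pass QC")
        matrix = matrix.subset_cells(result.kept)

        stage = "normalize"
        n_batches = matrix.cell_batch.nunique()
        if n_batches > 1:
            batch_eta = norm.estimate_batch_efficiency(matrix, reference)
            matrix_model = norm.normalize_by_batch_efficiency(matrix, batch_eta)
            log(stage, f"batch E[eta]: {batch_eta.round(4).to_dict()}")
        else:
            matrix_model = matrix
            log(stage, "single batch; raw counts used for model fitting")
        factors = norm.compute_both_size_factors(matrix)
        factors_frame = factors.technical.to_frame("technical")
        factors_frame["biological"] = factors.biological
        path = outdir / "size_factors.tsv"
        factors_frame.to_csv(path, sep="\t", index_label="cell_id")
        artifacts["size_factors"] = str(path)

        stage = "fit_technical"
        model = TechnicalNoiseModel(
            gamma_floor=config.gamma_floor,
            fit_method=config.fit_method,
            random_state=config.seed + STAGE_SEED_OFFSETS["fit_technical"],
        ).fit(matrix_model, reference)
        path = outdir / "technical_model.json"
        model.save(path)
        artifacts["technical_model"] = str(path)
        cv2 = model.predicted_spikein_cv2(matrix_model, reference)
        path = outdir / "spikein_cv2.tsv"
        cv2.to_csv(path, sep="\t", index_label="spike_id")
        artifacts["spikein_cv2"] = str(path)
        log(
            stage,
            "mu_eta=%.4g A=%.4g B=%.4g" % (model.mu_eta_, model.A_, model.B_),
        )

        stage = "decompose"
        decomposer = VarianceDecomposer(
            model,
            n_boot=config.n_boot,
            random_state=config.seed + STAGE_SEED_OFFSETS["decompose"],
        ).fit(matrix_model, reference)
        path = outdir / "decomposition.tsv"
        decomposer.results_.to_csv(path, sep="\t", index_label="gene_id")
        artifacts["decomposition"] = str(path)
        summary = summarize_frac_bio_by_expression(decomposer.results_)
        path = outdir / "frac_bio_summary.tsv"
        summary.to_csv(path, sep="\t", index=False)
        artifacts["frac_bio_summary"] = str(path)
        log(stage, f"genes decomposed {len(decomposer.results_)}")

        stage = "ase"
        if config.alleles:
            alleles = svio.load_allele_counts(config.alleles)
            keep = alleles.records["cell_id"].isin(matrix.cell_ids)
            from .datatypes import AlleleCountTable

            alleles = AlleleCountTable(records=alleles.records[keep])
            test = StochasticASETest(
                model,
                n_sim=config.n_sim,
                n_cells=config.n_pseudo_cells,
                alpha=config.alpha,
                min_cells=config.min_cells,
                level=config.ase_level,
                efficiency_source=config.efficiency_source,
                random_state=config.seed + STAGE_SEED_OFFSETS["ase"],
            ).fit(alleles)
            path = outdir / "ase_test.tsv"
            test.results_.to_csv(path, sep="\t", index_label="unit")
            artifacts["ase_test"] = str(path)
            mono = monoallelic_summary(alleles)
            profile = ratio_profile(
                alleles,
                model,
                seed=config.seed + STAGE_SEED_OFFSETS["ase"],
                level=config.ase_level,
            )
            path = outdir / "ratio_profile.tsv"
            profile.to_csv(path, sep="\t", index=False)
            artifacts["ratio_profile"] = str(path)
            n_called = int(test.results_["significant"].sum())
            n_tested = int(test.results_["p_emp"].notna().sum())
            log(
                stage,
                f"units tested {n_tested}, called {n_called} at "
                f"alpha={config.alpha}; monoallelic unit fraction "
                f"{mono['frac_units_flagged']:.3f}",
            )
        else:
            log(stage, "no allele table supplied; ASE stage skipped")
    except Exception as exc:  # pragma: no cover - exercised via tests
        log(stage, f"ERROR: {exc}")
        (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest = {
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": asdict(config),
        "seed": config.seed,
        "stage_seed_offsets": STAGE_SEED_OFFSETS,
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(exit_status=0, manifest=manifest, outputs=artifacts)


def run_from_manifest(path: str | Path) -> PipelineResult:
    """Re-run a pipeline from its manifest; reproduces outputs bit-exactly."""
    manifest = json.loads(Path(path).read_text())
    return run_pipeline(RunConfig(**manifest["config"]))
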