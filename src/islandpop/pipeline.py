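"""End-to-end analysis pipeline: QC -> diversity/inbreeding ->
relatedness/structure -> differentiation -> panel assignment.

Configured from a single TOML file; every stage writes TSV reports plus
a run log, and the whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

import sys
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, io, panel, qc, relatedness, simulate
from .dataset import DistanceMatrixExport, GenotypeDataset
from .differentiation import nei_distance_matrix, pairwise_fst_bootstrap, wc_fst

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "REPORT_FILES"]

#: Files a full run writes into the output directory.
REPORT_FILES = (
    "qc_report.tsv",
    "heterozygosity.tsv",
    "inbreeding.tsv",
    "roh_segments.tsv",
    "pihat.tsv",
    "grm.tsv",
    "pca_scores.tsv",
    "cluster_labels.tsv",
    "fst_pairwise.tsv",
    "nei_distances.tsv",
    "nei_distances.nex",
    "panel_grid.tsv",
)


@dataclass
class PipelineConfig:
    """All stage inputs and thresholds (defaults mirror the standard
    SNP-array protocol: 0.95/0.95/0.05/1e-4 QC, 50/5/0.5 LD pruning,
    25 SNP/1 Mb/1 het/1 missing/1 Mb-gap ROH, 2,610 Mb genome,
    1000 bootstraps at 0.95 CI, panels 25-150 x PCs 1-10)."""

    # input: either PLINK paths or a simulation config
    ped: str | None = None
    map: str | None = None
    bed: str | None = None
    bim: str | None = None
    fam: str | None = None
    metadata: str | None = None
    simulate: dict | None = None

    out_dir: str = "islandpop_out"
    seed: int = 17

    sample_call_rate: float = 0.95
    snp_call_rate: float = 0.95
    maf: float = 0.05
    hwe_p: float = 1e-4
    ld_window: int = 50
    ld_step: int = 5
    ld_r2: float = 0.50

    roh_min_snps: int = 25
    roh_min_length_bp: float = 1e6
    roh_max_het: int = 1
    roh_max_missing: int = 1
    roh_max_gap_bp: float = 1e6
    genome_length_bp: float = diversity.DEFAULT_GENOME_LENGTH_BP

    n_boot: int = 1000
    ci: float = 0.95
    kmeans_k: tuple[int, ...] = tuple(range(2, 9))
    n_pcs: int = 10
    panel_sizes: tuple[int, ...] = panel.DEFAULT_PANEL_SIZES
    pc_counts: tuple[int, ...] = panel.DEFAULT_PC_COUNTS
    panel_pooled: bool = False
    panel_nested: bool = False

    stages: tuple[str, ...] = (
        "qc", "diversity", "relatedness", "differentiation", "panel",
    )


def load_config(path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PipelineConfig(**raw)
    for name in ("kmeans_k", "panel_sizes", "pc_counts", "stages"):
        setattr(cfg, name, tuple(getattr(cfg, name)))
    return cfg


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_input(config: PipelineConfig) -> GenotypeDataset:
    meta = (
        io.read_sample_metadata(config.metadata) if config.metadata else None
    )
    if config.simulate is not None:
        sim_cfg = simulate.SimConfig(**config.simulate)
        rng = np.random.default_rng(config.seed)
        ds, _truth = simulate.simulate_dataset(sim_cfg, rng)
        return ds
    if config.bed:
        return io.read_plink_binary(config.bed, config.bim, config.fam, meta)
    if config.ped:
        return io.read_plink_text(config.ped, config.map, meta)
    raise ValueError("config must name PLINK input or a [simulate] section")


def run_pipeline(config: PipelineConfig, log=None) -> dict:
    """Run all enabled stages, writing reports under ``config.out_dir``.

    Returns a dict of in-memory results keyed by stage.  On a stage
    failure a :class:`PipelineError` is raised; reports already written
    are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    results: dict = {}

    def emit(msg: str) -> None:
        line = f"[{time.strftime('%H:%M:%S')}] {msg}"
        log_lines.append(line)
        print(line, file=log or sys.stderr)

    emit(f"seed={config.seed} out_dir={out}")
    t0 = time.time()
    stage = "input"
    try:
        ds = _load_input(config)
        emit(f"input: {ds.n_samples} samples x {ds.n_snps} SNPs")

        if "qc" in config.stages:
            stage = "qc"
            ds, report = qc.run_qc(
                ds,
                config.sample_call_rate,
                config.snp_call_rate,
                config.maf,
                config.hwe_p,
                config.ld_window,
                config.ld_step,
                config.ld_r2,
            )
            report.write_tsv(out / "qc_report.tsv")
            results["qc"] = report
            emit(f"qc: retained {ds.n_samples} samples x {ds.n_snps} SNPs")
        else:
            (out / "qc_report.tsv").write_text("# qc disabled\n")
            emit("qc: disabled")
        results["dataset"] = ds
        islands = ds.samples["island"].to_numpy()
        herds = ds.samples["herd"].to_numpy()

        if "diversity" in config.stages:
            stage = "diversity"
            het_isl = diversity.heterozygosity_stats(ds, islands)
            het_herd = diversity.heterozygosity_stats(ds, herds)
            het = pd.concat(
                [het_isl.assign(level="island"), het_herd.assign(level="herd")]
            )
            het.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
            fis = diversity.fis_per_sample(ds)
            segments = diversity.detect_roh(
                ds,
                config.roh_min_snps,
                config.roh_min_length_bp,
                config.roh_max_het,
                config.roh_max_missing,
                config.roh_max_gap_bp,
            )
            segments.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
            fr = diversity.froh(
                segments, ds.samples["sample_id"], config.genome_length_bp
            )
            inbreeding = fis.merge(fr, on="sample_id")
            inbreeding.to_csv(out / "inbreeding.tsv", sep="\t", index=False)
            results["diversity"] = {
                "heterozygosity": het,
                "inbreeding": inbreeding,
                "roh": segments,
            }
            emit(f"diversity: {len(segments)} ROH segments")

        if "relatedness" in config.stages:
            stage = "relatedness"
            pih = relatedness.pihat_matrix(ds)
            pih.to_csv(out / "pihat.tsv", sep="\t", index=False)
            a = relatedness.grm(ds)
            tri = np.triu_indices(ds.n_samples)
            pd.DataFrame(
                {
                    "id1": np.asarray(a.sample_ids)[tri[0]],
                    "id2": np.asarray(a.sample_ids)[tri[1]],
                    "value": a.values[tri],
                    "n_loci": a.n_loci[tri],
                }
            ).to_csv(out / "grm.tsv", sep="\t", index=False)
            sim, labels = relatedness.similarity_and_kmeans(
                a, config.kmeans_k, seed=config.seed
            )
            pd.DataFrame(
                {f"k{k}": v for k, v in labels.items()},
                index=a.sample_ids,
            ).rename_axis("sample_id").to_csv(out / "cluster_labels.tsv", sep="\t")
            pcares = relatedness.pca(a, min(config.n_pcs, ds.n_samples))
            scores = pd.DataFrame(
                pcares.scores,
                columns=[f"PC{i + 1}" for i in range(pcares.scores.shape[1])],
            )
            scores.insert(0, "sample_id", a.sample_ids)
            scores.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
            results["relatedness"] = {
                "pihat": pih,
                "grm": a,
                "similarity": sim,
                "clusters": labels,
                "pca": pcares,
            }
            emit(
                "relatedness: PC1 variance fraction "
                f"{pcares.variance_fraction[0]:.3f}"
            )

        if "differentiation" in config.stages:
            stage = "differentiation"
            fst = pairwise_fst_bootstrap(
                ds, herds, config.n_boot, config.ci, config.seed
            )
            pd.DataFrame(
                [
                    (r.group_a, r.group_b, r.theta, r.ci_lower, r.ci_upper,
                     r.n_boot, r.n_loci)
                    for r in fst
                ],
                columns=[
                    "group_a", "group_b", "theta", "ci_lower", "ci_upper",
                    "n_boot", "n_loci",
                ],
            ).to_csv(out / "fst_pairwise.tsv", sep="\t", index=False)
            labels_nei, dist = nei_distance_matrix(ds, herds)
            pd.DataFrame(dist, index=labels_nei, columns=labels_nei).rename_axis(
                "herd"
            ).to_csv(out / "nei_distances.tsv", sep="\t")
            io.export_distance_nexus(
                DistanceMatrixExport(labels_nei, dist), out / "nei_distances.nex"
            )
            _, theta_islands = wc_fst(
                ds, islands, *pd.unique(islands)[:2]
            )
            herd_mean = float(np.mean([r.theta for r in fst]))
            results["differentiation"] = {
                "fst": fst,
                "nei": (labels_nei, dist),
                "overall_fst_islands": theta_islands,
                "mean_herd_pair_fst": herd_mean,
            }
            emit(
                f"differentiation: island-vs-island theta={theta_islands:.4f}, "
                f"mean herd-pair theta={herd_mean:.4f}"
            )

        if "panel" in config.stages:
            stage = "panel"
            grid = panel.grid_evaluate(
                ds,
                islands,
                config.panel_sizes,
                config.pc_counts,
                pooled=config.panel_pooled,
                nested=config.panel_nested,
            )
            grid.to_csv(out / "panel_grid.tsv", sep="\t", index=False)
            results["panel"] = grid
            emit(f"panel: {len(grid)} grid cells")
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        emit(f"FAILED in stage {stage}: {exc}")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(stage, exc) from exc

    emit(f"done in {time.time() - t0:.1f}s")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results
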