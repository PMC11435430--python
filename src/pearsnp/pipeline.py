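"""End-to-end orchestration: simulate or load a collection, filter markers,
compute diversity and differentiation tables, build nested core panels, and
score variety identification.

Every stage is importable on its own; :func:`run_pipeline` chains them,
writes the report bundle under a run directory, and records every threshold
and seed in a manifest.  Given identical inputs, configuration and seed the
outputs are numerically identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, genotype_io, identification, marker_stats, panel_design, popgen
from .genotype_io import GenotypeMatrix, PopulationAssignment
from .synthetic_data import SimulationConfig, simulate_genotypes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds and paths.

    Defaults reproduce the published workflow's stated settings: MAF > 0.05,
    missing rate < 0.15, minimum depth 3x, PIC > 0.25, heterozygosity rate
    < 0.35, 10,000 permutations, nested subset sizes (192, 96, 48, 24).
    """

    vcf: str | None = None
    metadata: str | None = None
    outdir: str = "results/run"
    maf_min: float = 0.05
    missing_max: float = 0.15
    depth_min: int = 3
    pic_min: float = 0.25
    het_max: float = 0.35
    min_spacing_bp: int = 500_000
    panel_target: int = 232
    subset_sizes: tuple[int, ...] = (192, 96, 48, 24)
    n_perm: int = 10_000
    min_shared: int | None = None
    make_plots: bool = False
    seed: int = 0


def run_simulate(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate a dataset and write it in the pipeline's input dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, populations, params = simulate_genotypes(config)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "metadata": outdir / "populations.csv",
        "true_freqs": outdir / "true_allele_frequencies.csv",
        "true_params": outdir / "true_parameters.json",
    }
    genotype_io.write_vcf(matrix, paths["vcf"])
    genotype_io.write_population_table(populations, paths["metadata"])
    freq = pd.DataFrame(
        params.pop_alt_freq.T,
        columns=list(params.labels),
    )
    freq.insert(0, "marker_id", matrix.marker_ids)
    freq.insert(1, "ancestral_alt_freq", params.ancestral_alt_freq)
    freq.to_csv(paths["true_freqs"], index=False)
    paths["true_params"].write_text(
        json.dumps(
            {
                "labels": list(params.labels),
                "divergence_F": list(params.divergence_F),
                "seed": config.seed,
            },
            indent=2,
        )
    )
    logger.info("simulated %d accessions x %d loci -> %s",
                matrix.n_accessions, matrix.n_loci, outdir)
    return paths


def run_pipeline(
    config: RunConfig,
    matrix: GenotypeMatrix | None = None,
    populations: PopulationAssignment | None = None,
) -> dict:
    """Run filter -> stats -> popgen -> clustering -> panels -> identification.

    Inputs come either from ``config.vcf``/``config.metadata`` or directly as
    in-memory objects.  Returns a dict of the in-memory results; the report
    bundle is written under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if matrix is None:
        if config.vcf is None:
            raise ValueError("run_pipeline needs either a matrix or config.vcf")
        matrix = genotype_io.read_vcf(config.vcf)
    if populations is None:
        if config.metadata is None:
            raise ValueError("run_pipeline needs either populations or config.metadata")
        populations = genotype_io.read_population_table(config.metadata)
    populations.validate(matrix)

    results: dict = {"config": dataclasses.asdict(config)}

    # --- stage: marker filter -------------------------------------------
    filtered, report = marker_stats.filter_loci(
        matrix,
        maf_min=config.maf_min,
        missing_max=config.missing_max,
        depth_min=config.depth_min,
    )
    report.to_frame().to_csv(out / "filter_report.csv", index=False)
    stats = marker_stats.locus_stats_frame(filtered)
    stats.to_csv(out / "locus_stats.csv", index=False)
    results["filtered"] = filtered
    results["filter_report"] = report
    results["locus_stats"] = stats

    # --- stage: diversity and differentiation ---------------------------
    diversity = marker_stats.diversity_table(filtered, populations)
    diversity.to_csv(out / "diversity_by_population.csv", index=False)
    results["diversity"] = diversity

    if len(populations.labels) >= 2:
        square, tidy = popgen.pairwise_analysis(
            filtered, populations, n_perm=config.n_perm, seed=config.seed
        )
        square.to_csv(out / "pairwise_fst_nei.csv")
        tidy.to_csv(out / "pairwise_tests.csv", index=False)
        results["pairwise_square"] = square
        results["pairwise_tidy"] = tidy
    else:
        logger.warning("only one population label: skipping pairwise statistics")
        results["pairwise_square"] = None
        results["pairwise_tidy"] = None

    # --- stage: structure ------------------------------------------------
    scores, explained = clustering.pca_genotypes(filtered)
    pc = pd.DataFrame(
        scores[:, :10],
        columns=[f"PC{i + 1}" for i in range(min(10, scores.shape[1]))],
    )
    pc.insert(0, "accession_id", filtered.accessions)
    pc.to_csv(out / "pca_scores.csv", index=False)
    pd.DataFrame(
        {"component": np.arange(1, len(explained) + 1), "explained_fraction": explained}
    ).to_csv(out / "pca_explained.csv", index=False)
    results["pca_scores"] = scores
    results["pca_explained"] = explained
    if config.make_plots:
        clustering.plot_pca(
            scores, explained, populations, filtered.accessions,
            str(out / "pca.png"),
        )

    # --- stage: panels ----------------------------------------------------
    candidates = marker_stats.core_candidate_gate(
        stats, pic_min=config.pic_min, het_max=config.het_max
    )
    target = min(config.panel_target, len(candidates))
    if target < config.panel_target:
        logger.warning(
            "only %d gated candidates; reducing panel target from %d",
            len(candidates), config.panel_target,
        )
    panel = panel_design.select_core_panel(
        stats,
        target_size=target,
        pic_min=config.pic_min,
        het_max=config.het_max,
        min_spacing_bp=config.min_spacing_bp,
    )
    sizes = [s for s in config.subset_sizes if s < panel.size]
    subsets = panel_design.nested_subsets(panel, sizes) if sizes else []
    chain = [panel, *subsets]
    for p in chain:
        p.to_frame().to_csv(out / f"panel_{p.size}.csv", index=False)
    results["panels"] = chain

    # --- stage: identification -------------------------------------------
    reports = identification.evaluate_panels(
        filtered, chain, min_shared=config.min_shared
    )
    summary = pd.DataFrame([r.summary() for r in reports])
    summary.to_csv(out / "identification_summary.csv", index=False)
    for rep in reports:
        rep.to_frame().to_csv(out / f"groups_{rep.panel_id}.csv", index=False)
    results["identification"] = reports

    # --- dendrograms ------------------------------------------------------
    newicks = {}
    for p in chain:
        dist = clustering.euclidean_distances(filtered.subset_loci(p.markers))
        tree = clustering.upgma(dist)
        nw_path = out / f"upgma_{p.size}.nwk"
        nw_path.write_text(tree.to_newick() + "\n")
        newicks[p.size] = tree
        if config.make_plots:
            clustering.plot_dendrogram(tree, str(out / f"upgma_{p.size}.png"))
    results["dendrograms"] = newicks

    manifest = {
        "thresholds": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in {"vcf", "metadata", "outdir"}
        },
        "n_accessions": matrix.n_accessions,
        "n_loci_input": matrix.n_loci,
        "n_loci_filtered": filtered.n_loci,
        "panel_sizes": [p.size for p in chain],
        "identification_rates": {
            r.panel_id: r.identification_rate for r in reports
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results
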