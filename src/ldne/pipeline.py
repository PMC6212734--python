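"""Pipeline orchestration: configuration, staged execution, figures, PCA.

A run is driven by a structured YAML configuration and persists every
intermediate table to the artifact directory as TSV, so each stage can
be re-run from the previous stage's files and a full rerun with the
same config and seed reproduces all tables bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ldne import ancestral_ne, decay_fit, io_formats, ld_engine, meta_pool, qc, synthetic_data
from ldne.io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "output_dir", "input", "sample", "qc", "ld", "fit", "meta", "ancestral", "pca"},
    "input": {"ped", "map", "vcf", "linkage_map", "simulate"},
    "input.simulate": {
        "n_chromosomes",
        "chrom_length_bp",
        "recomb_rate",
        "founder_snps_per_chromosome",
        "ne_history",
        "interpolation",
        "burn_in_generations",
        "founder_maf_range",
        "n_output_individuals",
    },
    "sample": {"n_individuals", "missing_rate"},
    "qc": {"hwe_p_max", "missing_max", "maf_min", "hwe_test", "impute_method", "autosomes"},
    "ld": {"k_adjacent", "bin_classes"},
    "fit": {"init_a", "use_corrected_r2", "bin_means"},
    "meta": {"method"},
    "ancestral": {"grid", "bin_policy", "bin_param", "min_pairs", "use_corrected_r2"},
    "pca": {"enabled"},
}


def _check_keys(cfg: dict, section: str = "") -> None:
    allowed = _SCHEMA.get(section)
    if allowed is None:
        return
    unknown = set(cfg) - allowed
    if unknown:
        where = section or "top level"
        raise ValueError(f"unknown configuration keys at {where}: {sorted(unknown)}")
    for key, val in cfg.items():
        if isinstance(val, dict):
            _check_keys(val, f"{section}.{key}".lstrip("."))


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline configuration (unknown keys rejected)."""
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "input" not in cfg:
        raise ValueError("configuration must be a mapping with an 'input' section")
    _check_keys(cfg)
    return cfg


def _scenario_from_config(sim_cfg: dict, seed: int) -> synthetic_data.DemographicScenario:
    n_chrom = int(sim_cfg.get("n_chromosomes", 18))
    length = int(sim_cfg.get("chrom_length_bp", 10_000_000))
    rate = float(sim_cfg.get("recomb_rate", 1e-8))
    m = int(sim_cfg.get("founder_snps_per_chromosome", 650))
    history = [(int(g), int(ne)) for g, ne in sim_cfg.get("ne_history", [[1, 100]])]
    return synthetic_data.DemographicScenario(
        chromosomes=[(length, rate)] * n_chrom,
        snp_counts=[m] * n_chrom,
        ne_history=history,
        interpolation=sim_cfg.get("interpolation", "constant"),
        burn_in_generations=sim_cfg.get("burn_in_generations"),
        founder_maf_range=tuple(sim_cfg.get("founder_maf_range", (0.05, 0.5))),
        n_output_individuals=sim_cfg.get("n_output_individuals"),
        seed=seed,
    )


def _acquire_genotypes(cfg: dict, outdir: Path):
    """Load or simulate the input cohort; returns (G, snp_map, chrom_map)."""
    inp = cfg["input"]
    seed = int(cfg.get("seed", 0))
    if "simulate" in inp:
        scenario = _scenario_from_config(inp["simulate"], seed)
        cohort = synthetic_data.simulate_population(scenario)
        sample = cfg.get("sample", {})
        if sample:
            G, snp_map = synthetic_data.sample_genotypes(
                cohort,
                int(sample.get("n_individuals", cohort.genotypes.n)),
                float(sample.get("missing_rate", 0.0)),
                seed=seed + 1,
            )
        else:
            G, snp_map = cohort.genotypes, cohort.snp_map
        truth = pd.DataFrame(
            [(g, ne) for g, ne in scenario.ne_history],
            columns=["generations_before_present", "ne"],
        )
        io_formats.write_table(truth, outdir / "truth_ne_history.tsv")
        io_formats.write_ped_map(G, snp_map, outdir / "genotypes.ped", outdir / "genotypes.map")
        chrom_map = cohort.chrom_map
    elif "vcf" in inp:
        G, snp_map = io_formats.read_vcf(inp["vcf"])
        chrom_map = io_formats.read_linkage_map(inp["linkage_map"])
    else:
        G, snp_map = io_formats.read_ped_map(inp["ped"], inp["map"])
        chrom_map = io_formats.read_linkage_map(inp["linkage_map"])
    io_formats.write_table(chrom_map, outdir / "chrom_map.tsv")
    return G, snp_map, chrom_map


def run_pipeline(config, output_dir=None) -> Path:
    """Execute simulate/load -> QC -> LD -> fit -> pool -> ancestral.

    Every stage's table is persisted in the artifact directory; the run
    manifest (config echo, stage timings, record counts) is written on
    success and on failure.
    """
    cfg = load_config(config)
    outdir = Path(output_dir or cfg.get("output_dir", "ldne_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"config": cfg, "seed": seed, "stages": {}, "version": 1}
    t_all = time.perf_counter()

    def _stage(name: str):
        manifest["stages"][name] = {"start": time.perf_counter() - t_all}

    def _done(name: str, **counts) -> None:
        entry = manifest["stages"][name]
        entry["seconds"] = time.perf_counter() - t_all - entry.pop("start")
        entry.update(counts)

    try:
        _stage("acquire")
        G, snp_map, chrom_map = _acquire_genotypes(cfg, outdir)
        _done("acquire", n_individuals=G.n, n_snps=G.n_snps)

        _stage("qc")
        qc_cfg = cfg.get("qc", {})
        thresholds = qc.QcThresholds(
            hwe_p_max=float(qc_cfg.get("hwe_p_max", 1e-6)),
            missing_max=float(qc_cfg.get("missing_max", 0.1)),
            maf_min=float(qc_cfg.get("maf_min", 0.05)),
        )
        autosomes = qc_cfg.get("autosomes")
        G_f, map_f, report = qc.apply_filters(
            G,
            snp_map,
            thresholds,
            autosomes=set(map(str, autosomes)) if autosomes else None,
            hwe_test=qc_cfg.get("hwe_test", "exact"),
        )
        G_f = qc.impute_missing(G_f, method=qc_cfg.get("impute_method", "mode"), seed=seed + 2)
        io_formats.write_table(report.to_frame(), outdir / "qc_report.tsv")
        _done("qc", n_retained=report.n_retained)

        _stage("ld")
        ld_cfg = cfg.get("ld", {})
        map_f = ld_engine.mb_to_cm(map_f, chrom_map)
        io_formats.write_table(map_f, outdir / "snp_map.tsv")
        table = ld_engine.compute_ld_table(
            G_f, map_f, k=int(ld_cfg.get("k_adjacent", 100)), apply_correction=True
        )
        io_formats.write_table(table, outdir / "ld_pairs.tsv")
        for cls in ld_cfg.get("bin_classes", ["A", "B"]):
            bins = ld_engine.bin_pairs(table, cls)
            io_formats.write_table(bins, outdir / f"bins_{cls}.tsv")
        _done("ld", n_pairs=len(table), mean_r2=float(table["r2"].mean()))

        _stage("fit")
        fit_cfg = cfg.get("fit", {})
        fits = decay_fit.fit_all_chromosomes(
            table,
            value_col="r2_corrected" if fit_cfg.get("use_corrected_r2", False) else "r2",
            init_a=float(fit_cfg.get("init_a", 2.0)),
            bin_means=bool(fit_cfg.get("bin_means", False)),
        )
        io_formats.write_table(decay_fit.fits_to_frame(fits), outdir / "fits.tsv")
        _done("fit", n_chromosomes=len(fits))

        _stage("pool")
        pooled_a, pooled_b = meta_pool.pool_parameters(
            fits, method=cfg.get("meta", {}).get("method", "DL")
        )
        pooled = pd.DataFrame([pooled_a.to_row(), pooled_b.to_row()])
        io_formats.write_table(pooled, outdir / "pooled.tsv")
        _done("pool", current_ne=pooled_b.estimate)

        _stage("ancestral")
        anc_cfg = cfg.get("ancestral", {})
        grid_cfg = anc_cfg.get("grid", {})
        if isinstance(grid_cfg, list):
            grid = np.asarray(grid_cfg, dtype=float)
        else:
            grid = np.unique(
                np.round(
                    np.logspace(
                        np.log10(float(grid_cfg.get("lo", 10))),
                        np.log10(float(grid_cfg.get("hi", 100_000))),
                        int(grid_cfg.get("n", 40)),
                    )
                )
            )
        trajectory = ancestral_ne.build_trajectory(
            table,
            generation_grid=grid,
            bin_policy=(
                anc_cfg.get("bin_policy", "relative"),
                float(anc_cfg.get("bin_param", 0.2)),
            ),
            min_pairs=int(anc_cfg.get("min_pairs", 100)),
            correction=bool(anc_cfg.get("use_corrected_r2", True)),
        )
        io_formats.write_table(trajectory, outdir / "trajectory.tsv")
        _done("ancestral", n_points=len(trajectory))

        if cfg.get("pca", {}).get("enabled", False):
            _stage("pca")
            coords, explained = compute_pca(G_f)
            pca_df = pd.DataFrame(
                {"sample_id": G_f.sample_ids, "pc1": coords[:, 0], "pc2": coords[:, 1]}
            )
            io_formats.write_table(pca_df, outdir / "pca.tsv")
            _done("pca", explained_pc1=float(explained[0]), explained_pc2=float(explained[1]))

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, outdir)
        raise
    manifest["checksums"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        for p in sorted(outdir.glob("*.tsv"))
    }
    _write_manifest(manifest, outdir)
    return outdir


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def compute_pca(G: GenotypeMatrix, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA of column-standardized dosages (population-structure sanity check).

    Returns per-sample coordinates for the top components and their
    explained-variance fractions.
    """
    if G.n < 3:
        raise ValueError("PCA requires at least 3 samples")
    X = G.values.astype(float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    informative = sd > 0
    if not informative.any():
        raise ValueError("all SNP columns have zero variance")
    Z = (X[:, informative] - mean[informative]) / sd[informative]
    U, S, _ = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    var = S**2
    explained = var / var.sum()
    coords = U[:, :n_components] * S[:n_components]
    return coords, explained[:n_components]


def make_figures(artifact_dir) -> list[Path]:
    """Render the five standard report figures from persisted tables.

    1. binned LD decay (both distance-bin classes);
    2. SNPs per chromosome after QC;
    3. per-chromosome decay parameters vs chromosome genetic length;
    4. predicted (pooled a, b) vs observed binned r^2;
    5. Ne trajectory against past generations (log-log).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(artifact_dir)

    def _need(name: str) -> pd.DataFrame:
        path = outdir / name
        if not path.exists():
            raise FileNotFoundError(f"required table missing from artifact dir: {name}")
        return io_formats.read_table(path)

    written: list[Path] = []

    bins = {cls: _need(f"bins_{cls}.tsv") for cls in ("A", "B") if (outdir / f"bins_{cls}.tsv").exists()}
    if bins:
        fig, axes = plt.subplots(1, len(bins), figsize=(5 * len(bins), 4))
        for ax, (cls, b) in zip(np.atleast_1d(axes), bins.items()):
            ax.plot(b["median_of_range"], b["mean_r2"], "o-", ms=3)
            ax.set_xlabel("distance (Mb)")
            ax.set_ylabel("mean $r^2$")
            ax.set_title(f"bin class {cls}")
        fig.tight_layout()
        path = outdir / "fig1_ld_decay_bins.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    snp_map = _need("snp_map.tsv")
    counts = snp_map.groupby("chromosome").size()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(counts.index.astype(str), counts.to_numpy())
    ax.set_xlabel("chromosome")
    ax.set_ylabel("SNPs after QC")
    fig.tight_layout()
    path = outdir / "fig2_snps_per_chromosome.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fits = _need("fits.tsv")
    chrom_map = _need("chrom_map.tsv")
    merged = fits.merge(chrom_map, on="chromosome")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, param in zip(axes, ("a_hat", "b_hat")):
        ax.errorbar(
            merged["genetic_cm"],
            merged[param],
            yerr=merged["se_" + param[0]],
            fmt="o",
            ms=4,
            capsize=2,
        )
        ax.set_xlabel("chromosome length (cM)")
        ax.set_ylabel(param.replace("_hat", ""))
    fig.tight_layout()
    path = outdir / "fig3_parameters_by_chromosome.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    pooled = _need("pooled.tsv").set_index("parameter")
    if "B" in bins:
        b = bins["B"].dropna(subset=["mean_r2"])
        snp_map_rate = snp_map["position_morgans"].max() / max(snp_map["position_bp"].max(), 1)
        d = b["median_of_range"].to_numpy() * 1e6 * snp_map_rate
        pred = decay_fit.predict_r2(
            float(pooled.loc["a", "estimate"]), float(pooled.loc["b", "estimate"]), d
        )
        fig, ax = plt.subplots(figsize=(5.5, 4))
        ax.plot(b["median_of_range"], b["mean_r2"], "o", ms=3, label="observed")
        ax.plot(b["median_of_range"], pred, "-", label="predicted")
        ax.set_xlabel("distance (Mb)")
        ax.set_ylabel("$r^2$")
        ax.legend()
        fig.tight_layout()
        path = outdir / "fig4_predicted_vs_observed.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    trajectory = _need("trajectory.tsv")
    if trajectory.empty:
        logger.warning("trajectory table empty; Ne trajectory figure skipped")
    else:
        fig, ax = plt.subplots(figsize=(5.5, 4))
        ax.plot(trajectory["t"], trajectory["nt"], "o-", ms=3)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("generations before present")
        ax.set_ylabel("estimated $N_e$")
        fig.tight_layout()
        path = outdir / "fig5_ne_trajectory.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
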