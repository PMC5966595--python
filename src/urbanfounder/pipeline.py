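"""End-to-end pipeline wiring: filter → structure → summary stats →
reference table → rejection ABC → pooled trajectories, with a manifest
recording seeds, versions and output checksums."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, popstruct
from .genotypes import GenotypeMatrix, SampleInfo
from .inference import (
    ReferenceTable,
    SimulationConfig,
    build_reference_table,
    default_window_times,
    posterior_trajectory,
    rejection_abc,
)
from .sumstats import distance_bins_from_times, observed_summary_stats
from .synthetic import StudyDesign, generate_study_fixture
from .variant_io import FilterConfig, apply_site_filters, read_vcf, write_vcf

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML with flat overrides."""

    vcf: str = ""
    metadata: str = ""
    outdir: str = "results"
    seed: int = 1

    filter: FilterConfig = field(default_factory=FilterConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    design: StudyDesign = field(default_factory=StudyDesign)

    # analysis settings
    n_fst_perm: int = 1000
    n_mantel_perm: int = 1000
    n_mantel_boot: int = 1000
    ld_prune_window_bp: int = 50_000
    ld_prune_r2_max: float = 0.5
    min_scaffold_bp: float = 20_000_000
    maf_min: float = 0.15
    max_pairs_per_bin: int = 10_000
    n_reference_sims: int = 500
    acceptance_rate: float = 5e-5
    reference_table: str = ""  # reuse an existing table instead of building

    # stage toggles
    run_structure: bool = True
    run_abc: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("filter", FilterConfig),
            ("simulation", SimulationConfig),
            ("design", StudyDesign),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter"]["excluded_scaffolds"] = sorted(self.filter.excluded_scaffolds)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _pop_subset(gm: GenotypeMatrix, info: SampleInfo, pop: str):
    idx = info.indices_of(gm, pop)
    sub = gm.take_individuals(idx)
    tbl = (
        info.table.set_index("sample_id")
        .loc[sub.sample_ids]
        .reset_index()
    )
    return sub, SampleInfo(tbl)


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every enabled stage; returns the manifest dict.

    Any stage failure aborts with the stage name; outputs written so far
    stay on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
        "outputs": {},
    }
    stage = "load"
    try:
        for path, what in ((cfg.vcf, "VCF"), (cfg.metadata, "metadata")):
            if not path or not os.path.exists(path):
                raise FileNotFoundError(f"{what} file not found: {path!r}")
        gm, info = read_vcf(cfg.vcf, cfg.metadata)
        manifest["stages"]["load"] = {"n_individuals": gm.n_individuals, "n_sites": gm.n_sites}

        stage = "filter"
        gmf, report = apply_site_filters(gm, cfg.filter)
        manifest["stages"]["filter"] = report.as_dict()
        filtered_vcf = outdir / "filtered.vcf"
        write_vcf(gmf, filtered_vcf)
        manifest["outputs"]["filtered_vcf"] = str(filtered_vcf)

        if cfg.run_structure:
            stage = "structure"
            _structure_stage(gmf, info, cfg, outdir, manifest)

        if cfg.run_abc:
            stage = "abc"
            _abc_stage(gmf, info, cfg, outdir, manifest)

        stage = "manifest"
        manifest["checksums"] = {
            k: _sha256(Path(v)) for k, v in manifest["outputs"].items()
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return manifest
    except (FileNotFoundError, ValueError, KeyError) as exc:
        # user-correctable: keep the type so callers can exit with code 1
        raise type(exc)(f"pipeline stage {stage!r}: {exc}") from exc
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


def _structure_stage(gmf, info, cfg, outdir: Path, manifest: dict) -> None:
    het = popstruct.individual_heterozygosity(gmf)
    het_df = pd.DataFrame({"sample_id": gmf.sample_ids, "heterozygosity": het})
    het_df.to_csv(outdir / "heterozygosity.tsv", sep="\t", index=False)
    manifest["outputs"]["heterozygosity"] = str(outdir / "heterozygosity.tsv")

    counts = {
        p: popstruct.population_snp_counts(gmf, info, p) for p in info.populations
    }
    pd.Series(counts, name="n_snps").rename_axis("population").to_csv(
        outdir / "snp_counts.tsv", sep="\t"
    )
    manifest["outputs"]["snp_counts"] = str(outdir / "snp_counts.tsv")

    fst = popstruct.pairwise_fst_table(
        gmf, info, n_perm=cfg.n_fst_perm, seed=cfg.seed
    )
    fst.to_csv(outdir / "fst.tsv", sep="\t", index=False)
    manifest["outputs"]["fst"] = str(outdir / "fst.tsv")

    pruned_idx = popstruct.ld_prune(
        gmf, window_bp=cfg.ld_prune_window_bp, r2_max=cfg.ld_prune_r2_max
    )
    coords, expl = popstruct.pca_genotypes(gmf.take_sites(pruned_idx))
    pca_df = pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    pca_df.insert(0, "sample_id", gmf.sample_ids)
    pca_df.to_csv(outdir / "pca.tsv", sep="\t", index=False)
    manifest["outputs"]["pca"] = str(outdir / "pca.tsv")
    manifest["stages"]["structure"] = {
        "n_pruned_sites": int(len(pruned_idx)),
        "explained_var": expl.tolist(),
    }

    order = {s: i for i, s in enumerate(gmf.sample_ids)}
    rural_idx = [
        order[s]
        for p in info.populations
        if info.habitat_of(p) == "rural"
        for s in info.samples_in(p)
        if s in order
    ]
    cdist = popstruct.centroid_distance(coords, rural_idx)
    pd.DataFrame({"sample_id": gmf.sample_ids, "centroid_distance": cdist}).to_csv(
        outdir / "centroid_distance.tsv", sep="\t", index=False
    )
    manifest["outputs"]["centroid_distance"] = str(outdir / "centroid_distance.tsv")

    mantel_rows = []
    for pop in info.populations:
        sub, si = _pop_subset(gmf, info, pop)
        ibs = popstruct.ibs_matrix(sub)
        geo = popstruct.geodesic_distance_matrix(si)
        res = popstruct.mantel_test(
            ibs, geo, n_perm=cfg.n_mantel_perm, n_boot=cfg.n_mantel_boot, seed=cfg.seed
        )
        tri = geo[np.tril_indices(len(geo), k=-1)]
        mantel_rows.append(
            {
                "population": pop,
                "n_snps": counts[pop],
                "mean_geo_dist_m": float(tri.mean()),
                "sd_geo_dist_m": float(tri.std(ddof=1)),
                "mantel_r": res.r,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
            }
        )
    pd.DataFrame(mantel_rows).to_csv(outdir / "mantel.tsv", sep="\t", index=False)
    manifest["outputs"]["mantel"] = str(outdir / "mantel.tsv")


def _abc_stage(gmf, info, cfg, outdir: Path, manifest: dict) -> None:
    bins = distance_bins_from_times(default_window_times(), cfg.simulation.rec)
    if cfg.reference_table:
        table = ReferenceTable.load(cfg.reference_table)
    else:
        table = build_reference_table(
            cfg.n_reference_sims,
            cfg.simulation,
            bins=bins,
            seed=cfg.seed,
            maf_min=cfg.maf_min,
            max_pairs_per_bin=cfg.max_pairs_per_bin,
            checkpoint_path=outdir / "reference_table.checkpoint.tsv",
        )
        table.save(outdir / "reference_table.tsv")
        manifest["outputs"]["reference_table"] = str(outdir / "reference_table.tsv")
    manifest["stages"]["abc"] = {"n_sims": table.n_sims}

    posteriors: dict[str, list] = {"urban": [], "rural": []}
    for pop in info.populations:
        sub, _ = _pop_subset(gmf, info, pop)
        if sub.n_individuals != table.config.n_ind:
            raise ValueError(
                f"population {pop} has {sub.n_individuals} individuals but the "
                f"reference table simulated {table.config.n_ind}"
            )
        obs = observed_summary_stats(
            sub,
            table.bins,
            min_scaffold_bp=cfg.min_scaffold_bp,
            maf_min=cfg.maf_min,
            max_pairs_per_bin=cfg.max_pairs_per_bin,
            seed=cfg.seed,
        )
        post = rejection_abc(obs, table, acceptance_rate=cfg.acceptance_rate)
        posteriors[info.habitat_of(pop)].append(post)
        traj = posterior_trajectory(post, gen_time=cfg.simulation.gen_time)
        path = outdir / f"trajectory_{pop}.tsv"
        traj.to_csv(path, sep="\t", index=False)
        manifest["outputs"][f"trajectory_{pop}"] = str(path)

    for habitat, posts in posteriors.items():
        if not posts:
            continue
        pooled = posterior_trajectory(posts, gen_time=cfg.simulation.gen_time)
        path = outdir / f"trajectory_pooled_{habitat}.tsv"
        pooled.to_csv(path, sep="\t", index=False)
        manifest["outputs"][f"trajectory_pooled_{habitat}"] = str(path)
    _plot_trajectories(outdir, posteriors, cfg)
    manifest["outputs"]["trajectory_plot"] = str(outdir / "trajectories.png")


def _plot_trajectories(outdir: Path, posteriors: dict, cfg) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    colors = {"urban": "tab:red", "rural": "tab:blue"}
    for habitat, posts in posteriors.items():
        if not posts:
            continue
        traj = posterior_trajectory(posts, gen_time=cfg.simulation.gen_time)
        x = traj["window_start_years"]
        ax.plot(x, traj["ne_median"], color=colors[habitat], label=habitat)
        ax.plot(x, traj["ne_q05"], color=colors[habitat], ls=":")
        ax.plot(x, traj["ne_q95"], color=colors[habitat], ls=":")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("years before present")
    ax.set_ylabel("effective population size")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "trajectories.png", dpi=150)
    plt.close(fig)


def simulate_fixture(cfg: PipelineConfig) -> tuple[str, str]:
    """Write the synthetic study VCF + metadata into the output directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf = outdir / "fixture.vcf"
    meta = outdir / "fixture_metadata.tsv"
    generate_study_fixture(cfg.design, cfg.simulation, vcf, meta)
    return str(vcf), str(meta)
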