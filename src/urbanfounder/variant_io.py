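"""VCF import/export and analysis-ready site filtering.

Internally sites live on 0-based coordinates; the VCF boundary converts
to/from the format's 1-based ``POS``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix, SampleInfo

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Site-filter thresholds.

    ``max_missing`` — keep sites with at most this many missing genotypes
    (strictly more are removed).  ``depth_sd_mult`` — sites are kept only
    if mean depth < global mean + ``depth_sd_mult`` × SD, evaluated on the
    pre-filter site set.  ``excluded_scaffolds`` — e.g. the Z-linked set.
    """

    max_missing: int = 12
    drop_singletons: bool = True
    depth_sd_mult: float = 5.0
    excluded_scaffolds: frozenset = field(default_factory=frozenset)
    depth_cap: float | None = None  # explicit cap overrides the mean+k·SD rule

    def __post_init__(self) -> None:
        if self.max_missing < 0:
            raise ValueError("max_missing must be >= 0")
        if self.depth_sd_mult <= 0:
            raise ValueError("depth_sd_mult must be > 0")
        self.excluded_scaffolds = frozenset(self.excluded_scaffolds)


@dataclass
class FilterReport:
    """Per-rule removal counts; overlapping rules both count a site."""

    n_input: int
    n_output: int
    removed_scaffold: int
    removed_monomorphic: int
    removed_singleton: int
    removed_missing: int
    removed_depth: int
    depth_cap: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def read_vcf(path, metadata) -> tuple[GenotypeMatrix, SampleInfo]:
    """Read a VCF (GT required) and its sample-metadata table.

    Multi-allelic records are dropped with a logged count.  Every VCF
    sample must appear in the metadata.
    """
    info = metadata if isinstance(metadata, SampleInfo) else SampleInfo.from_file(metadata)
    vcf = VCF(str(path), gts012=True)
    known = set(info.table["sample_id"])
    for s in vcf.samples:
        if s not in known:
            raise ValueError(f"sample {s!r} in VCF but absent from metadata")

    scaffold_lengths = {}
    try:
        if vcf.seqlens:
            scaffold_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:
        pass

    dosage_cols, positions, scaffolds, depths = [], [], [], []
    n_multi = 0
    any_depth = False
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = dosage, 3 = unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        if gt.min() < 0 or gt.max() > 3:
            raise ValueError(f"malformed GT at {v.CHROM}:{v.POS}")
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        positions.append(v.POS - 1)
        scaffolds.append(v.CHROM)
        mdp = v.INFO.get("MDP")
        if mdp is None:
            try:
                dp = v.format("DP")
            except KeyError:
                dp = None
            mdp = float(np.nanmean(dp)) if dp is not None else np.nan
        else:
            mdp = float(mdp)
        any_depth = any_depth or np.isfinite(mdp)
        depths.append(mdp)
    if n_multi:
        log.info("dropped %d multi-allelic records", n_multi)

    n_sites = len(dosage_cols)
    dosages = (
        np.stack(dosage_cols, axis=1)
        if n_sites
        else np.zeros((len(vcf.samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        dosages=dosages,
        positions=np.asarray(positions, dtype=np.int64),
        scaffold=np.asarray(scaffolds, dtype=object),
        sample_ids=list(vcf.samples),
        site_depth=np.asarray(depths) if any_depth else None,
        scaffold_lengths=scaffold_lengths,
    )
    return gm, info


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=urbanfounder
##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean read depth across individuals">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write *gm* as an uncompressed VCFv4.2 with GT fields.

    ``read_vcf(write_vcf(gm))`` reproduces dosage, position and scaffold
    exactly (REF/ALT are placeholders).
    """
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        seen = list(dict.fromkeys(gm.scaffold))
        for scaf in seen:
            length = gm.scaffold_lengths.get(scaf)
            if length is None:
                length = int(gm.positions[gm.scaffold == scaf].max()) + 1
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        for scaf, length in gm.scaffold_lengths.items():
            if scaf not in seen:
                fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            info_col = (
                f"MDP={gm.site_depth[j]:.4f}"
                if gm.site_depth is not None and np.isfinite(gm.site_depth[j])
                else "."
            )
            gts = "\t".join(_GT_CODE[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{gm.scaffold[j]}\t{gm.positions[j] + 1}\t.\tA\tT\t.\tPASS\t"
                f"{info_col}\tGT\t{gts}\n"
            )


def apply_site_filters(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the study's site-level filters; returns the kept matrix and a
    per-rule removal report.

    Rules: excluded scaffolds; monomorphic sites; singletons (minor allele
    count exactly 1, pooled over all individuals); more than ``max_missing``
    missing genotypes; mean site depth ≥ mean + ``depth_sd_mult`` × SD over
    the pre-filter site set (strict "<" keeps a site).
    """
    cfg = cfg or FilterConfig()
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")

    scaf_mask = np.isin(gm.scaffold, list(cfg.excluded_scaffolds))
    mac = gm.minor_allele_counts()
    mono_mask = mac == 0
    singleton_mask = (mac == 1) if cfg.drop_singletons else np.zeros(gm.n_sites, bool)
    miss_mask = gm.missing_counts() > cfg.max_missing

    depth_cap = cfg.depth_cap
    if gm.site_depth is not None:
        if depth_cap is None:
            finite = gm.site_depth[np.isfinite(gm.site_depth)]
            depth_cap = float(finite.mean() + cfg.depth_sd_mult * finite.std())
        depth_mask = gm.site_depth >= depth_cap
    else:
        depth_mask = np.zeros(gm.n_sites, bool)

    drop = scaf_mask | mono_mask | singleton_mask | miss_mask | depth_mask
    keep = np.flatnonzero(~drop)
    report = FilterReport(
        n_input=gm.n_sites,
        n_output=len(keep),
        removed_scaffold=int(scaf_mask.sum()),
        removed_monomorphic=int(mono_mask.sum()),
        removed_singleton=int(singleton_mask.sum()),
        removed_missing=int(miss_mask.sum()),
        removed_depth=int(depth_mask.sum()),
        depth_cap=depth_cap,
    )
    if len(keep) == 0:
        log.warning("all %d sites removed by filters", gm.n_sites)
    return gm.take_sites(keep), report
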