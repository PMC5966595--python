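"""ABC summary statistics: folded AFS and binned long-range LD.

The same functions serve the observed data and every simulated dataset,
so the two paths cannot drift apart.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .popstruct import composite_ld_r2

log = logging.getLogger(__name__)

#: Default clip range of the LD distance bins, in bp.
D_MIN_BP = 50_000
D_MAX_BP = 17_000_000


def ld_distance_for_time(t, rec: float) -> np.ndarray:
    """Marker distance (bp) whose LD is most sensitive to the population
    size ``t`` generations ago: d = 1 / (2 · rec · t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0) or rec <= 0:
        raise ValueError("times and recombination rate must be positive")
    return 1.0 / (2.0 * rec * t)


def distance_bins_from_times(
    times,
    rec: float,
    d_min: float = D_MIN_BP,
    d_max: float = D_MAX_BP,
) -> np.ndarray:
    """Build 20 LD distance bins targeted at the time windows.

    Target distances are ``1/(2·rec·t)`` for the 20 most recent of the 21
    window times; bin edges are geometric midpoints between consecutive
    targets, with the outer edges clipped to ``[d_min, d_max]``.  Returns
    a ``(20, 2)`` array of (lower, upper) bp bounds, strictly increasing
    and non-overlapping.
    """
    times = np.sort(np.asarray(times, dtype=float))
    if len(times) < 2:
        raise ValueError("need at least 2 window times")
    targets = ld_distance_for_time(times[:-1], rec)  # drop the oldest window
    clipped = np.clip(targets, d_min, d_max)
    if np.any(clipped != targets):
        log.info(
            "%d bin targets clipped into [%g, %g] bp",
            int((clipped != targets).sum()), d_min, d_max,
        )
    targets = np.sort(clipped)
    inner = np.sqrt(targets[:-1] * targets[1:])  # geometric midpoints
    edges = np.concatenate([[d_min], inner, [d_max]])
    bins = np.column_stack([edges[:-1], edges[1:]])
    if np.any(bins[:, 1] <= bins[:, 0]):
        raise ValueError("degenerate distance bins; check times/clip range")
    return bins


@dataclass
class SummaryStats:
    """Folded AFS proportions, SNP density and per-bin mean LD."""

    afs: np.ndarray            # proportions for minor-count classes 1..n_ind
    density: float             # SNPs per bp of analysed sequence
    ld: np.ndarray             # mean r² per distance bin (NaN = empty bin)
    bins: np.ndarray           # (n_bins, 2) bp bounds
    ld_pair_counts: np.ndarray = field(default=None)

    def to_vector(self) -> np.ndarray:
        """Flat statistic vector used for ABC distances:
        [afs classes..., density, ld bins...]."""
        return np.concatenate([self.afs, [self.density], self.ld])

    def stat_names(self) -> list[str]:
        return (
            [f"afs_{i + 1}" for i in range(len(self.afs))]
            + ["snp_density"]
            + [f"ld_{i}" for i in range(len(self.ld))]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "afs": self.afs.tolist(),
                    "density": self.density,
                    "ld": [None if not np.isfinite(v) else v for v in self.ld],
                    "bins": self.bins.tolist(),
                    "ld_pair_counts": (
                        None
                        if self.ld_pair_counts is None
                        else np.asarray(self.ld_pair_counts).tolist()
                    ),
                },
                fh,
                indent=1,
            )


def folded_afs(gm: GenotypeMatrix, total_bp: float | None = None) -> tuple[np.ndarray, float]:
    """Folded allele-frequency spectrum and SNP density.

    Returns proportions over minor-allele-count classes ``1..n_ind``
    (monomorphic sites are ignored) and SNPs per bp.  ``total_bp``
    defaults to the sum of known scaffold lengths.
    """
    n_classes = gm.n_individuals
    mac = gm.minor_allele_counts()
    mac = mac[mac > 0]
    counts = np.bincount(np.minimum(mac, n_classes), minlength=n_classes + 1)[1:]
    total = counts.sum()
    afs = counts / total if total > 0 else np.zeros(n_classes)
    if total_bp is None:
        if gm.scaffold_lengths:
            total_bp = float(
                sum(gm.scaffold_lengths[s] for s in dict.fromkeys(gm.scaffold))
            )
        else:
            total_bp = float(gm.positions.max() + 1) if gm.n_sites else 0.0
    density = total / total_bp if total_bp > 0 else 0.0
    return afs, float(density)


def _pairs_in_bin(positions: np.ndarray, lo: float, hi: float):
    """All index pairs (i, j>i) with hi > pos_j - pos_i >= lo, returned as
    (left index array, per-left counts, searchsorted starts)."""
    lo_idx = np.searchsorted(positions, positions + lo, side="left")
    hi_idx = np.searchsorted(positions, positions + hi, side="left")
    counts = np.maximum(hi_idx - lo_idx, 0)
    return lo_idx, counts


def binned_ld_curve(
    gm: GenotypeMatrix,
    bins: np.ndarray,
    maf_min: float = 0.15,
    max_pairs_per_bin: int = 10_000,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean composite r² per distance bin.

    Only pairs on the same scaffold with both minor-allele frequencies
    ≥ ``maf_min`` enter; a bin whose pair count exceeds
    ``max_pairs_per_bin`` is subsampled with a seeded RNG.  Empty bins
    are NaN.  Returns ``(ld_means, pair_counts)``.
    """
    bins = np.asarray(bins, dtype=float)
    alt, tot = gm.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(tot > 0, np.minimum(alt, tot - alt) / tot, 0.0)
    usable = maf >= maf_min

    rng = np.random.default_rng(seed)
    n_bins = len(bins)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    has_missing = bool((gm.dosages == MISSING).any())
    for scaf in dict.fromkeys(gm.scaffold):
        sel = np.flatnonzero((gm.scaffold == scaf) & usable)
        if len(sel) < 2:
            continue
        pos = gm.positions[sel].astype(float)
        dos = gm.dosages[:, sel].astype(float)
        if not has_missing:
            std = dos.std(axis=0)
            z = (dos - dos.mean(axis=0)) / np.where(std > 0, std, 1.0)
        for b, (lo, hi) in enumerate(bins):
            lo_idx, per_left = _pairs_in_bin(pos, lo, hi)
            total = int(per_left.sum())
            if total == 0:
                continue
            if total > max_pairs_per_bin:
                ranks = np.sort(rng.choice(total, size=max_pairs_per_bin, replace=False))
            else:
                ranks = np.arange(total)
            cum = np.concatenate([[0], np.cumsum(per_left)])
            left = np.searchsorted(cum, ranks, side="right") - 1
            right = lo_idx[left] + (ranks - cum[left])
            if not has_missing:
                r = (z[:, left] * z[:, right]).mean(axis=0)
                r2 = r * r
                valid = std[left] * std[right] > 0
                r2 = r2[valid]
            else:
                r2 = np.array(
                    [composite_ld_r2(dos[:, i], dos[:, j]) for i, j in zip(left, right)]
                )
                r2 = r2[np.isfinite(r2)]
            sums[b] += r2.sum()
            counts[b] += len(r2)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def summary_stats(
    gm: GenotypeMatrix,
    bins: np.ndarray,
    maf_min: float = 0.15,
    max_pairs_per_bin: int = 10_000,
    seed: int = 1,
    total_bp: float | None = None,
) -> SummaryStats:
    """Folded AFS + binned LD curve for one dataset (simulated or observed)."""
    afs, density = folded_afs(gm, total_bp=total_bp)
    ld, pair_counts = binned_ld_curve(
        gm, bins, maf_min=maf_min, max_pairs_per_bin=max_pairs_per_bin, seed=seed
    )
    return SummaryStats(
        afs=afs,
        density=density,
        ld=ld,
        bins=np.asarray(bins, float),
        ld_pair_counts=pair_counts,
    )


def observed_summary_stats(
    gm: GenotypeMatrix,
    bins: np.ndarray,
    min_scaffold_bp: float = 20_000_000,
    maf_min: float = 0.15,
    max_pairs_per_bin: int = 10_000,
    seed: int = 1,
) -> SummaryStats:
    """Summary statistics of the observed data, restricted to long scaffolds.

    Scaffolds shorter than ``min_scaffold_bp`` are excluded before
    computing the AFS and LD curve; raises if none qualifies.
    """
    if not gm.scaffold_lengths:
        raise ValueError("scaffold lengths unknown; cannot select long scaffolds")
    long_scafs = {s for s, ln in gm.scaffold_lengths.items() if ln >= min_scaffold_bp}
    if not long_scafs:
        raise ValueError(
            f"no scaffold reaches {min_scaffold_bp:g} bp; largest is "
            f"{max(gm.scaffold_lengths.values()):g}"
        )
    keep = np.flatnonzero(np.isin(gm.scaffold, list(long_scafs)))
    sub = gm.take_sites(keep)
    total_bp = float(sum(gm.scaffold_lengths[s] for s in long_scafs))
    return summary_stats(
        sub,
        bins,
        maf_min=maf_min,
        max_pairs_per_bin=max_pairs_per_bin,
        seed=seed,
        total_bp=total_bp,
    )
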