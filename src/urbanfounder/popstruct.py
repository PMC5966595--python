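"""Population-structure and diversity statistics.

Heterozygosity, per-population SNP accounting, Weir–Cockerham F_ST with
permutation significance, LD pruning, genotype PCA, centroid genetic
distances, shared-SNP permutation and Mantel isolation-by-distance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix, SampleInfo

EARTH_RADIUS_M = 6_371_000.0


# ---------------------------------------------------------------------------
# diversity and SNP accounting
# ---------------------------------------------------------------------------

def individual_heterozygosity(gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of an individual's non-missing sites that are heterozygous.

    Individuals with zero typed sites get NaN.
    """
    typed = (gm.dosages != MISSING).sum(axis=1)
    het = (gm.dosages == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(typed > 0, het / typed, np.nan)


def _segregating_mask(dosages: np.ndarray) -> np.ndarray:
    """Per-site flag: both alleles present among the given individuals."""
    called = dosages != MISSING
    alt = np.where(called, dosages, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    return (alt > 0) & (alt < total)


def population_snp_counts(
    gm: GenotypeMatrix, info: SampleInfo, population: str
) -> int:
    """Number of sites segregating within one population's individuals."""
    idx = info.indices_of(gm, population)
    if len(idx) == 0:
        raise KeyError(f"no individuals of population {population!r} in matrix")
    return int(_segregating_mask(gm.dosages[idx, :]).sum())


def percent_reduction(urban_count: float, rural_count: float) -> float:
    """Relative SNP deficit of an urban population, in percent."""
    if rural_count <= 0:
        raise ValueError("rural_count must be > 0")
    return 100.0 * (rural_count - urban_count) / rural_count


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Classical paired t-test on ``d = x - y``; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors, n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def shared_snp_permutation(
    gm: GenotypeMatrix,
    info: SampleInfo,
    pop_a: str,
    pop_b: str,
    n_perm: int = 20,
    seed: int = 1,
) -> dict:
    """Observed vs. permutation-expected shared/private SNP counts.

    The expectation reassigns the pooled individuals at random into
    groups of the original sizes ``n_perm`` times and averages.
    """
    if pop_a == pop_b:
        raise ValueError("populations must differ")
    ia = info.indices_of(gm, pop_a)
    ib = info.indices_of(gm, pop_b)
    pool = np.concatenate([ia, ib])

    def counts(idx_a, idx_b):
        seg_a = _segregating_mask(gm.dosages[idx_a, :])
        seg_b = _segregating_mask(gm.dosages[idx_b, :])
        return (
            int((seg_a & seg_b).sum()),
            int((seg_a & ~seg_b).sum()),
            int((~seg_a & seg_b).sum()),
        )

    shared, priv_a, priv_b = counts(ia, ib)
    rng = np.random.default_rng(seed)
    perm = np.zeros((n_perm, 3))
    for k in range(n_perm):
        shuffled = rng.permutation(pool)
        perm[k] = counts(shuffled[: len(ia)], shuffled[len(ia):])
    exp_shared, exp_priv_a, exp_priv_b = perm.mean(axis=0)
    return {
        "shared": shared,
        "private_a": priv_a,
        "private_b": priv_b,
        "expected_shared": float(exp_shared),
        "expected_private_a": float(exp_priv_a),
        "expected_private_b": float(exp_priv_b),
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def composite_ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete entries (composite/genotypic LD).

    NaN if fewer than 2 complete pairs or either locus is monomorphic
    among them.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        return float("nan")
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix, window_bp: int = 50_000, r2_max: float = 0.5
) -> np.ndarray:
    """Greedy left-to-right LD pruning per scaffold.

    A site is dropped if its composite r² with any already-retained site
    within ``window_bp`` is ≥ ``r2_max``.  Returns retained site indices.
    """
    keep: list[int] = []
    for scaf in dict.fromkeys(gm.scaffold):
        idx = np.flatnonzero(gm.scaffold == scaf)
        retained: list[int] = []
        for j in idx:
            pos_j = gm.positions[j]
            ok = True
            for k in reversed(retained):
                if pos_j - gm.positions[k] > window_bp:
                    break
                r2 = composite_ld_r2(gm.dosages[:, j], gm.dosages[:, k])
                if np.isfinite(r2) and r2 >= r2_max:
                    ok = False
                    break
            if ok:
                retained.append(j)
        keep.extend(retained)
    return np.asarray(sorted(keep), dtype=np.int64)


# ---------------------------------------------------------------------------
# PCA and centroid distances
# ---------------------------------------------------------------------------

def pca_genotypes(
    gm: GenotypeMatrix, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix with allele-frequency normalization.

    Sites are centred by twice the allele frequency and scaled by the
    binomial SD ``sqrt(p(1-p))``; missing entries are mean-imputed
    (zero after centring).  Returns ``(coords, explained_var)`` where
    coords is ``n_individuals × k``.
    """
    if gm.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if gm.n_sites < 1:
        raise ValueError("need at least 1 site")
    d = gm.dosages.astype(float)
    d[gm.dosages == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    d = d[:, poly]
    p = p[poly]
    if d.shape[1] == 0:
        raise ValueError("no polymorphic sites")
    x = (d - 2 * p) / np.sqrt(p * (1 - p))
    x[np.isnan(x)] = 0.0
    cov = x @ x.T / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    k = min(n_components, gm.n_individuals - 1)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    explained = evals[:k] / evals.sum() if evals.sum() > 0 else np.zeros(k)
    return coords, explained


def centroid_distance(pc_coords: np.ndarray, rural_idx) -> np.ndarray:
    """Euclidean distance of each individual to the rural centroid in the
    (PC1, PC2) plane; centroid = per-axis median of the rural individuals."""
    rural_idx = np.asarray(rural_idx)
    if len(rural_idx) == 0:
        raise ValueError("rural_idx must be non-empty")
    if pc_coords.shape[1] < 2:
        raise ValueError("need at least 2 principal components")
    centre = np.median(pc_coords[rural_idx, :2], axis=0)
    return np.linalg.norm(pc_coords[:, :2] - centre, axis=1)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def _wc_components(
    da: np.ndarray, db: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components a, b, c for
    two populations given dosage sub-matrices (individuals × sites)."""
    r = 2
    comps = []
    for d in (da, db):
        called = d != MISSING
        n = called.sum(axis=0).astype(float)  # typed individuals
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
            h = np.where(n > 0, np.where(called, d == 1, False).sum(axis=0) / n, np.nan)
        comps.append((n, p, h))
    (na, pa, ha), (nb, pb, hb) = comps

    valid = (na > 0) & (nb > 0) & (na + nb > 2)
    n_bar = (na + nb) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (na**2 + nb**2) / (r * n_bar)) / (r - 1)
        p_bar = (na * pa + nb * pb) / (r * n_bar)
        s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (na * ha + nb * hb) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - 1.0
            / (n_bar - 1)
            * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
        )
        b = (
            n_bar
            / (n_bar - 1)
            * (
                p_bar * (1 - p_bar)
                - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
        )
        c = h_bar / 2.0
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return a, b, c


def wc_fst_from_dosages(da: np.ndarray, db: np.ndarray) -> float:
    """Multi-locus Weir–Cockerham F_ST as a ratio of summed variance
    components (ratio of averages).  NaN if the denominator is zero."""
    a, b, c = _wc_components(da, db)
    denom = np.nansum(a + b + c)
    if denom == 0:
        return float("nan")
    return float(np.nansum(a) / denom)


def wc_fst(
    gm: GenotypeMatrix, info: SampleInfo, pop_a: str, pop_b: str
) -> float:
    """Weir–Cockerham (1984) F_ST between two labelled populations."""
    ia = info.indices_of(gm, pop_a)
    ib = info.indices_of(gm, pop_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both populations need >= 2 individuals")
    return wc_fst_from_dosages(gm.dosages[ia, :], gm.dosages[ib, :])


def fst_permutation_p(
    gm: GenotypeMatrix,
    info: SampleInfo,
    pop_a: str,
    pop_b: str,
    n_perm: int = 1000,
    seed: int = 1,
) -> tuple[float, float]:
    """Permutation p-value for F_ST by random reassignment of individuals
    between the two populations.

    Returns ``(fst_observed, p)`` with ``p = (1 + #{F_perm >= F_obs}) /
    (n_perm + 1)``.
    """
    ia = info.indices_of(gm, pop_a)
    ib = info.indices_of(gm, pop_b)
    obs = wc_fst_from_dosages(gm.dosages[ia, :], gm.dosages[ib, :])
    pool = np.concatenate([ia, ib])
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        shuffled = rng.permutation(pool)
        f = wc_fst_from_dosages(
            gm.dosages[shuffled[: len(ia)], :], gm.dosages[shuffled[len(ia):], :]
        )
        if np.isfinite(f) and f >= obs:
            n_ge += 1
    return obs, (1 + n_ge) / (n_perm + 1)


def pairwise_fst_table(
    gm: GenotypeMatrix, info: SampleInfo, n_perm: int = 1000, seed: int = 1
) -> "pd.DataFrame":
    """All pairwise F_ST values with permutation p-values."""
    import pandas as pd

    pops = info.populations
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            fst, p = fst_permutation_p(gm, info, a, b, n_perm=n_perm, seed=seed)
            rows.append({"pop_a": a, "pop_b": b, "fst": fst, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# isolation by distance
# ---------------------------------------------------------------------------

def ibs_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Identity-by-state matrix: ``1 - mean(|d_i - d_j|) / 2`` over
    pairwise-complete sites.  Diagonal is 1; a pair with no shared typed
    site gets NaN."""
    n = gm.n_individuals
    d = gm.dosages.astype(float)
    d[gm.dosages == MISSING] = np.nan
    out = np.ones((n, n))
    for i in range(n):
        diff = np.abs(d[i] - d[i + 1:])  # (n-i-1, sites), NaN where incomplete
        with np.errstate(invalid="ignore"):
            vals = 1.0 - np.nanmean(diff, axis=1) / 2.0
        out[i, i + 1:] = vals
        out[i + 1:, i] = vals
    return out


def geodesic_distance_matrix(info: SampleInfo) -> np.ndarray:
    """Great-circle distance matrix in metres (haversine, R = 6371 km)."""
    lat = np.radians(info.table["latitude"].to_numpy(float))
    lon = np.radians(info.table["longitude"].to_numpy(float))
    if np.any(np.abs(lat) > np.pi / 2):
        raise ValueError("latitude outside [-90, 90] degrees")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass
class MantelResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n_perm: int
    n_boot: int


def mantel_test(
    genetic: np.ndarray,
    geographic: np.ndarray,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 1,
) -> MantelResult:
    """Mantel correlation between two square matrices.

    r is the Pearson correlation of the lower triangles; p is two-sided
    from row/column permutations of one matrix; the 95% CI is a
    percentile bootstrap over individuals.
    """
    genetic = np.asarray(genetic, float)
    geographic = np.asarray(geographic, float)
    if genetic.shape != geographic.shape or genetic.ndim != 2:
        raise ValueError("matrices must be square and conformable")
    n = genetic.shape[0]
    il = np.tril_indices(n, k=-1)

    def corr(a, b):
        x, y = a[il], b[il]
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(genetic, geographic)
    if not np.isfinite(r_obs):
        raise ValueError("Mantel r undefined (constant matrix)")
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(genetic[np.ix_(perm, perm)], geographic)
        if np.isfinite(r_p) and abs(r_p) >= abs(r_obs):
            n_extreme += 1
    p = (1 + n_extreme) / (n_perm + 1)

    boots = []
    for _ in range(n_boot):
        samp = rng.integers(0, n, n)
        r_b = corr(genetic[np.ix_(samp, samp)], geographic[np.ix_(samp, samp)])
        if np.isfinite(r_b):
            boots.append(r_b)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return MantelResult(r_obs, float(lo), float(hi), p, n_perm, n_boot)
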