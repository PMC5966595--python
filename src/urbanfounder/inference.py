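"""Rejection-ABC inference of piecewise-constant Ne trajectories.

Prior over stepwise histories, msprime-backed coalescent simulation,
reference-table construction, rejection sampling on standardized summary
statistics, posterior trajectory summaries and cross-validated
prediction error.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .sumstats import SummaryStats, distance_bins_from_times, summary_stats

#: Prior bounds on diploid Ne and on the time windows (generations).
NE_MIN = 32.0
NE_MAX = 316_228.0
T_MIN = 3.0
T_MAX = 500.0
N_WINDOWS = 21

#: Maximum factor by which Ne may change between consecutive windows.
STEP_FACTOR = 10.0


def default_window_times(
    n_windows: int = N_WINDOWS, t_min: float = T_MIN, t_max: float = T_MAX
) -> np.ndarray:
    """Log-spaced window start times in generations before present."""
    return np.logspace(np.log10(t_min), np.log10(t_max), n_windows)


def ld_time_depth(d_bp: float, rec: float) -> float:
    """Generations before present probed by LD at distance ``d_bp``:
    t = 1/(2c) with c = rec · d in Morgans."""
    if d_bp <= 0 or rec <= 0:
        raise ValueError("distance and recombination rate must be positive")
    return 1.0 / (2.0 * rec * d_bp)


def generations_to_years(g: float, gen_time: float = 2.5) -> float:
    """Convert generations to calendar years."""
    if g < 0:
        raise ValueError("generations must be >= 0")
    return g * gen_time


@dataclass
class NeHistory:
    """Stepwise diploid effective sizes over the 21 time windows.

    ``ne[i]`` applies from ``window_starts[i]`` generations ago back to
    the next window start (the most recent value also covers
    [0, window_starts[0])); beyond the oldest window Ne stays at
    ``ne[-1]``.
    """

    window_starts: np.ndarray
    ne: np.ndarray

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if self.window_starts.shape != self.ne.shape:
            raise ValueError("window_starts and ne must have equal length")
        if np.any(np.diff(self.window_starts) <= 0):
            raise ValueError("window_starts must be strictly increasing")
        if np.any((self.ne < NE_MIN * (1 - 1e-9)) | (self.ne > NE_MAX * (1 + 1e-9))):
            raise ValueError(f"ne outside [{NE_MIN}, {NE_MAX}]")
        ratio = self.ne[1:] / self.ne[:-1]
        if np.any((ratio > STEP_FACTOR * (1 + 1e-9)) | (ratio < 1 / STEP_FACTOR * (1 - 1e-9))):
            raise ValueError("consecutive ne ratio outside [1/10, 10]")

    @property
    def log10_ne(self) -> np.ndarray:
        return np.log10(self.ne)


def sample_prior_history(
    rng: np.random.Generator, window_times: np.ndarray | None = None
) -> NeHistory:
    """Draw a stepwise Ne history from the prior.

    log10(Ne) of the most recent window is uniform on the prior bounds;
    each subsequent window takes a uniform ±1 step on the log10 scale,
    truncated to the bounds (Ne may change by at most a factor of 10
    between windows).
    """
    times = default_window_times() if window_times is None else np.asarray(window_times)
    lo, hi = math.log10(NE_MIN), math.log10(NE_MAX)
    logne = np.empty(len(times))
    logne[0] = rng.uniform(lo, hi)
    for i in range(1, len(times)):
        logne[i] = rng.uniform(max(lo, logne[i - 1] - 1), min(hi, logne[i - 1] + 1))
    return NeHistory(window_starts=times, ne=10.0 ** logne)


@dataclass
class SimulationConfig:
    """Coalescent-simulation settings shared by the reference table and
    pseudo-observed datasets."""

    n_ind: int = 20
    seq_len: float = 2e7
    n_seg: int = 16
    mu: float = 4e-9
    rec: float = 2e-8
    gen_time: float = 2.5

    def __post_init__(self) -> None:
        if self.n_ind < 2:
            raise ValueError("n_ind must be >= 2")
        if min(self.seq_len, self.gen_time) <= 0 or self.n_seg < 1:
            raise ValueError("sequence length, generation time and n_seg must be positive")
        if min(self.mu, self.rec) < 0:
            raise ValueError("mutation and recombination rates must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _demography(history: NeHistory) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="pop", initial_size=history.ne[0])
    for t, n in zip(history.window_starts[1:], history.ne[1:]):
        dem.add_population_parameters_change(time=t, initial_size=n)
    return dem


def simulate_under_history(
    history: NeHistory, cfg: SimulationConfig, seed: int = 1
) -> GenotypeMatrix:
    """Simulate ``cfg.n_seg`` independent segments under the stepwise
    demography and return diploid dosages (haplotypes paired in order)."""
    dem = _demography(history)
    seeds = np.random.SeedSequence(seed).generate_state(2 * cfg.n_seg) % (2**31 - 1) + 1
    cols, positions, scafs = [], [], []
    scaffold_lengths = {}
    for s in range(cfg.n_seg):
        name = f"seg{s}"
        scaffold_lengths[name] = int(cfg.seq_len)
        ts = msprime.sim_ancestry(
            samples=cfg.n_ind,
            sequence_length=cfg.seq_len,
            recombination_rate=cfg.rec,
            demography=dem,
            random_seed=int(seeds[2 * s]),
        )
        ts = msprime.sim_mutations(
            ts, rate=cfg.mu, model=msprime.BinaryMutationModel(),
            random_seed=int(seeds[2 * s + 1]),
        )
        if ts.num_sites:
            hap = ts.genotype_matrix()  # sites x haplotypes, entries 0/1
            dos = (hap[:, ::2] + hap[:, 1::2]).T  # individuals x sites
            cols.append(dos)
            positions.append(ts.sites_position.astype(np.int64))
            scafs.append(np.array([name] * ts.num_sites, dtype=object))
    if cols:
        dosages = np.concatenate(cols, axis=1)
        positions = np.concatenate(positions)
        scaffold = np.concatenate(scafs)
    else:
        dosages = np.zeros((cfg.n_ind, 0), dtype=np.int8)
        positions = np.zeros(0, dtype=np.int64)
        scaffold = np.zeros(0, dtype=object)
    return GenotypeMatrix(
        dosages=dosages,
        positions=positions,
        scaffold=scaffold,
        sample_ids=[f"sim{i}" for i in range(cfg.n_ind)],
        scaffold_lengths=scaffold_lengths,
    )


@dataclass
class ReferenceTable:
    """Prior draws with their summary statistics."""

    window_starts: np.ndarray          # (n_windows,)
    ne: np.ndarray                     # (n_sims, n_windows)
    stats: np.ndarray                  # (n_sims, n_stats)
    stat_names: list[str]
    bins: np.ndarray
    config: SimulationConfig
    row_seeds: np.ndarray = None

    @property
    def n_sims(self) -> int:
        return self.ne.shape[0]

    def save(self, path) -> None:
        """Persist as TSV (one row per simulation) + JSON sidecar."""
        df = pd.DataFrame(
            np.hstack([self.ne, self.stats]),
            columns=[f"ne_{i}" for i in range(self.ne.shape[1])] + self.stat_names,
        )
        if self.row_seeds is not None:
            df.insert(0, "row_seed", self.row_seeds)
        df.to_csv(path, sep="\t", index=False)
        with open(str(path) + ".json", "w") as fh:
            json.dump(
                {
                    "window_starts": self.window_starts.tolist(),
                    "bins": self.bins.tolist(),
                    "stat_names": self.stat_names,
                    "config": self.config.__dict__,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        df = pd.read_csv(path, sep="\t")
        ne_cols = [c for c in df.columns if c.startswith("ne_")]
        return cls(
            window_starts=np.asarray(meta["window_starts"]),
            ne=df[ne_cols].to_numpy(),
            stats=df[meta["stat_names"]].to_numpy(),
            stat_names=meta["stat_names"],
            bins=np.asarray(meta["bins"]),
            config=SimulationConfig(**meta["config"]),
            row_seeds=df["row_seed"].to_numpy() if "row_seed" in df else None,
        )


def _simulate_row(
    i: int, seed: int, cfg: SimulationConfig, bins: np.ndarray, maf_min: float,
    max_pairs_per_bin: int, window_times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    row_seed = int(
        np.random.SeedSequence(entropy=seed, spawn_key=(i,)).generate_state(1)[0]
        % (2**31 - 1) + 1
    )
    rng = np.random.default_rng(row_seed)
    history = sample_prior_history(rng, window_times)
    gm = simulate_under_history(history, cfg, seed=row_seed)
    st = summary_stats(
        gm, bins, maf_min=maf_min, max_pairs_per_bin=max_pairs_per_bin, seed=row_seed
    )
    return history.ne, st.to_vector(), row_seed


def build_reference_table(
    n_sims: int,
    cfg: SimulationConfig,
    bins: np.ndarray | None = None,
    seed: int = 1,
    maf_min: float = 0.15,
    max_pairs_per_bin: int = 10_000,
    checkpoint_path=None,
    checkpoint_every: int = 50,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_sims`` (prior draw → dataset → summary stats) rows.

    Each row derives its own seed from ``seed`` and the row index, so the
    table is bitwise reproducible and resumable: with ``checkpoint_path``
    set, completed rows are flushed to disk and reused on restart.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    window_times = default_window_times()
    if bins is None:
        bins = distance_bins_from_times(window_times, cfg.rec)

    template = SummaryStats(
        afs=np.zeros(cfg.n_ind), density=0.0, ld=np.zeros(len(bins)), bins=bins
    )
    stat_names = template.stat_names()

    done_ne, done_stats, done_seeds = [], [], []
    start = 0
    if checkpoint_path is not None and os.path.exists(checkpoint_path):
        prev = pd.read_csv(checkpoint_path, sep="\t")
        start = len(prev)
        if start:
            done_ne = list(prev[[f"ne_{i}" for i in range(N_WINDOWS)]].to_numpy())
            done_stats = list(prev[stat_names].to_numpy())
            done_seeds = list(prev["row_seed"].to_numpy())

    iterator = range(start, n_sims)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="reference table", initial=start, total=n_sims)
    pending = 0
    for i in iterator:
        ne, vec, row_seed = _simulate_row(
            i, seed, cfg, bins, maf_min, max_pairs_per_bin, window_times
        )
        done_ne.append(ne)
        done_stats.append(vec)
        done_seeds.append(row_seed)
        pending += 1
        if checkpoint_path is not None and (
            pending >= checkpoint_every or i == n_sims - 1
        ):
            _flush_checkpoint(checkpoint_path, done_ne, done_stats, done_seeds, stat_names)
            pending = 0

    return ReferenceTable(
        window_starts=window_times,
        ne=np.asarray(done_ne)[:n_sims],
        stats=np.asarray(done_stats)[:n_sims],
        stat_names=stat_names,
        bins=np.asarray(bins),
        config=cfg,
        row_seeds=np.asarray(done_seeds)[:n_sims],
    )


def _flush_checkpoint(path, ne, stats, seeds, stat_names) -> None:
    df = pd.DataFrame(
        np.hstack([np.asarray(ne), np.asarray(stats)]),
        columns=[f"ne_{i}" for i in range(N_WINDOWS)] + stat_names,
    )
    df.insert(0, "row_seed", seeds)
    tmp = str(path) + ".tmp"
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


@dataclass
class ABCPosterior:
    """Accepted histories with per-window quantile summaries."""

    window_starts: np.ndarray
    accepted_ne: np.ndarray            # (k, n_windows)
    distances: np.ndarray              # (k,)
    accepted_idx: np.ndarray           # table row indices
    acceptance_rate: float
    n_sims: int

    @property
    def n_accepted(self) -> int:
        return self.accepted_ne.shape[0]

    def quantiles(self, q=(0.05, 0.5, 0.95)) -> np.ndarray:
        """Per-window Ne quantiles of the accepted histories (computed on
        log10 Ne and back-transformed)."""
        logq = np.quantile(np.log10(self.accepted_ne), q, axis=0)
        return 10.0 ** logq

    @property
    def median(self) -> np.ndarray:
        return self.quantiles((0.5,))[0]

    @property
    def q05(self) -> np.ndarray:
        return self.quantiles((0.05,))[0]

    @property
    def q95(self) -> np.ndarray:
        return self.quantiles((0.95,))[0]


def rejection_abc(
    obs: SummaryStats | np.ndarray,
    table: ReferenceTable,
    acceptance_rate: float = 5e-5,
    max_missing_frac: float = 0.5,
) -> ABCPosterior:
    """Simple rejection ABC.

    Every statistic is standardized by its SD across the table; the
    distance is Euclidean on the standardized vectors; the
    ``floor(acceptance_rate × n_sims)`` closest rows are accepted (ties
    broken by row index).  Empty-flagged statistics (NaN LD bins) are
    dropped when the observation lacks them or when fewer than
    ``max_missing_frac`` of the table rows carry them; a table row
    missing a retained statistic gets infinite distance.
    """
    obs_vec = obs.to_vector() if isinstance(obs, SummaryStats) else np.asarray(obs, float)
    if obs_vec.shape != (table.stats.shape[1],):
        raise ValueError("observed statistics do not match the table's structure")
    k = math.floor(acceptance_rate * table.n_sims)
    if k < 1:
        raise ValueError(
            f"acceptance_rate {acceptance_rate} accepts 0 of {table.n_sims} "
            "simulations; increase the rate"
        )
    finite_frac = np.isfinite(table.stats).mean(axis=0)
    usable = np.isfinite(obs_vec) & (finite_frac >= max_missing_frac)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(table.stats[:, usable], axis=0)
    usable_idx = np.flatnonzero(usable)[sd > 0]
    sd = sd[sd > 0]
    if len(usable_idx) == 0:
        raise ValueError("no usable (finite, non-constant) statistics")
    z_obs = obs_vec[usable_idx] / sd
    z_tab = table.stats[:, usable_idx] / sd
    with np.errstate(invalid="ignore"):
        dist = np.sqrt(((z_tab - z_obs) ** 2).sum(axis=1))
    # a simulation lacking a statistic the observation has cannot be close
    dist[~np.isfinite(dist)] = np.inf
    order = np.argsort(dist, kind="stable")[:k]
    return ABCPosterior(
        window_starts=table.window_starts,
        accepted_ne=table.ne[order],
        distances=dist[order],
        accepted_idx=order,
        acceptance_rate=acceptance_rate,
        n_sims=table.n_sims,
    )


def posterior_trajectory(
    posteriors, gen_time: float = 2.5
) -> pd.DataFrame:
    """Pool accepted histories across posteriors; per-window median and
    90% credible interval.

    Returns a table with window start in generations and years, the
    median Ne and the 5%/95% quantiles.
    """
    if isinstance(posteriors, ABCPosterior):
        posteriors = [posteriors]
    posteriors = list(posteriors)
    if not posteriors:
        raise ValueError("need at least one posterior")
    times = posteriors[0].window_starts
    for p in posteriors[1:]:
        if not np.allclose(p.window_starts, times):
            raise ValueError("posteriors use different window grids")
    pooled = np.vstack([p.accepted_ne for p in posteriors])
    logq = np.quantile(np.log10(pooled), [0.05, 0.5, 0.95], axis=0)
    return pd.DataFrame(
        {
            "window_start_gen": times,
            "window_start_years": times * gen_time,
            "ne_median": 10.0 ** logq[1],
            "ne_q05": 10.0 ** logq[0],
            "ne_q95": 10.0 ** logq[2],
            "n_pooled": pooled.shape[0],
        }
    )


def prediction_error_cv(
    table: ReferenceTable,
    n_validation: int,
    acceptance_rate: float,
    seed: int = 1,
) -> tuple[np.ndarray, float]:
    """Leave-out cross-validated standardized prediction error.

    For each of ``n_validation`` random rows, rejection ABC runs against
    the remaining rows with that row's statistics as pseudo-observation;
    the per-window error is the mean squared difference between the
    posterior-median and true log10 Ne, divided by the prior variance of
    log10 Ne in that window (estimated from the whole table).  1 means no
    better than the prior.  Returns ``(per-window errors, mean error)``.
    """
    if not 0 < n_validation < table.n_sims:
        raise ValueError("n_validation must be in (0, table size)")
    rng = np.random.default_rng(seed)
    rows = rng.choice(table.n_sims, size=n_validation, replace=False)
    log_ne = np.log10(table.ne)
    prior_var = log_ne.var(axis=0)

    sq_err = np.zeros((n_validation, table.ne.shape[1]))
    mask = np.ones(table.n_sims, dtype=bool)
    for out, row in enumerate(rows):
        mask[row] = False
        sub = ReferenceTable(
            window_starts=table.window_starts,
            ne=table.ne[mask],
            stats=table.stats[mask],
            stat_names=table.stat_names,
            bins=table.bins,
            config=table.config,
        )
        post = rejection_abc(table.stats[row], sub, acceptance_rate)
        est = np.median(np.log10(post.accepted_ne), axis=0)
        sq_err[out] = (est - log_ne[row]) ** 2
        mask[row] = True

    per_window = sq_err.mean(axis=0) / prior_var
    return per_window, float(per_window.mean())
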