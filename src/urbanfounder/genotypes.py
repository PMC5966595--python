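"""Core genotype-matrix and sample-metadata containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype in a dosage matrix.
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotypes as alternate-allele dosages.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_sites)`` integer array with entries in
        ``{0, 1, 2}`` or :data:`MISSING`.
    positions
        0-based position of each site on its scaffold.  Strictly
        increasing within each scaffold.
    scaffold
        Scaffold identifier per site.  Sites of one scaffold must be
        contiguous.
    sample_ids
        Ordered individual identifiers, one per dosage row.
    site_depth
        Optional mean read depth per site (used by the depth filter).
    scaffold_lengths
        Optional mapping of scaffold id to length in bp; needed for
        SNP-density and long-scaffold selection.
    """

    dosages: np.ndarray
    positions: np.ndarray
    scaffold: np.ndarray
    sample_ids: list[str]
    site_depth: np.ndarray | None = None
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.scaffold = np.asarray(self.scaffold, dtype=object)
        if self.site_depth is not None:
            self.site_depth = np.asarray(self.site_depth, dtype=float)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x sites)")
        n_ind, n_sites = self.dosages.shape
        if len(self.sample_ids) != n_ind:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_ind} dosage rows"
            )
        if len(set(self.sample_ids)) != n_ind:
            raise ValueError("duplicate sample ids")
        if self.positions.shape != (n_sites,) or self.scaffold.shape != (n_sites,):
            raise ValueError("positions/scaffold must have one entry per site")
        ok = (self.dosages == MISSING) | (
            (self.dosages >= 0) & (self.dosages <= 2)
        )
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid dosage {self.dosages[tuple(bad)]} at row {bad[0]}, site {bad[1]}"
            )
        for scaf in pd.unique(self.scaffold):
            pos = self.positions[self.scaffold == scaf]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")
        if self.site_depth is not None and self.site_depth.shape != (n_sites,):
            raise ValueError("site_depth must have one entry per site")

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        idx = np.asarray(idx, dtype=np.int64) if np.size(idx) else np.zeros(0, np.int64)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            positions=self.positions[idx],
            scaffold=self.scaffold[idx],
            sample_ids=list(self.sample_ids),
            site_depth=None if self.site_depth is None else self.site_depth[idx],
            scaffold_lengths=dict(self.scaffold_lengths),
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given individual indices (order preserved)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            positions=self.positions,
            scaffold=self.scaffold,
            sample_ids=[self.sample_ids[i] for i in idx],
            site_depth=self.site_depth,
            scaffold_lengths=dict(self.scaffold_lengths),
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, number of called alleles)."""
        called = self.dosages != MISSING
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def minor_allele_counts(self) -> np.ndarray:
        alt, total = self.allele_counts()
        return np.minimum(alt, total - alt)

    def missing_counts(self) -> np.ndarray:
        """Number of individuals with a missing genotype, per site."""
        return (self.dosages == MISSING).sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.dosages.shape == other.dosages.shape
            and np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.scaffold, other.scaffold)
        )


@dataclass
class SampleInfo:
    """Per-individual metadata: population label, habitat, coordinates."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "population", "habitat", "longitude", "latitude")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids in metadata: {list(dup)}")
        bad_hab = set(self.table["habitat"]) - {"urban", "rural"}
        if bad_hab:
            raise ValueError(f"habitat must be urban/rural, got {bad_hab}")
        # habitat must be constant within a population label
        per_pop = self.table.groupby("population")["habitat"].nunique()
        mixed = per_pop[per_pop > 1]
        if len(mixed):
            raise ValueError(f"mixed habitat within population(s): {list(mixed.index)}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_file(cls, path) -> "SampleInfo":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df)

    def to_file(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.table["population"]))

    def samples_in(self, population: str) -> list[str]:
        if population not in set(self.table["population"]):
            raise KeyError(f"unknown population label: {population!r}")
        mask = self.table["population"] == population
        return list(self.table.loc[mask, "sample_id"])

    def habitat_of(self, population: str) -> str:
        mask = self.table["population"] == population
        if not mask.any():
            raise KeyError(f"unknown population label: {population!r}")
        return self.table.loc[mask, "habitat"].iloc[0]

    def indices_of(self, gm: GenotypeMatrix, population: str) -> np.ndarray:
        """Row indices in *gm* of the individuals of *population*."""
        wanted = set(self.samples_in(population))
        return np.array(
            [i for i, s in enumerate(gm.sample_ids) if s in wanted], dtype=np.int64
        )


def make_toy_genotypes(
    rows,
    positions=None,
    scaffold="scaf1",
    sample_ids=None,
    scaffold_lengths=None,
) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from an inline dosage table.

    ``rows`` is a sequence of equal-length dosage sequences, one per
    individual; :data:`MISSING` entries are preserved.  Positions default
    to 0, 100, 200, ...
    """
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"ragged dosage rows: lengths {sorted(lengths)}")
    dosages = np.asarray(rows, dtype=np.int8)
    n_ind, n_sites = dosages.shape
    if positions is None:
        positions = np.arange(n_sites, dtype=np.int64) * 100
    if isinstance(scaffold, str):
        scaffold = np.array([scaffold] * n_sites, dtype=object)
    if sample_ids is None:
        sample_ids = [f"ind{i}" for i in range(n_ind)]
    return GenotypeMatrix(
        dosages=dosages,
        positions=np.asarray(positions),
        scaffold=np.asarray(scaffold, dtype=object),
        sample_ids=list(sample_ids),
        scaffold_lengths=scaffold_lengths or {},
    )
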