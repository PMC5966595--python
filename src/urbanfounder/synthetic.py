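"""Synthetic study fixtures: multi-population founder-event demographies
with spatial metadata, so the whole pipeline can run and be validated
without external data.

The design mirrors a 7-population urban-colonization layout: three
widely spaced rural source populations, four recently founded urban
populations (two cities share one rural source).  Within-population
isolation-by-distance comes from a 1-D stepping-stone of sub-demes whose
locations set the sample coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleInfo
from .inference import SimulationConfig
from .variant_io import write_vcf

#: (urban population, paired rural source) layout of the default design.
DEFAULT_CITY_MAP = {
    "BB1_urban": "BB_rural",
    "BB2_urban": "BB_rural",
    "SV_urban": "SV_rural",
    "TA_urban": "TA_rural",
}


@dataclass
class StudyDesign:
    """Demographic and spatial design of the synthetic study.

    Urban populations split from their paired rural source
    ``colonization_gen`` generations ago through a brief founder
    bottleneck of ``urban_founders`` diploids, then grow to
    ``urban_ne`` with restricted gene flow back to the source.
    ``ibd_strength`` scales within-population isolation-by-distance
    (larger = stronger, by reducing sub-deme migration).
    """

    city_map: dict = field(default_factory=lambda: dict(DEFAULT_CITY_MAP))
    samples_per_pop: int = 20
    rural_ne: float = 20_000.0
    urban_ne: float = 1000.0
    urban_founders: int = 60
    colonization_gen: float = 25.0
    rural_split_gen: float = 200.0
    migration_rate: float = 1e-3          # urban <-> paired rural, per gen
    n_sub: int = 4                        # stepping-stone sub-demes per pop
    m_sub_urban: float = 0.05             # adjacent sub-deme migration
    m_sub_rural: float = 0.002
    ibd_strength: float = 1.0
    city_spacing_km: float = 150.0
    urban_extent_km: float = 3.0
    rural_extent_km: float = 40.0
    origin_lon: float = -62.0
    origin_lat: float = -38.5
    seed: int = 1

    def __post_init__(self) -> None:
        if not (3 <= self.colonization_gen <= 500):
            raise ValueError("colonization_gen must lie in [3, 500]")
        if self.urban_founders < 2:
            raise ValueError("urban_founders must be >= 2")
        if self.n_sub < 2:
            raise ValueError("need >= 2 sub-demes for isolation-by-distance")
        missing = [r for r in self.city_map.values() if not r]
        if missing or not self.city_map:
            raise ValueError("every urban population needs a paired rural source")

    @property
    def rural_pops(self) -> list[str]:
        return sorted(set(self.city_map.values()))

    @property
    def urban_pops(self) -> list[str]:
        return list(self.city_map)

    @property
    def populations(self) -> list[str]:
        return self.urban_pops + self.rural_pops


def _deme(pop: str, k: int) -> str:
    return f"{pop}_d{k}"


def _build_demography(design: StudyDesign) -> msprime.Demography:
    dem = msprime.Demography()
    m_urban = design.m_sub_urban / design.ibd_strength
    m_rural = design.m_sub_rural / design.ibd_strength

    for pop in design.rural_pops:
        for k in range(design.n_sub):
            dem.add_population(
                name=_deme(pop, k), initial_size=design.rural_ne / design.n_sub
            )
    for pop in design.urban_pops:
        for k in range(design.n_sub):
            dem.add_population(
                name=_deme(pop, k), initial_size=design.urban_ne / design.n_sub
            )
    dem.add_population(name="ancestral", initial_size=design.rural_ne)

    # stepping-stone migration between adjacent sub-demes
    for pop in design.populations:
        m = m_urban if pop in design.city_map else m_rural
        for k in range(design.n_sub - 1):
            dem.set_symmetric_migration_rate([_deme(pop, k), _deme(pop, k + 1)], m)
    # restricted urban <-> paired-rural gene flow through gateway demes
    for urban, rural in design.city_map.items():
        dem.set_symmetric_migration_rate(
            [_deme(urban, 0), _deme(rural, 0)], design.migration_rate
        )

    # founder bottleneck just before the split (backwards in time)
    t_bottleneck = max(design.colonization_gen - 2.0, 1.0)
    for urban in design.urban_pops:
        for k in range(design.n_sub):
            dem.add_population_parameters_change(
                time=t_bottleneck,
                population=_deme(urban, k),
                initial_size=design.urban_founders / design.n_sub,
            )
    # rural gateway demes are ancestral to the urban splits; msprime would
    # otherwise mark them inactive before the split time
    for pop in design.populations:
        for k in range(design.n_sub):
            dem[_deme(pop, k)].initially_active = True

    by_rural: dict[str, list[str]] = {}
    for urban, rural in design.city_map.items():
        by_rural.setdefault(rural, []).extend(
            _deme(urban, k) for k in range(design.n_sub)
        )
    for rural, derived in by_rural.items():
        dem.add_population_split(
            time=design.colonization_gen, derived=derived, ancestral=_deme(rural, 0)
        )
    dem.add_population_split(
        time=design.rural_split_gen,
        derived=[_deme(p, k) for p in design.rural_pops for k in range(design.n_sub)],
        ancestral="ancestral",
    )
    dem.sort_events()
    return dem


def _sample_coordinates(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Sample ids, deme assignment and lon/lat for all individuals.

    Rural populations sit on a coarse grid ``city_spacing_km`` apart;
    each urban population is offset ~1/5 of that from its source.
    Sub-demes are strung along a line (urban: ``urban_extent_km``,
    rural: ``rural_extent_km``) and individuals jitter around their
    sub-deme, so genetic similarity and distance covary.
    """
    km_per_deg = 111.0
    centres: dict[str, tuple[float, float]] = {}
    for i, pop in enumerate(design.rural_pops):
        centres[pop] = (i * design.city_spacing_km, 0.0)
    seen: dict[str, int] = {}
    for urban, rural in design.city_map.items():
        j = seen.get(rural, 0)
        seen[rural] = j + 1
        cx, cy = centres[rural]
        centres[urban] = (
            cx + design.city_spacing_km / 5.0,
            cy + design.city_spacing_km / 5.0 * (1 + j),
        )

    rows = []
    per_deme = _samples_per_deme(design)
    for pop in design.populations:
        extent = (
            design.urban_extent_km if pop in design.city_map else design.rural_extent_km
        )
        step = extent / (design.n_sub - 1)
        cx, cy = centres[pop]
        i_local = 0
        for k in range(design.n_sub):
            for _ in range(per_deme[pop][k]):
                x = cx + k * step + rng.normal(0, step / 6)
                y = cy + rng.normal(0, step / 6)
                rows.append(
                    {
                        "sample_id": f"{pop}_{i_local:02d}",
                        "population": pop,
                        "habitat": "urban" if pop in design.city_map else "rural",
                        "longitude": design.origin_lon + x / km_per_deg,
                        "latitude": design.origin_lat + y / km_per_deg,
                        "deme": _deme(pop, k),
                    }
                )
                i_local += 1
    return pd.DataFrame(rows)


def _samples_per_deme(design: StudyDesign) -> dict[str, list[int]]:
    base, extra = divmod(design.samples_per_pop, design.n_sub)
    counts = [base + (1 if k < extra else 0) for k in range(design.n_sub)]
    return {pop: list(counts) for pop in design.populations}


def generate_study_matrix(
    design: StudyDesign, cfg: SimulationConfig
) -> tuple[GenotypeMatrix, SampleInfo]:
    """Simulate the full study: returns the genotype matrix and metadata.

    ``cfg.n_seg`` independent segments of ``cfg.seq_len`` bp are
    simulated under the founder-event demography; ``cfg.n_ind`` is
    ignored (sampling follows the design).
    """
    rng = np.random.default_rng(design.seed)
    coords = _sample_coordinates(design, rng)
    dem = _build_demography(design)
    sample_sets = [
        msprime.SampleSet(int(n), population=deme, ploidy=2)
        for deme, n in coords.groupby("deme", sort=False).size().items()
    ]

    seeds = (
        np.random.SeedSequence(design.seed).generate_state(2 * cfg.n_seg)
        % (2**31 - 1) + 1
    )
    cols, positions, scafs = [], [], []
    scaffold_lengths = {}
    for s in range(cfg.n_seg):
        name = f"scaf{s}"
        scaffold_lengths[name] = int(cfg.seq_len)
        ts = msprime.sim_ancestry(
            samples=sample_sets,
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
            hap = ts.genotype_matrix()
            cols.append((hap[:, ::2] + hap[:, 1::2]).T)
            positions.append(ts.sites_position.astype(np.int64))
            scafs.append(np.array([name] * ts.num_sites, dtype=object))

    n_ind = len(coords)
    gm = GenotypeMatrix(
        dosages=np.concatenate(cols, axis=1) if cols else np.zeros((n_ind, 0), np.int8),
        positions=np.concatenate(positions) if cols else np.zeros(0, np.int64),
        scaffold=np.concatenate(scafs) if cols else np.zeros(0, object),
        sample_ids=list(coords["sample_id"]),
        scaffold_lengths=scaffold_lengths,
    )
    info = SampleInfo(coords.drop(columns=["deme"]))
    return gm, info


def generate_study_fixture(
    design: StudyDesign, cfg: SimulationConfig, vcf_path, metadata_path
) -> tuple[GenotypeMatrix, SampleInfo]:
    """Simulate the study and write VCF + metadata TSV files."""
    gm, info = generate_study_matrix(design, cfg)
    write_vcf(gm, vcf_path)
    info.to_file(metadata_path)
    return gm, info
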