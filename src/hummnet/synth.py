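"""Synthetic visitation records and biogeography tables with known structure.

The network generator emulates the statistical shape of a compiled
continental visitation data set -- on the order of 292 hummingbird species,
1287 plant species and ~4500 species-level interactions aggregated into 9
clades and ~100 families -- while giving the analyst a dial for each
structural property:

* heavy-tailed clade and family sizes (a few speciose groups, many small);
* nestedness through a latent generalism model: species i and j interact
  with probability proportional to exp(eta * (u_i + v_j)) for latent scores
  u, v, so eta = 0 yields an unstructured (ER-like) matrix and large eta a
  strongly nested one;
* modularity through block structure: when bird and plant guilds are split
  into blocks, off-block interaction probabilities are multiplied by
  (1 - block_affinity), so affinity 0 means no modules and affinity near 1
  near-disconnected compartments.

The biogeography generator draws per-species multi-region occupancy from
clade-center-specific odds, so the niche-conservatism GLM has a known true
odds ratio to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biogeo import SpeciesBiogeo
from .matrix import CLADES, SYNDROMES, InteractionRecord, TaxonMaps

__all__ = [
    "NetworkGenConfig",
    "BiogeoGenConfig",
    "generate_records",
    "generate_biogeo",
    "records_to_species_matrix",
]

FILL_TOLERANCE = 0.10
FILL_RETRIES = 50


@dataclass(frozen=True)
class NetworkGenConfig:
    n_bird_species: int = 292
    n_plant_species: int = 1287
    n_clades: int = 9
    n_families: int = 100
    target_fill: float = 0.012  # species-level fill, ~4500 of 292*1287
    eta: float = 2.0  # nestedness strength; 0 = unstructured
    n_blocks: int = 0
    block_affinity: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.target_fill < 1):
            raise ValueError("target_fill must be in (0, 1)")
        if self.n_clades > self.n_bird_species:
            raise ValueError("n_clades cannot exceed n_bird_species")
        if self.n_families > self.n_plant_species:
            raise ValueError("n_families cannot exceed n_plant_species")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if not (0 <= self.block_affinity <= 1):
            raise ValueError("block_affinity must be in [0, 1]")


@dataclass(frozen=True)
class BiogeoGenConfig:
    n_species_per_clade: dict = field(
        default_factory=lambda: {c: 36 for c in CLADES if c != "Patagona"}
    )
    center_by_clade: dict = field(
        default_factory=lambda: {
            c: ("North America" if c in ("Bees", "Mountain Gems") else "South America")
            for c in CLADES
        }
    )
    # odds of occupying >= 2 regions, by diversification center
    colonization_odds: dict = field(
        default_factory=lambda: {"North America": 1.06, "South America": 0.118}
    )
    p_success_near: float = 0.55  # success realized as Nearctic+Neotropical vs Neo+Austral
    lat_max_mean: float = 10.0
    lat_max_sd: float = 12.0
    lat_range_mean: float = 14.0
    lat_range_sd: float = 10.0
    elev_min_mean: float = 500.0
    elev_min_sd: float = 500.0
    elev_range_mean: float = 1500.0
    elev_range_sd: float = 800.0
    seed: int = 0

    def __post_init__(self):
        for center, odds in self.colonization_odds.items():
            if odds <= 0:
                raise ValueError(f"odds for {center!r} must be positive")


def _heavy_tailed_sizes(n_items: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Group sizes ~ Zipf-like weights, each group non-empty, summing to n_items."""
    weights = 1.0 / np.arange(1, n_groups + 1) ** 1.2
    rng.shuffle(weights)
    sizes = np.maximum(1, np.floor(weights / weights.sum() * n_items).astype(int))
    while sizes.sum() > n_items:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_items:
        sizes[rng.integers(0, n_groups)] += 1
    return sizes


def _calibrate_scale(weights: np.ndarray, target_links: float) -> float:
    """Bisection for s such that sum(min(1, s*w)) hits the target link count."""
    lo, hi = 0.0, 1.0
    while np.minimum(1.0, hi * weights).sum() < target_links:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("infeasible fill: cannot reach target link count")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.minimum(1.0, mid * weights).sum() < target_links:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_records(config: NetworkGenConfig) -> tuple:
    """Sample species-level visitation records plus matching taxon maps.

    Returns ``(records, maps)``.  The realized species-level fill is kept
    within +/-10% of ``target_fill`` by rejection sampling (exact fill would
    distort the probabilistic structure); deterministic under ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    nb, npl = config.n_bird_species, config.n_plant_species

    clade_names = list(CLADES[: config.n_clades])
    if config.n_clades > len(CLADES):
        clade_names += [f"Clade{k}" for k in range(len(CLADES), config.n_clades)]
    family_names = [f"Fam{k + 1:03d}" for k in range(config.n_families)]

    clade_sizes = _heavy_tailed_sizes(nb, config.n_clades, rng)
    family_sizes = _heavy_tailed_sizes(npl, config.n_families, rng)
    bird_clade_idx = np.repeat(np.arange(config.n_clades), clade_sizes)
    plant_family_idx = np.repeat(np.arange(config.n_families), family_sizes)

    birds = [f"Bird{i + 1:04d}" for i in range(nb)]
    plants = [f"Plant{j + 1:04d}" for j in range(npl)]

    u = rng.random(nb)
    v = rng.random(npl)
    weights = np.exp(config.eta * (u[:, None] + v[None, :] - 1.0))
    if config.n_blocks > 0:
        bird_block = bird_clade_idx % config.n_blocks
        plant_block = plant_family_idx % config.n_blocks
        off_block = bird_block[:, None] != plant_block[None, :]
        weights = weights * np.where(off_block, 1.0 - config.block_affinity, 1.0)

    target_links = config.target_fill * nb * npl
    scale = _calibrate_scale(weights.ravel(), target_links)
    p = np.minimum(1.0, scale * weights)

    for _ in range(FILL_RETRIES):
        cells = rng.random((nb, npl)) < p
        fill = cells.sum() / cells.size
        if abs(fill - config.target_fill) <= FILL_TOLERANCE * config.target_fill:
            break
    else:
        raise ValueError("infeasible fill: realized fill never landed within the tolerance band")

    ii, jj = np.nonzero(cells)
    records = [
        InteractionRecord(birds[i], plants[j], source_id="synthetic", plant_native=True)
        for i, j in zip(ii, jj)
    ]
    syndromes = rng.choice(SYNDROMES, size=config.n_families, p=[0.14, 0.36, 0.50])
    maps = TaxonMaps(
        bird_to_clade={birds[i]: clade_names[bird_clade_idx[i]] for i in range(nb)},
        plant_to_family={plants[j]: family_names[plant_family_idx[j]] for j in range(npl)},
        family_syndrome=dict(zip(family_names, syndromes)),
    )
    return records, maps


def records_to_species_matrix(records) -> "BipartiteMatrix":
    """Species-level plant-by-bird matrix straight from visitation records.

    Group-level aggregation (clade x family) saturates cells when groups are
    large, damping the generator's structural dials; this view exposes the
    nestedness/modularity structure at the resolution where it is injected.
    """
    from .matrix import BipartiteMatrix

    birds = sorted({r.bird_species for r in records})
    plants = sorted({r.plant_species for r in records})
    bi = {b: i for i, b in enumerate(birds)}
    pi = {p: i for i, p in enumerate(plants)}
    cells = np.zeros((len(plants), len(birds)), dtype=np.int8)
    for r in records:
        cells[pi[r.plant_species], bi[r.bird_species]] = 1
    return BipartiteMatrix(plants, birds, cells, "given")


def generate_biogeo(config: BiogeoGenConfig) -> list:
    """Sample a per-species biogeography table with known colonization odds.

    Success (>= 2 regions) is drawn per species from its clade center's
    odds; failures occupy the Neotropics only.  Latitude and elevation
    extremes are drawn from the configured normals with min <= max enforced.
    """
    rng = np.random.default_rng(config.seed)
    table = []
    for clade, n in sorted(config.n_species_per_clade.items()):
        center = config.center_by_clade[clade]
        odds = config.colonization_odds[center]
        p_success = odds / (1.0 + odds)
        for k in range(n):
            success = rng.random() < p_success
            if success:
                if rng.random() < config.p_success_near:
                    near, neo, aus = True, True, False
                else:
                    near, neo, aus = False, True, True
            else:
                near, neo, aus = False, True, False
            lat_max = rng.normal(config.lat_max_mean, config.lat_max_sd)
            lat_min = lat_max - abs(rng.normal(config.lat_range_mean, config.lat_range_sd))
            elev_min = abs(rng.normal(config.elev_min_mean, config.elev_min_sd))
            elev_max = elev_min + abs(rng.normal(config.elev_range_mean, config.elev_range_sd))
            table.append(SpeciesBiogeo(
                species=f"{clade.replace(' ', '')}_sp{k + 1:03d}",
                clade=clade,
                nearctic=near, neotropical=neo, austral=aus,
                lat_max=float(lat_max), lat_min=float(lat_min),
                elev_min=float(elev_min), elev_max=float(elev_max),
                diversification_center=center,
            ))
    return table
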