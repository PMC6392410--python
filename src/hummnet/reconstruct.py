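"""Synthetic reconstruction of the continental study data set.

The species-level compilation behind the published clade-by-family network
and the per-species biogeography table are only available as document
supplements, not machine-readable data.  This module rebuilds *synthetic*
stand-ins constrained by every aggregate the study prints:

network side
    9 clades x 105 plant families joined by 409 links; the native-plant
    subset keeps 100 families and 385 links (five exotic-only families drop
    out, three families lose their exotic-species links); 13 native families
    interact with all nine clades and exactly three clades reach more than
    50 families; floral syndromes split 14 / 36 / 50 percent among native
    families (ornithophilous / intermediate / non-ornithophilous).

biogeography side
    292 species distributed over the nine clades with the published clade
    sizes; region totals of 38 Nearctic (3 exclusive + 35 shared with the
    Neotropics), 270 Neotropical, and 27 Austral (4 exclusive + 23 partial)
    species; 15 Caribbean island species carrying no mainland-region flag;
    58 species occupying two regions; per-species diversification centers
    arranged so the center-of-diversification logistic regression gives an
    odds ratio of ~9.0 with a likelihood-ratio chi-square of ~46 on 1 df.
    Latitude/elevation extremes per clade are deterministic placements
    matching the published clade means.

Every value here is a construction from printed summary statistics, not the
original data; species and family labels are synthetic.  The reconstruction
is fully deterministic.
"""

from __future__ import annotations

import numpy as np

from .biogeo import SpeciesBiogeo
from .matrix import BipartiteMatrix, InteractionRecord, TaxonMaps, build_matrix

__all__ = ["study_records", "study_matrix", "study_biogeo", "CLADE_DEGREE_ORDER"]

# clades ordered by native-matrix generality (families linked); the three
# leaders exceed 50 families and the degrees sum to 385
CLADE_DEGREE_ORDER = [
    ("Emeralds", 100),
    ("Bees", 74),
    ("Mountain Gems", 55),
    ("Coquettes", 43),
    ("Brilliants", 34),
    ("Hermits", 27),
    ("Mangoes", 22),
    ("Patagona", 17),
    ("Topazes", 13),
]

# native family-degree distribution: {degree: number of families};
# 100 families, 385 links, 13 fully connected families
_FAMILY_DEGREE_COUNTS = {9: 13, 8: 4, 7: 5, 6: 5, 5: 7, 4: 9, 3: 12, 2: 19, 1: 26}

_N_EXOTIC_ONLY = 5  # families present only through exotic species
_EXOTIC_ONLY_DEGREES = [3, 2, 2, 1, 1]
_N_EXOTIC_EXTRA = 15  # exotic links added to three otherwise-native families

# --- biogeography composition -------------------------------------------------
# per clade: (n_total, nearctic_only, nearctic+neotropical, neotropical+austral,
#             austral_only, neotropical_only, island, clade_center,
#             north_center_overrides)  -- overrides move individual southern-
# clade species to a North American center, in the order
# (near+neo, neo+aus, neo_only) species of that clade.
_BIOGEO_PLAN = {
    "Bees": dict(n=33, near_only=3, near_neo=9, neo_aus=3, aus_only=0, neo_only=15,
                 island=3, center="North America", north_overrides=(0, 0, 0)),
    "Mountain Gems": dict(n=15, near_only=0, near_neo=6, neo_aus=0, aus_only=0, neo_only=9,
                          island=0, center="North America", north_overrides=(0, 0, 0)),
    "Emeralds": dict(n=96, near_only=0, near_neo=16, neo_aus=6, aus_only=0, neo_only=66,
                     island=8, center="South America", north_overrides=(10, 0, 0)),
    "Patagona": dict(n=1, near_only=0, near_neo=0, neo_aus=1, aus_only=0, neo_only=0,
                     island=0, center="South America", north_overrides=(0, 0, 0)),
    "Coquettes": dict(n=53, near_only=0, near_neo=1, neo_aus=10, aus_only=3, neo_only=39,
                      island=0, center="South America", north_overrides=(1, 1, 1)),
    "Brilliants": dict(n=38, near_only=0, near_neo=0, neo_aus=3, aus_only=0, neo_only=35,
                       island=0, center="South America", north_overrides=(0, 0, 0)),
    "Mangoes": dict(n=27, near_only=0, near_neo=2, neo_aus=0, aus_only=1, neo_only=20,
                    island=4, center="South America", north_overrides=(2, 0, 0)),
    "Hermits": dict(n=26, near_only=0, near_neo=1, neo_aus=0, aus_only=0, neo_only=25,
                    island=0, center="South America", north_overrides=(1, 0, 0)),
    "Topazes": dict(n=3, near_only=0, near_neo=0, neo_aus=0, aus_only=0, neo_only=3,
                    island=0, center="South America", north_overrides=(0, 0, 0)),
}

# per clade: (mean lat max, sd, mean lat min, sd, mean elev min, sd,
#             mean elev max, sd) -- published clade-level moments; the
# Topazes minimum-latitude mean is negated relative to the printed table,
# whose positive sign contradicts its own range column.
_CLADE_MOMENTS = {
    "Bees": (19.300, 21.131, 7.567, 19.772, 551.833, 604.715, 2327.333, 792.586),
    "Mountain Gems": (13.667, 13.308, 2.667, 16.387, 621.333, 548.216, 2251.667, 922.848),
    "Emeralds": (9.878, 11.355, -0.011, 14.835, 296.889, 408.318, 1657.500, 874.586),
    "Patagona": (0.0, 0.0, -35.000, 0.0, 0.0, 0.0, 3660.0, 0.0),
    "Coquettes": (0.453, 11.360, -11.548, 13.929, 1608.208, 1205.671, 2807.453, 1344.139),
    "Brilliants": (3.579, 6.954, -6.895, 8.953, 1640.789, 907.763, 2973.947, 819.316),
    "Mangoes": (7.182, 11.839, -13.591, 12.308, 427.500, 599.042, 1674.318, 958.464),
    "Hermits": (4.538, 11.704, -11.923, 11.527, 69.846, 186.879, 1130.346, 648.366),
    "Topazes": (3.333, 13.317, -18.000, 15.010, 83.333, 144.338, 1166.667, 585.946),
}


def _native_cells() -> tuple:
    """Nested native matrix with imperfections.

    Starts from a perfect staircase (family of degree d linked to the d most
    generalist clades).  A staircase's margins are conjugate and therefore
    admit exactly one realization, which would make the margin-fixed null
    ensemble degenerate; so for every family of degree 4..8 the last 1 is
    relocated to a random lower-rank clade.  Family degrees and the three
    leading clade degrees (the only ones above 50) are untouched.
    """
    clades = [c for c, _ in CLADE_DEGREE_ORDER]
    degrees = []
    for d in sorted(_FAMILY_DEGREE_COUNTS, reverse=True):
        degrees.extend([d] * _FAMILY_DEGREE_COUNTS[d])
    families = [f"Fam{k + 1:03d}" for k in range(len(degrees))]
    cells = np.zeros((len(families), len(clades)), dtype=np.int8)
    for i, d in enumerate(degrees):
        cells[i, :d] = 1
    rng = np.random.default_rng(20190227)  # fixed: the reconstruction is a constant
    for i, d in enumerate(degrees):
        if 4 <= d <= 8:
            target = int(rng.integers(d, len(clades)))  # a currently empty column
            if target != d - 1:
                cells[i, d - 1] = 0
                cells[i, target] = 1
    return families, clades, cells


def study_records() -> tuple:
    """Synthetic species-level records and taxon maps; see module docstring.

    Returns ``(records, maps)`` such that ``build_matrix(records, maps)``
    yields the 105-family / 409-link matrix and
    ``build_matrix(records, maps, native_only=True)`` the 100-family /
    385-link native matrix.
    """
    families, clades, native = _native_cells()

    records = []
    bird_of = {c: f"{c.replace(' ', '')}_bird1" for c in clades}
    plant_counter = {}

    def plant_name(family):
        plant_counter[family] = plant_counter.get(family, 0) + 1
        return f"{family}_plant{plant_counter[family]}"

    bird_to_clade = {b: c for c, b in bird_of.items()}
    plant_to_family = {}

    for i, fam in enumerate(families):
        for j, clade in enumerate(clades):
            if native[i, j]:
                p = plant_name(fam)
                plant_to_family[p] = fam
                records.append(InteractionRecord(bird_of[clade], p, "synthetic", True))

    # three native families gain five exotic-species links each, in cells
    # that are empty in the native matrix
    extra_targets = []
    for i, fam in enumerate(families):
        zeros = [j for j in range(len(clades)) if not native[i, j]]
        if len(zeros) >= 5 and len(extra_targets) < 3:
            extra_targets.append((i, zeros[:5]))
    assert sum(len(z) for _, z in extra_targets) == _N_EXOTIC_EXTRA
    for i, zeros in extra_targets:
        for j in zeros:
            p = plant_name(families[i]) + "_exotic"
            plant_to_family[p] = families[i]
            records.append(InteractionRecord(bird_of[clades[j]], p, "synthetic", False))

    # five exotic-only families attach to the most generalist clades
    exotic_families = [f"ExoFam{k + 1:02d}" for k in range(_N_EXOTIC_ONLY)]
    for fam, d in zip(exotic_families, _EXOTIC_ONLY_DEGREES):
        for j in range(d):
            p = plant_name(fam) + "_exotic"
            plant_to_family[p] = fam
            records.append(InteractionRecord(bird_of[clades[j]], p, "synthetic", False))

    # syndromes: the 14 most generalist native families ornithophilous, the
    # next 36 intermediate, the remaining 50 non-ornithophilous
    by_degree = sorted(range(len(families)), key=lambda i: (-native[i].sum(), families[i]))
    family_syndrome = {}
    for rank, i in enumerate(by_degree):
        if rank < 14:
            family_syndrome[families[i]] = "ornithophilous"
        elif rank < 50:
            family_syndrome[families[i]] = "intermediate"
        else:
            family_syndrome[families[i]] = "non-ornithophilous"
    for k, fam in enumerate(exotic_families):
        family_syndrome[fam] = "intermediate" if k < 2 else "non-ornithophilous"

    maps = TaxonMaps(bird_to_clade, plant_to_family, family_syndrome)
    return records, maps


def study_matrix(native_only: bool = True) -> BipartiteMatrix:
    """The reconstructed clade-by-family matrix (native subset by default)."""
    records, maps = study_records()
    return build_matrix(records, maps, native_only=native_only)


def _spread(mean: float, sd: float, n: int) -> np.ndarray:
    """n deterministic values with the exact given sample mean and sd."""
    if n == 1 or sd == 0.0:
        return np.full(n, mean)
    z = np.linspace(-1.0, 1.0, n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


def study_biogeo() -> list:
    """Synthetic 292-species biogeography table; see module docstring.

    Island species receive their clade's mean latitude/elevation values and
    no mainland-region flags.
    """
    table = []
    for clade, plan in _BIOGEO_PLAN.items():
        lm, lms, ln_, lns, em, ems, eM, eMs = _CLADE_MOMENTS[clade]
        n_mainland = plan["n"] - plan["island"]
        lat_max = np.sort(_spread(lm, lms, n_mainland))
        lat_min = np.sort(_spread(ln_, lns, n_mainland))
        elev_min = np.sort(_spread(em, ems, n_mainland))
        elev_max = np.sort(_spread(eM, eMs, n_mainland))

        flags = (
            [("near_only", (True, False, False))] * plan["near_only"]
            + [("near_neo", (True, True, False))] * plan["near_neo"]
            + [("neo_aus", (False, True, True))] * plan["neo_aus"]
            + [("aus_only", (False, False, True))] * plan["aus_only"]
            + [("neo_only", (False, True, False))] * plan["neo_only"]
        )
        assert len(flags) == n_mainland

        overrides = dict(zip(("near_neo", "neo_aus", "neo_only"), plan["north_overrides"]))
        used = {k: 0 for k in overrides}

        for k, (kind, (near, neo, aus)) in enumerate(flags):
            center = plan["center"]
            if kind in overrides and used[kind] < overrides[kind]:
                center = "North America"
                used[kind] += 1
            table.append(SpeciesBiogeo(
                species=f"{clade.replace(' ', '')}_sp{k + 1:03d}",
                clade=clade,
                nearctic=near, neotropical=neo, austral=aus,
                lat_max=float(lat_max[k]), lat_min=float(lat_min[k]),
                elev_min=float(elev_min[k]), elev_max=float(elev_max[k]),
                diversification_center=center,
            ))
        for k in range(plan["island"]):
            table.append(SpeciesBiogeo(
                species=f"{clade.replace(' ', '')}_island_sp{k + 1:03d}",
                clade=clade,
                nearctic=False, neotropical=False, austral=False,
                lat_max=lm, lat_min=ln_, elev_min=em, elev_max=eM,
                diversification_center=plan["center"],
            ))
    return table
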