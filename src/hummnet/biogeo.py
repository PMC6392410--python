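"""Per-species biogeography tables and clade-level summaries.

Each hummingbird species carries presence flags for the three mainland
biogeographical regions (Nearctic, Neotropical, Austral), its latitudinal
and elevational extremes, its clade, and the geographic center where its
clade's radiation primarily occurred (North vs South America).  Island-only
species (Caribbean endemics) may carry no mainland-region flag.

Summaries aggregate to the clade level: the percentage of each clade's
species present in each region, and mean +/- sd of the latitudinal and
elevational extremes, with the clade's range reported as the difference of
the clade means.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .matrix import CLADES, SYNDROMES, BipartiteMatrix, TaxonMaps

__all__ = [
    "SpeciesBiogeo",
    "CladeSummary",
    "read_biogeo",
    "write_biogeo",
    "species_region_summary",
    "clade_summary",
    "syndrome_summary",
]

CENTERS = ("North America", "South America")


@dataclass(frozen=True)
class SpeciesBiogeo:
    species: str
    clade: str
    nearctic: bool
    neotropical: bool
    austral: bool
    lat_max: float  # northernmost limit, degrees (south negative)
    lat_min: float  # southernmost limit
    elev_min: float  # meters
    elev_max: float
    diversification_center: str

    def __post_init__(self):
        if self.clade not in CLADES:
            raise ValueError(f"unknown clade {self.clade!r}")
        if self.diversification_center not in CENTERS:
            raise ValueError(f"unknown diversification center {self.diversification_center!r}")
        if self.lat_max < self.lat_min:
            raise ValueError(f"{self.species}: lat_max < lat_min")
        if self.elev_max < self.elev_min:
            raise ValueError(f"{self.species}: elev_max < elev_min")

    @property
    def n_regions(self) -> int:
        return int(self.nearctic) + int(self.neotropical) + int(self.austral)


@dataclass(frozen=True)
class CladeSummary:
    clade: str
    n_species: int
    pct_nearctic: float
    pct_neotropical: float
    pct_austral: float
    diversification_center: str
    mean_lat_max: float
    sd_lat_max: float
    mean_lat_min: float
    sd_lat_min: float
    mean_lat_range: float
    mean_elev_min: float
    sd_elev_min: float
    mean_elev_max: float
    sd_elev_max: float
    mean_elev_range: float


_FIELDS = [
    "species", "clade", "nearctic", "neotropical", "austral",
    "lat_max", "lat_min", "elev_min", "elev_max", "diversification_center",
]


def write_biogeo(table, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_FIELDS)
        for s in table:
            w.writerow([
                s.species, s.clade, int(s.nearctic), int(s.neotropical), int(s.austral),
                s.lat_max, s.lat_min, s.elev_min, s.elev_max, s.diversification_center,
            ])


def read_biogeo(path) -> list:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(SpeciesBiogeo(
                row["species"], row["clade"],
                bool(int(row["nearctic"])), bool(int(row["neotropical"])), bool(int(row["austral"])),
                float(row["lat_max"]), float(row["lat_min"]),
                float(row["elev_min"]), float(row["elev_max"]),
                row["diversification_center"],
            ))
    return out


def species_region_summary(table) -> dict:
    """Counts and percentages per region and region combination.

    Percentages are over the full table size (island species with no
    mainland flag count in the denominator).
    """
    if not table:
        raise ValueError("empty biogeography table")
    n = len(table)
    near = sum(s.nearctic for s in table)
    neo = sum(s.neotropical for s in table)
    aus = sum(s.austral for s in table)
    near_only = sum(s.nearctic and not s.neotropical and not s.austral for s in table)
    near_neo = sum(s.nearctic and s.neotropical for s in table)
    aus_only = sum(s.austral and not s.neotropical and not s.nearctic for s in table)
    aus_partial = sum(s.austral and (s.neotropical or s.nearctic) for s in table)
    multi = sum(s.n_regions >= 2 for s in table)

    def pct(x):
        return 100.0 * x / n

    return {
        "n_species": n,
        "nearctic": near, "neotropical": neo, "austral": aus,
        "pct_nearctic": pct(near), "pct_neotropical": pct(neo), "pct_austral": pct(aus),
        "nearctic_exclusive": near_only,
        "nearctic_and_neotropical": near_neo,
        "nearctic_related": near_only + near_neo,
        "pct_nearctic_related": pct(near_only + near_neo),
        "austral_exclusive": aus_only,
        "austral_partial": aus_partial,
        "austral_related": aus_only + aus_partial,
        "pct_austral_related": pct(aus_only + aus_partial),
        "multi_region": multi,
    }


def _mean_sd(values) -> tuple:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def clade_summary(table) -> list:
    """One summary row per clade, in the fixed clade vocabulary order.

    Region percentages use the clade's full species count as denominator;
    the clade's latitudinal/elevational range is the difference of clade
    means (not the mean of per-species ranges).  Standard deviations use the
    n-1 sample convention.
    """
    by_clade = {}
    for s in table:
        by_clade.setdefault(s.clade, []).append(s)
    out = []
    for clade in CLADES:
        if clade not in by_clade:
            continue
        sp = by_clade[clade]
        n = len(sp)
        centers = {s.diversification_center for s in sp}
        center = sorted(centers)[0] if len(centers) == 1 else max(
            centers, key=lambda c: sum(s.diversification_center == c for s in sp)
        )
        lat_max, sd_lat_max = _mean_sd([s.lat_max for s in sp])
        lat_min, sd_lat_min = _mean_sd([s.lat_min for s in sp])
        elev_min, sd_elev_min = _mean_sd([s.elev_min for s in sp])
        elev_max, sd_elev_max = _mean_sd([s.elev_max for s in sp])
        out.append(CladeSummary(
            clade=clade,
            n_species=n,
            pct_nearctic=100.0 * sum(s.nearctic for s in sp) / n,
            pct_neotropical=100.0 * sum(s.neotropical for s in sp) / n,
            pct_austral=100.0 * sum(s.austral for s in sp) / n,
            diversification_center=center,
            mean_lat_max=lat_max, sd_lat_max=sd_lat_max,
            mean_lat_min=lat_min, sd_lat_min=sd_lat_min,
            mean_lat_range=lat_max - lat_min,
            mean_elev_min=elev_min, sd_elev_min=sd_elev_min,
            mean_elev_max=elev_max, sd_elev_max=sd_elev_max,
            mean_elev_range=elev_max - elev_min,
        ))
    return out


def syndrome_summary(maps: TaxonMaps, matrix: BipartiteMatrix) -> dict:
    """Counts and percentages of floral syndromes among the matrix families."""
    missing = [f for f in matrix.rows if f not in maps.family_syndrome]
    if missing:
        raise ValueError(f"families without syndrome annotation: {sorted(missing)}")
    counts = {s: 0 for s in SYNDROMES}
    for f in matrix.rows:
        counts[maps.family_syndrome[f]] += 1
    n = len(matrix.rows)
    return {
        "counts": counts,
        "percentages": {s: 100.0 * c / n for s, c in counts.items()},
        "n_families": n,
    }
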