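"""Bipartite interaction matrices for clade-by-family mutualistic networks.

The central container is :class:`BipartiteMatrix`: a binary plant-family
(rows) by hummingbird-clade (columns) matrix assembled from species-level
visitation records.  A cell is 1 when at least one species of the family was
recorded visiting at least one species of the clade; the matrix is
qualitative by design because visitation counts compiled from heterogeneous
sources are not comparable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InteractionRecord",
    "TaxonMaps",
    "BipartiteMatrix",
    "MatrixFormatError",
    "UnmappedSpeciesError",
    "read_interaction_records",
    "write_interaction_records",
    "build_matrix",
    "order_matrix",
    "read_tip_order",
]

SYNDROMES = ("ornithophilous", "intermediate", "non-ornithophilous")

#: The nine hummingbird clades used as column nodes.
CLADES = (
    "Bees",
    "Brilliants",
    "Coquettes",
    "Emeralds",
    "Hermits",
    "Mangoes",
    "Mountain Gems",
    "Patagona",
    "Topazes",
)

_TRUE = {"true", "1", "native", "yes"}
_FALSE = {"false", "0", "exotic", "no"}


class MatrixFormatError(ValueError):
    """Raised for malformed record/matrix files."""


class UnmappedSpeciesError(KeyError):
    """Raised when records contain species absent from the taxon maps."""

    def __init__(self, kind: str, labels: list[str]):
        self.kind = kind
        self.labels = sorted(labels)
        super().__init__(f"unmapped {kind} species: {', '.join(self.labels)}")


@dataclass(frozen=True)
class InteractionRecord:
    """One species-level visitation record (bird visits flower)."""

    bird_species: str
    plant_species: str
    source_id: str = ""
    plant_native: bool = True

    def __post_init__(self):
        if not self.bird_species:
            raise ValueError("bird_species must be non-empty")
        if not self.plant_species:
            raise ValueError("plant_species must be non-empty")


@dataclass(frozen=True)
class TaxonMaps:
    """Species-to-group lookup tables.

    ``bird_to_clade`` maps each hummingbird species to one of the nine
    clades; ``plant_to_family`` maps plant species to family; and
    ``family_syndrome`` annotates families with a floral pollination
    syndrome (ornithophilous / intermediate / non-ornithophilous).
    """

    bird_to_clade: dict
    plant_to_family: dict
    family_syndrome: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = {c for c in self.bird_to_clade.values() if c not in CLADES}
        if bad:
            raise ValueError(f"unknown clade labels: {sorted(bad)}")
        bad = {s for s in self.family_syndrome.values() if s not in SYNDROMES}
        if bad:
            raise ValueError(f"unknown syndrome labels: {sorted(bad)}")


@dataclass
class BipartiteMatrix:
    """Binary family-by-clade interaction matrix with ordered labels."""

    rows: list
    cols: list
    cells: np.ndarray
    order_mode: str = "unordered"  # {degree, given, unordered}

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.rows), len(self.cols)):
            raise ValueError("cells shape does not match labels")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary")
        if len(set(self.rows)) != len(self.rows) or len(set(self.cols)) != len(self.cols):
            raise ValueError("row/column labels must be unique")

    @property
    def shape(self) -> tuple:
        return self.cells.shape

    @property
    def n_links(self) -> int:
        return int(self.cells.sum())

    @property
    def fill(self) -> float:
        return self.n_links / self.cells.size

    def row_degrees(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    def col_degrees(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def copy(self) -> "BipartiteMatrix":
        return BipartiteMatrix(list(self.rows), list(self.cols), self.cells.copy(), self.order_mode)

    # -- CSV round trip: first row clade labels, first column family labels --
    def write_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow([""] + list(self.cols))
            for label, row in zip(self.rows, self.cells):
                w.writerow([label] + [int(v) for v in row])

    @classmethod
    def read_csv(cls, path, order_mode: str = "given") -> "BipartiteMatrix":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise MatrixFormatError(f"{path}: empty matrix file") from None
            cols = header[1:]
            rows, data = [], []
            for lineno, parts in enumerate(reader, start=2):
                if not parts:
                    continue
                if len(parts) != len(cols) + 1:
                    raise MatrixFormatError(f"{path}:{lineno}: expected {len(cols) + 1} fields")
                rows.append(parts[0])
                try:
                    data.append([int(v) for v in parts[1:]])
                except ValueError:
                    raise MatrixFormatError(f"{path}:{lineno}: non-integer cell") from None
        return cls(rows, cols, np.array(data, dtype=np.int8), order_mode)


def read_interaction_records(path) -> list:
    """Read species-level visitation records from a CSV file.

    The header must name ``bird_species, plant_species, source_id,
    plant_native``; the native flag accepts true/false, 1/0, native/exotic.
    Duplicate (bird, plant) pairs are retained -- collapse happens at matrix
    build time.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = ["bird_species", "plant_species", "source_id", "plant_native"]
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise MatrixFormatError(f"{path}: missing column(s) {', '.join(missing)}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            flag = (row["plant_native"] or "").strip().lower()
            if flag in _TRUE:
                native = True
            elif flag in _FALSE:
                native = False
            else:
                raise MatrixFormatError(
                    f"{path}:{lineno}: unparsable plant_native value {row['plant_native']!r}"
                )
            try:
                records.append(
                    InteractionRecord(
                        row["bird_species"].strip(),
                        row["plant_species"].strip(),
                        (row["source_id"] or "").strip(),
                        native,
                    )
                )
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_interaction_records(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["bird_species", "plant_species", "source_id", "plant_native"])
        for r in records:
            w.writerow([r.bird_species, r.plant_species, r.source_id, str(r.plant_native).lower()])


def build_matrix(records, maps: TaxonMaps, native_only: bool = False) -> BipartiteMatrix:
    """Aggregate species-level records into a binary family-by-clade matrix.

    A single record suffices for a 1.  With ``native_only`` the filter is
    applied at the record level *before* aggregation, so a family remains in
    the native matrix if any native member was visited.  All-zero rows and
    columns are dropped (only families actually used by hummingbirds, and
    clades actually recorded, are nodes).
    """
    if native_only:
        records = [r for r in records if r.plant_native]
    if not records:
        raise ValueError("no records remain after filtering; cannot build a matrix")

    bad_birds = {r.bird_species for r in records} - set(maps.bird_to_clade)
    if bad_birds:
        raise UnmappedSpeciesError("bird", list(bad_birds))
    bad_plants = {r.plant_species for r in records} - set(maps.plant_to_family)
    if bad_plants:
        raise UnmappedSpeciesError("plant", list(bad_plants))

    pairs = {
        (maps.plant_to_family[r.plant_species], maps.bird_to_clade[r.bird_species])
        for r in records
    }
    rows = sorted({fam for fam, _ in pairs})
    cols = sorted({cl for _, cl in pairs})
    ri = {f: i for i, f in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    cells = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for fam, cl in pairs:
        cells[ri[fam], ci[cl]] = 1
    return BipartiteMatrix(rows, cols, cells, order_mode="unordered")


def _degree_order(labels, degrees):
    # descending degree, ties broken alphabetically
    return [lab for lab, _ in sorted(zip(labels, degrees), key=lambda t: (-t[1], t[0]))]


def order_matrix(matrix: BipartiteMatrix, mode: str, row_order=None, col_order=None) -> BipartiteMatrix:
    """Return a re-ordered copy of ``matrix``.

    ``mode='degree'`` sorts rows and columns by descending link count
    (alphabetical tie-break); ``mode='given'`` applies explicit label
    permutations (e.g. phylogenetic tip orders).
    """
    if mode == "degree":
        new_rows = _degree_order(matrix.rows, matrix.row_degrees())
        new_cols = _degree_order(matrix.cols, matrix.col_degrees())
    elif mode == "given":
        new_rows = list(row_order) if row_order is not None else list(matrix.rows)
        new_cols = list(col_order) if col_order is not None else list(matrix.cols)
        for name, new, cur in (("row", new_rows, matrix.rows), ("col", new_cols, matrix.cols)):
            if sorted(new) != sorted(cur):
                missing = sorted(set(cur) - set(new))
                extra = sorted(set(new) - set(cur))
                raise ValueError(
                    f"{name} order is not a permutation (missing: {missing}, extra: {extra})"
                )
    else:
        raise ValueError(f"unknown order mode {mode!r}")

    ri = [matrix.rows.index(r) for r in new_rows]
    ci = [matrix.cols.index(c) for c in new_cols]
    return BipartiteMatrix(new_rows, new_cols, matrix.cells[np.ix_(ri, ci)], order_mode=mode)


def read_tip_order(path) -> list:
    """Tip labels of a single-tree Newick file in left-to-right order.

    Branch lengths are ignored; the traversal order is what matters, since it
    encodes the phylogenetic node ordering used for fixed-order nestedness.
    """
    import dendropy

    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise MatrixFormatError(f"unbalanced parentheses at character {offset}")
    if depth != 0:
        raise MatrixFormatError(f"unbalanced parentheses: {depth} unclosed at end of file")

    trees = dendropy.TreeList.get(data=text, schema="newick")
    if len(trees) != 1:
        raise MatrixFormatError(f"expected exactly one tree, found {len(trees)}")
    return [leaf.taxon.label for leaf in trees[0].leaf_node_iter()]
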