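"""Core containers: marker maps, dosage matrices, pedigrees, QTL sets, phenotypes.

All genotypes are diploid dosage codes (0/1/2 copies of the counted "B"
allele) tied to an ordered multi-chromosome marker map.  Containers are thin
wrappers over numpy arrays / pandas frames that validate the invariants the
rest of the pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

UNKNOWN_PARENT = -1


class DataValidationError(ValueError):
    """Raised when an input file or container violates a structural invariant."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered SNP map: one row per marker, sorted by (chromosome, position_bp).

    The row order defines the panel ordering used everywhere else ("every
    m-th ordered SNP", flanking windows, thinning).
    """

    table: pd.DataFrame  # columns: marker_id, chromosome, position_bp

    def __post_init__(self) -> None:
        required = {"marker_id", "chromosome", "position_bp"}
        if not required.issubset(self.table.columns):
            raise DataValidationError(f"marker map needs columns {sorted(required)}")
        t = self.table
        if t["marker_id"].duplicated().any():
            raise DataValidationError("duplicate marker ids in map")
        if (t["position_bp"] < 0).any():
            raise DataValidationError("negative bp position in map")
        chrom = t["chromosome"].to_numpy()
        pos = t["position_bp"].to_numpy()
        if not (np.diff(chrom) >= 0).all():
            raise DataValidationError("map not sorted by chromosome")
        same = np.diff(chrom) == 0
        if not (np.diff(pos)[same] > 0).all():
            raise DataValidationError("positions not strictly increasing within chromosome")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions_bp(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    def chromosome_indices(self, chrom: int) -> np.ndarray:
        """Panel indices (0-based, in panel order) of the markers on one chromosome."""
        return np.flatnonzero(self.chromosomes == chrom)

    def subset(self, indices: Sequence[int]) -> "MarkerMap":
        idx = np.asarray(indices, dtype=np.int64)
        if len(idx) and not (np.diff(idx) > 0).all():
            raise DataValidationError("subset indices must be strictly increasing")
        return MarkerMap(self.table.iloc[idx].reset_index(drop=True))

    def indices_of(self, marker_ids: Sequence[str]) -> np.ndarray:
        """Panel indices of the given marker ids (raises if any is absent)."""
        lookup = pd.Index(self.table["marker_id"])
        pos = lookup.get_indexer(list(marker_ids))
        if (pos < 0).any():
            missing = [m for m, p in zip(marker_ids, pos) if p < 0]
            raise KeyError(f"marker ids not in map: {missing[:5]}")
        return pos.astype(np.int64)


@dataclass
class GenotypeMatrix:
    """Individuals x ordered markers dosage matrix (codes 0/1/2, no missing)."""

    dosage: np.ndarray  # (n_individuals, n_markers) small-int codes
    individual_ids: list[str]
    map: MarkerMap

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise DataValidationError("dosage must be 2-D (individuals x markers)")
        if self.dosage.shape[1] != len(self.map):
            raise DataValidationError(
                f"dosage has {self.dosage.shape[1]} columns but map has {len(self.map)} markers"
            )
        if self.dosage.shape[0] != len(self.individual_ids):
            raise DataValidationError("individual_ids length mismatch")
        bad = (self.dosage < 0) | (self.dosage > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataValidationError(
                f"dosage code {self.dosage[i, j]} not in {{0,1,2}} at row {i}, column {j}"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise DataValidationError("duplicate individual ids")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the counted allele per marker."""
        return self.dosage.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_frequencies()
        return np.minimum(f, 1.0 - f)

    def subset_markers(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.int64)
        return GenotypeMatrix(self.dosage[:, idx], list(self.individual_ids), self.map.subset(idx))

    def subset_individuals(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=np.int64)
        ids = [self.individual_ids[i] for i in rows]
        return GenotypeMatrix(self.dosage[rows, :], ids, self.map)


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parents are stored as positional indices into ``ids`` (UNKNOWN_PARENT for
    unknown); storage order must place every parent before its offspring,
    which also rules out ancestry cycles.
    """

    ids: list[str]
    sire: np.ndarray  # positional index or UNKNOWN_PARENT
    dam: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        if not (len(self.sire) == len(self.dam) == len(self.generation) == n):
            raise DataValidationError("pedigree arrays must have equal length")
        if len(set(self.ids)) != n:
            raise DataValidationError("duplicate individual ids in pedigree")
        for name, arr in (("sire", self.sire), ("dam", self.dam)):
            if ((arr != UNKNOWN_PARENT) & (arr >= np.arange(n))).any():
                raise DataValidationError(f"{name} appears at or after its offspring")
            if (arr < UNKNOWN_PARENT).any():
                raise DataValidationError(f"invalid {name} index")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN_PARENT) & (self.dam == UNKNOWN_PARENT)

    @property
    def n_founders(self) -> int:
        return int(self.is_founder.sum())


def concat_pedigrees(pedigrees: Sequence[Pedigree], prefixes: Optional[Sequence[str]] = None) -> Pedigree:
    """Stack disjoint pedigrees (e.g. independent families) into one.

    Ids are prefixed to keep them unique; parent indices are offset.  The
    result is ordered family-by-family, which preserves topological order.
    """
    if prefixes is None:
        prefixes = [f"F{k}_" for k in range(len(pedigrees))]
    ids: list[str] = []
    sire: list[np.ndarray] = []
    dam: list[np.ndarray] = []
    gen: list[np.ndarray] = []
    offset = 0
    for ped, pre in zip(pedigrees, prefixes):
        ids.extend(pre + i for i in ped.ids)
        s = ped.sire.copy()
        d = ped.dam.copy()
        s[s != UNKNOWN_PARENT] += offset
        d[d != UNKNOWN_PARENT] += offset
        sire.append(s)
        dam.append(d)
        gen.append(ped.generation)
        offset += len(ped)
    return Pedigree(ids, np.concatenate(sire), np.concatenate(dam), np.concatenate(gen))


@dataclass(frozen=True)
class QTLSet:
    """Marker indices designated as QTL, chosen as every m-th ordered SNP."""

    indices: np.ndarray  # 0-based panel indices, increasing
    spacing_m: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if len(idx) and not (np.diff(idx) > 0).all():
            raise DataValidationError("QTL indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def marker_ids(self, marker_map: MarkerMap) -> np.ndarray:
        return marker_map.marker_ids[self.indices]

    def in_panel(self, source_map: MarkerMap, target_map: MarkerMap) -> "QTLSet":
        """Re-express the QTL indices relative to another panel sharing marker ids."""
        ids = source_map.marker_ids[self.indices]
        return QTLSet(target_map.indices_of(ids), self.spacing_m)


@dataclass(frozen=True)
class PhenotypeVector:
    """h² = 1 phenotype: a QTL dosage column (single) or the QTL dosage sum (summed)."""

    y: np.ndarray
    mode: str  # "single" | "summed"
    qtl: QTLSet
    target_qtl: Optional[int] = None  # panel index, single mode only

    def __post_init__(self) -> None:
        if self.mode not in ("single", "summed"):
            raise DataValidationError(f"unknown phenotype mode {self.mode!r}")
        object.__setattr__(self, "y", np.asarray(self.y, dtype=np.float64))


@dataclass
class CVPartition:
    """Cross-validation grouping: label in 1..K per individual, no empty group."""

    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        if not (set(present) <= set(range(1, self.K + 1))):
            raise DataValidationError("labels must lie in 1..K")
        if len(present) != self.K:
            raise DataValidationError("every group must be non-empty")

    def fold_indices(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(training rows, validation rows) for fold k (validation = group k)."""
        mask = self.labels == k
        return np.flatnonzero(~mask), np.flatnonzero(mask)
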