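"""Readers/writers for the plain-text formats the pipeline touches.

Genotypes travel either as a PLINK-style ``.ped``/``.map`` text pair or as a
tab-separated dosage table (individuals x markers, header row of marker
ids, first column the individual id).  The counted allele is the alternate
"B" allele: ``.ped`` genotypes A A / A B / B B map to dosages 0 / 1 / 2.
Pedigrees are 3-column CSV (id, sire, dam; 0 = unknown), phenotypes
2-column CSV (id, y).  All writers round-trip losslessly through their
paired readers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datatypes import (
    UNKNOWN_PARENT,
    CVPartition,
    DataValidationError,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    QTLSet,
)

PathLike = Union[str, Path]


# --- dosage table -----------------------------------------------------------

def write_dosage_table(genotypes: GenotypeMatrix, path: PathLike) -> None:
    df = pd.DataFrame(
        genotypes.dosage,
        index=pd.Index(genotypes.individual_ids, name="individual_id"),
        columns=genotypes.map.marker_ids,
    )
    df.to_csv(path, sep="\t")


def read_dosage_table(path: PathLike, marker_map: MarkerMap) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(marker_map.marker_ids):
        raise DataValidationError("dosage table columns do not match the marker map")
    values = df.to_numpy()
    bad = (values < 0) | (values > 2) | (values != np.floor(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataValidationError(
            f"invalid dosage {values[i, j]!r} at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return GenotypeMatrix(values.astype(np.int8), [str(i) for i in df.index], marker_map)


# --- PLINK .ped / .map ------------------------------------------------------

def write_plink(genotypes: GenotypeMatrix, prefix: PathLike) -> None:
    """Write ``{prefix}.ped`` and ``{prefix}.map`` (A = reference, B = counted allele)."""
    prefix = Path(prefix)
    m = genotypes.map
    cm = m.positions_bp / 1e6  # 1 cM per Mb
    with open(prefix.with_suffix(".map"), "w") as fh:
        for mid, chrom, c_m, bp in zip(m.marker_ids, m.chromosomes, cm, m.positions_bp):
            fh.write(f"{chrom}\t{mid}\t{c_m:.6f}\t{bp}\n")
    alleles = {0: "A A", 1: "A B", 2: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for ind, row in zip(genotypes.individual_ids, genotypes.dosage):
            geno = "\t".join(alleles[int(d)] for d in row)
            fh.write(f"FAM\t{ind}\t0\t0\t0\t-9\t{geno}\n")


def read_plink(prefix: PathLike) -> GenotypeMatrix:
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            chrom, mid, _cm, bp = line.split()
            map_rows.append((mid, int(chrom), int(bp)))
    marker_map = MarkerMap(pd.DataFrame(map_rows, columns=["marker_id", "chromosome", "position_bp"]))

    ids: list[str] = []
    rows: list[list[int]] = []
    code = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2}
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if len(fields) != 6 + 2 * len(marker_map):
                raise DataValidationError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * len(marker_map)} fields, got {len(fields)}"
                )
            ids.append(fields[1])
            geno = fields[6:]
            try:
                rows.append([code[(geno[2 * j], geno[2 * j + 1])] for j in range(len(marker_map))])
            except KeyError as err:
                raise DataValidationError(
                    f"{prefix}.ped line {lineno}: non-biallelic allele code {err.args[0]}"
                ) from None
    return GenotypeMatrix(np.array(rows, dtype=np.int8), ids, marker_map)


# --- pedigree ---------------------------------------------------------------

def write_pedigree(pedigree: Pedigree, path: PathLike) -> None:
    """3-column CSV (id, sire, dam); 0 encodes an unknown parent."""
    def name(idx: int) -> str:
        return "0" if idx == UNKNOWN_PARENT else pedigree.ids[idx]

    df = pd.DataFrame(
        {
            "id": pedigree.ids,
            "sire": [name(s) for s in pedigree.sire],
            "dam": [name(d) for d in pedigree.dam],
        }
    )
    df.to_csv(path, index=False)


def read_pedigree(path: PathLike) -> Pedigree:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["id", "sire", "dam"]:
        raise DataValidationError("pedigree CSV must have columns id,sire,dam")
    ids = list(df["id"])
    pos = {ind: i for i, ind in enumerate(ids)}

    def resolve(col: str, i: int, parent: str) -> int:
        if parent == "0":
            return UNKNOWN_PARENT
        if parent not in pos:
            raise DataValidationError(f"row {i}: unknown {col} {parent!r}")
        if pos[parent] >= i:
            raise DataValidationError(f"row {i}: {col} {parent!r} appears at or after its offspring")
        return pos[parent]

    sire = np.array([resolve("sire", i, s) for i, s in enumerate(df["sire"])])
    dam = np.array([resolve("dam", i, d) for i, d in enumerate(df["dam"])])
    gen = np.zeros(len(ids), dtype=np.int64)
    for i in range(len(ids)):
        parents = [p for p in (sire[i], dam[i]) if p != UNKNOWN_PARENT]
        gen[i] = 1 + max((gen[p] for p in parents), default=-1)
    return Pedigree(ids, sire, dam, gen)


# --- phenotypes, QTL, relationships, partitions -----------------------------

def write_phenotypes(individual_ids: list[str], y: np.ndarray, path: PathLike) -> None:
    pd.DataFrame({"id": individual_ids, "y": y}).to_csv(path, index=False)


def read_phenotypes(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ["id", "y"]:
        raise DataValidationError("phenotype CSV must have columns id,y")
    return df


def write_qtl(qtl: QTLSet, marker_map: MarkerMap, path: PathLike) -> None:
    pd.DataFrame(
        {"panel_index": qtl.indices, "marker_id": qtl.marker_ids(marker_map), "spacing_m": qtl.spacing_m}
    ).to_csv(path, index=False)


def read_qtl(path: PathLike) -> QTLSet:
    df = pd.read_csv(path)
    return QTLSet(df["panel_index"].to_numpy(), int(df["spacing_m"].iloc[0]))


def write_relationship_matrix(A: np.ndarray, ids: list[str], path: PathLike) -> None:
    pd.DataFrame(A, index=pd.Index(ids, name="id"), columns=ids).to_csv(path, sep="\t")


def read_relationship_matrix(path: PathLike) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), [str(i) for i in df.index]


def write_partition(partition: CVPartition, ids: list[str], path: PathLike) -> None:
    pd.DataFrame({"id": ids, "group": partition.labels}).to_csv(path, index=False)


def read_partition(path: PathLike) -> tuple[CVPartition, list[str]]:
    df = pd.read_csv(path)
    labels = df["group"].to_numpy()
    return CVPartition(labels, int(labels.max())), [str(i) for i in df["id"]]
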