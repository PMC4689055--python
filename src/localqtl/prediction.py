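"""Local vs whole-genome training and direct genomic value (DGV) prediction.

Two strategies are compared for predicting a QTL's genotype from SNPs:

1. *local training and prediction* — estimate effects of only the ±k SNPs
   flanking the QTL and predict from those effects;
2. *whole-genome training and local prediction* — estimate effects of all
   non-QTL SNPs genome-wide, then predict from the estimated effects of the
   ±k flanking SNPs only.

Accuracy is the Pearson correlation between the phenotype and the DGV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .bayes import ChainConfig, PosteriorSummary, PriorSpec, run_chain
from .datatypes import GenotypeMatrix, MarkerMap, QTLSet

__all__ = [
    "TrainingScheme",
    "flank_indices",
    "whole_genome_indices",
    "train",
    "dgv",
    "accuracy",
]

FLANK_SIZES = (1, 2, 5, 10, 50, 100)


@dataclass(frozen=True)
class TrainingScheme:
    """Which markers are trained: a ±k local window or all non-QTL markers."""

    strategy: str  # "local" | "whole_genome"
    flank_k: Union[int, str] = "all"  # window half-width, or "all" for whole-genome prediction

    def __post_init__(self) -> None:
        if self.strategy not in ("local", "whole_genome"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def flank_indices(marker_map: MarkerMap, qtl_index: int, k: int) -> np.ndarray:
    """Panel indices of up to k markers on each side of the QTL, same chromosome.

    Windows are truncated at chromosome ends and never contain the QTL
    itself.  A QTL alone on its chromosome has no flanking markers and is an
    error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0 <= qtl_index < len(marker_map)):
        raise ValueError("qtl_index outside the panel")
    chrom = marker_map.chromosomes[qtl_index]
    on_chrom = marker_map.chromosome_indices(chrom)
    pos = int(np.flatnonzero(on_chrom == qtl_index)[0])
    left = on_chrom[max(0, pos - k) : pos]
    right = on_chrom[pos + 1 : pos + 1 + k]
    out = np.concatenate([left, right])
    if len(out) == 0:
        raise ValueError(f"QTL at panel index {qtl_index} has no flanking markers")
    return out


def whole_genome_indices(marker_map: MarkerMap, qtl: QTLSet) -> np.ndarray:
    """All panel indices except the designated QTL."""
    mask = np.ones(len(marker_map), dtype=bool)
    mask[qtl.indices] = False
    return np.flatnonzero(mask)


def train(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    predictor_indices: Sequence[int],
    prior: PriorSpec,
    config: ChainConfig,
    qtl: Optional[QTLSet] = None,
) -> PosteriorSummary:
    """Fit a Bayesian-alphabet chain on the chosen predictor columns.

    QTL columns must never be in the predictor set; pass ``qtl`` to have
    this asserted.
    """
    idx = np.asarray(predictor_indices, dtype=np.int64)
    if len(idx) == 0:
        raise ValueError("empty predictor set")
    if qtl is not None and np.intersect1d(idx, qtl.indices).size:
        raise ValueError("predictor set contains designated QTL columns")
    summary = run_chain(
        genotypes.dosage[:, idx],
        y,
        prior,
        config,
        marker_ids=genotypes.map.marker_ids[idx],
    )
    return summary


def dgv(
    genotypes: GenotypeMatrix,
    posterior: PosteriorSummary,
    subset_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Direct genomic values from posterior-mean effects and genotypes only.

    ``subset_ids`` restricts the sum to a subset of the trained markers
    (the flanking window for local prediction after whole-genome training);
    default is all trained markers.  Dosages are centered with the training
    column means, so DGV is comparable across training/validation sets.
    """
    if posterior.marker_ids is None:
        raise ValueError("posterior carries no marker ids")
    trained = list(posterior.marker_ids)
    if subset_ids is None:
        subset_ids = trained
    lookup = {m: i for i, m in enumerate(trained)}
    try:
        cols_in_post = np.array([lookup[m] for m in subset_ids], dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"marker {err.args[0]!r} was not in the trained predictor set") from None
    panel_cols = genotypes.map.indices_of(list(subset_ids))
    Zc = genotypes.dosage[:, panel_cols] - posterior.column_means[cols_in_post]
    return Zc @ posterior.effect_mean[cols_in_post]


def accuracy(y: np.ndarray, dgv_vector: np.ndarray) -> float:
    """Pearson correlation between phenotype and DGV.

    Returns NaN with a warning when either vector has zero variance (e.g.
    all flank effects shrunk to zero).
    """
    y = np.asarray(y, dtype=np.float64)
    g = np.asarray(dgv_vector, dtype=np.float64)
    if len(y) != len(g):
        raise ValueError("length mismatch")
    if y.std() == 0.0 or g.std() == 0.0:
        warnings.warn("zero-variance input; accuracy undefined")
        return float("nan")
    return float(np.corrcoef(y, g)[0, 1])
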