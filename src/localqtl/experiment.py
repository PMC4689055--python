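"""Experiment orchestration: accuracy grids over method x pi x panel x flank size.

Four experiments mirror the study design: single-QTL prediction (local
training vs whole-genome training with local prediction), the summed-QTL
polygenic trait, leave-one-group-out cross-validation on relatedness
clusters, and the relationship between QTL minor allele frequency and
accuracy.  Results are tidy DataFrames with one row per
(method, panel, strategy, flank size, QTL-or-summed, fold, split).

Every chain's seed is derived deterministically from the master seed and the
grid-cell coordinates (blake2s hash), so a full experiment re-run with the
same master seed reproduces every record.
"""

from __future__ import annotations

import hashlib
import warnings
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .bayes import ChainConfig, PriorSpec
from .datatypes import CVPartition, GenotypeMatrix, QTLSet
from .prediction import accuracy, dgv, flank_indices, train, whole_genome_indices
from .simulate import StudyData, simulate_phenotype

__all__ = [
    "child_seed",
    "default_priors",
    "run_single_qtl",
    "run_summed_qtl",
    "run_cross_validation",
    "run_maf_analysis",
]

RECORD_COLUMNS = [
    "method", "pi", "panel", "strategy", "flank_k",
    "qtl_id", "fold", "split", "accuracy", "n_predictors",
]

FlankK = Union[int, str]


def child_seed(master_seed: int, *coords) -> int:
    """Deterministic 31-bit child seed from the master seed and grid-cell coordinates."""
    key = "|".join(str(c) for c in (master_seed, *coords))
    digest = hashlib.blake2s(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


def default_priors(panel: str, preset: str = "desk") -> list[PriorSpec]:
    """Method x pi grid for one panel density.

    The sparse-panel pi grid is {0, 0.95, 0.996} and the dense-panel grid
    {0, 0.9997}; the desk preset keeps a representative subset
    (BayesC0, BayesC with the panel's large pi, BayesCpi).
    """
    if panel == "sparse":
        pis = (0.95, 0.996)
    elif panel == "dense":
        pis = (0.9997,)
    else:
        raise ValueError(f"unknown panel {panel!r}")
    if preset == "desk":
        return [
            PriorSpec("C", pi=0.0),
            PriorSpec("C", pi=pis[-1]),
            PriorSpec("Cpi", pi=pis[0]),
        ]
    if preset == "full":
        out: list[PriorSpec] = [PriorSpec("A"), PriorSpec("C", pi=0.0)]
        for pi in pis:
            out.append(PriorSpec("B", pi=pi))
            out.append(PriorSpec("C", pi=pi))
        for pi in (0.95, 0.996):
            out.append(PriorSpec("Cpi", pi=pi))
        return out
    raise ValueError(f"unknown preset {preset!r}")


def _local_predictors(geno: GenotypeMatrix, qtl: QTLSet, qtl_index: int, k: int) -> np.ndarray:
    """Flanking window minus any designated QTL columns."""
    fl = flank_indices(geno.map, qtl_index, k)
    return np.setdiff1d(fl, qtl.indices)

def _union_window(geno: GenotypeMatrix, qtl: QTLSet, k: int) -> np.ndarray:
    """Union of the per-QTL flank windows (each marker once), minus QTL columns."""
    parts = [flank_indices(geno.map, int(q), k) for q in qtl.indices]
    return np.setdiff1d(np.unique(np.concatenate(parts)), qtl.indices)


def _record(method, pi, panel, strategy, flank_k, qtl_id, fold, split, acc, n_pred):
    return dict(
        method=method, pi=pi, panel=panel, strategy=strategy, flank_k=flank_k,
        qtl_id=qtl_id, fold=fold, split=split, accuracy=acc, n_predictors=n_pred,
    )


def run_single_qtl(
    data: StudyData,
    priors: Sequence[PriorSpec],
    panels: Sequence[str],
    ks: Sequence[int],
    chain: ChainConfig,
    master_seed: int,
    strategies: Sequence[str] = ("local", "whole_genome"),
    wg_chain: ChainConfig | None = None,
) -> pd.DataFrame:
    """Single-QTL experiment: one h²=1 phenotype per QTL, both strategies.

    Local training fits only the ±k flanking SNPs; whole-genome training fits
    all non-QTL SNPs once per (prior, panel, QTL) and is re-used for every
    window size.  Per-QTL rows plus QTL-averaged rows (``qtl_id = "mean"``)
    are returned.  ``wg_chain`` optionally shortens the whole-genome chains.
    """
    wg_chain = wg_chain or chain
    rows: list[dict] = []
    for panel in panels:
        geno, qtl = data.panel(panel)
        for prior in priors:
            for q in qtl.indices:
                q = int(q)
                qtl_id = geno.map.marker_ids[q]
                y = simulate_phenotype(geno, qtl, "single", q).y
                if "local" in strategies:
                    for k in ks:
                        pred = _local_predictors(geno, qtl, q, k)
                        seed = child_seed(master_seed, panel, prior.label, qtl_id, "local", k)
                        post = train(y, geno, pred, prior, _reseed(chain, seed), qtl=qtl)
                        acc = accuracy(y, dgv(geno, post))
                        rows.append(_record(prior.label, prior.pi, panel, "local", k,
                                            qtl_id, "-", "training", acc, len(pred)))
                if "whole_genome" in strategies:
                    pred = whole_genome_indices(geno.map, qtl)
                    seed = child_seed(master_seed, panel, prior.label, qtl_id, "wg")
                    post = train(y, geno, pred, prior, _reseed(wg_chain, seed), qtl=qtl)
                    for k in ks:
                        window = _local_predictors(geno, qtl, q, k)
                        window_ids = geno.map.marker_ids[window]
                        acc = accuracy(y, dgv(geno, post, window_ids))
                        rows.append(_record(prior.label, prior.pi, panel, "whole_genome", k,
                                            qtl_id, "-", "training", acc, len(window)))
    table = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return pd.concat([table, qtl_averaged(table)], ignore_index=True)


def qtl_averaged(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of per-QTL accuracies, one row per grid cell (qtl_id = 'mean')."""
    per_qtl = table[table["qtl_id"] != "mean"]
    grouped = (
        per_qtl.groupby(["method", "pi", "panel", "strategy", "flank_k", "fold", "split"],
                        as_index=False, sort=False)
        .agg(accuracy=("accuracy", "mean"), n_predictors=("n_predictors", "mean"))
    )
    grouped["qtl_id"] = "mean"
    return grouped[RECORD_COLUMNS]


def run_summed_qtl(
    data: StudyData,
    priors: Sequence[PriorSpec],
    panels: Sequence[str],
    ks: Sequence[FlankK],
    chain: ChainConfig,
    master_seed: int,
) -> pd.DataFrame:
    """Summed-QTL polygenic trait: whole-genome training, local + all-marker prediction.

    One phenotype (the dosage sum over all QTL) per panel; training runs once
    per (prior, panel).  For an integer k the prediction window is the union
    of the per-QTL flank windows (each marker counted once); ``"all"``
    predicts from every trained marker.
    """
    rows: list[dict] = []
    for panel in panels:
        geno, qtl = data.panel(panel)
        y = simulate_phenotype(geno, qtl, "summed").y
        for prior in priors:
            pred = whole_genome_indices(geno.map, qtl)
            seed = child_seed(master_seed, panel, prior.label, "summed", "wg")
            post = train(y, geno, pred, prior, _reseed(chain, seed), qtl=qtl)
            for k in ks:
                if k == "all":
                    window_ids = None
                    n_pred = len(pred)
                else:
                    window = _union_window(geno, qtl, int(k))
                    window_ids = geno.map.marker_ids[window]
                    n_pred = len(window)
                acc = accuracy(y, dgv(geno, post, window_ids))
                rows.append(_record(prior.label, prior.pi, panel, "whole_genome", k,
                                    "summed", "-", "training", acc, n_pred))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def run_cross_validation(
    data: StudyData,
    priors: Sequence[PriorSpec],
    panel: str,
    ks: Sequence[FlankK],
    chain: ChainConfig,
    partition: CVPartition,
    master_seed: int,
) -> pd.DataFrame:
    """Leave-one-group-out CV of the summed-QTL trait.

    Each of the K relatedness groups is predicted once from a whole-genome
    fit on the other K−1 groups; per-fold validation and training accuracies
    are recorded for every window size, plus fold-averaged rows
    (``fold = "mean"``).  Folds whose held-out phenotype is constant are
    skipped with a warning.
    """
    geno, qtl = data.panel(panel)
    y = simulate_phenotype(geno, qtl, "summed").y
    pred = whole_genome_indices(geno.map, qtl)
    rows: list[dict] = []
    for fold in range(1, partition.K + 1):
        tr, va = partition.fold_indices(fold)
        y_tr, y_va = y[tr], y[va]
        if np.std(y_va) == 0.0:
            warnings.warn(f"fold {fold}: held-out phenotype constant; fold skipped")
            continue
        geno_tr = geno.subset_individuals(tr)
        geno_va = geno.subset_individuals(va)
        for prior in priors:
            seed = child_seed(master_seed, panel, prior.label, "cv", fold)
            post = train(y_tr, geno_tr, pred, prior, _reseed(chain, seed), qtl=qtl)
            for k in ks:
                if k == "all":
                    window_ids = None
                    n_pred = len(pred)
                else:
                    window = _union_window(geno, qtl, int(k))
                    window_ids = geno.map.marker_ids[window]
                    n_pred = len(window)
                rows.append(_record(prior.label, prior.pi, panel, "whole_genome", k, "summed",
                                    fold, "validation", accuracy(y_va, dgv(geno_va, post, window_ids)), n_pred))
                rows.append(_record(prior.label, prior.pi, panel, "whole_genome", k, "summed",
                                    fold, "training", accuracy(y_tr, dgv(geno_tr, post, window_ids)), n_pred))
    table = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    means = (
        table.groupby(["method", "pi", "panel", "strategy", "flank_k", "qtl_id", "split"],
                      as_index=False, sort=False)
        .agg(accuracy=("accuracy", "mean"), n_predictors=("n_predictors", "mean"))
    )
    means["fold"] = "mean"
    return pd.concat([table, means[RECORD_COLUMNS]], ignore_index=True)


def run_maf_analysis(
    single_qtl_table: pd.DataFrame,
    genotypes: GenotypeMatrix,
    qtl: QTLSet,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Join per-QTL MAF to single-QTL accuracies and correlate them.

    Returns (per-QTL long table, correlation table with one row per
    (method, strategy, flank_k), and a MAF summary dict with min/max/mean).
    Correlations need >= 3 QTL with MAF variance; otherwise the correlation
    table is empty.
    """
    qtl_ids = qtl.marker_ids(genotypes.map)
    mafs = genotypes.maf()[qtl.indices]
    maf_frame = pd.DataFrame({"qtl_id": qtl_ids, "maf": mafs})
    per_qtl = single_qtl_table[
        (single_qtl_table["qtl_id"] != "mean") & (single_qtl_table["split"] == "training")
    ].merge(maf_frame, on="qtl_id", how="inner")

    corr_rows = []
    if len(qtl_ids) >= 3 and np.std(mafs) > 0:
        for (method, strategy, k), grp in per_qtl.groupby(["method", "strategy", "flank_k"], sort=False):
            if len(grp) >= 3 and grp["maf"].std() > 0 and grp["accuracy"].std() > 0:
                r = float(np.corrcoef(grp["maf"], grp["accuracy"])[0, 1])
                corr_rows.append({"method": method, "strategy": strategy, "flank_k": k,
                                  "corr_maf_accuracy": r, "n_qtl": len(grp)})
    summary = {
        "maf_min": float(mafs.min()),
        "maf_max": float(mafs.max()),
        "maf_mean": float(mafs.mean()),
        "n_qtl": int(len(qtl_ids)),
    }
    return per_qtl, pd.DataFrame(corr_rows), summary


def _reseed(chain: ChainConfig, seed: int) -> ChainConfig:
    from dataclasses import replace

    return replace(chain, seed=seed)
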