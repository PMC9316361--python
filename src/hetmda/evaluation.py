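"""Ranking-based validation protocols: global/local LOOCV and repeated k-fold CV.

Each verified association is held out (alone, or as part of a fold), the
model is retrained on the remaining associations, and the held-out pair's
score is ranked against the *candidate* set — all pairs never verified in
the full data.  Global LOOCV pools candidates across every disease; local
LOOCV ranks a held-out pair only against the unverified miRNAs of its own
disease.  AUC follows the Mann-Whitney convention (ties count one half),
so it equals the probability that a random held-out positive outranks a
random candidate.

A *trainer* is any callable ``trainer(assoc_matrix) -> score_matrix`` taking
the (masked) binary m x n association matrix and returning an m x n score
matrix.  The real model supplies one via :func:`make_model_trainer`; tests
may pass deterministic mocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph import AssociationData, SimilarityMatrix
from .model import ModelConfig, train
from .rwr import RestartConfig

__all__ = [
    "CVProtocol",
    "RankingResult",
    "Trainer",
    "make_model_trainer",
    "compute_metrics",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "rank_candidates",
]

logger = logging.getLogger(__name__)

Trainer = Callable[[np.ndarray], np.ndarray]


@dataclass
class CVProtocol:
    """Cross-validation protocol parameters.

    ``retrain=True`` retrains for every held-out association (faithful but
    O(#positives) trainings for LOOCV); ``retrain=False`` trains once on the
    full data and treats the frozen scorer as the ranking source.
    """

    mode: str = "kfold"
    k: int = 5
    repeats: int = 1
    seed: int = 0
    retrain: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("global_loocv", "local_loocv", "kfold"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class RankingResult:
    """Per-sample ranks plus pooled threshold-free metrics.

    ``ranks[t]`` is the 1-based rank of held-out positive ``t`` within its
    candidate set (1 = best); ``candidate_sizes[t]`` the size of that set.
    ``auc`` is the mean Mann-Whitney contribution over held-out samples,
    ``aupr``/``acc`` are computed from the pooled positive and candidate
    score lists.  For k-fold CV, ``fold_metrics`` holds one metrics dict per
    (repeat, fold) and the headline numbers are their means; ``auc_sd`` the
    standard deviation across folds.
    """

    ranks: list[int] = field(default_factory=list)
    candidate_sizes: list[int] = field(default_factory=list)
    auc: float = float("nan")
    aupr: float = float("nan")
    acc: float = float("nan")
    auc_sd: float = float("nan")
    fold_metrics: list[dict] = field(default_factory=list)
    pos_scores: list[float] = field(default_factory=list)
    neg_scores: list[float] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "acc": self.acc,
            "auc_sd": self.auc_sd,
            "n_test": len(self.ranks),
        }


def make_model_trainer(
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    mirna_names: Sequence[str],
    disease_names: Sequence[str],
    cfg: ModelConfig,
    rwr_cfg: RestartConfig | None = None,
) -> Trainer:
    """Wrap the model's ``train`` into the trainer contract used by the protocols."""

    def trainer(matrix: np.ndarray) -> np.ndarray:
        assoc = AssociationData(matrix, list(mirna_names), list(disease_names))
        return train(sm, sd, assoc, cfg, rwr_cfg).scores

    return trainer


def compute_metrics(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    threshold: float = 0.5,
    acc_rng: np.random.Generator | None = None,
) -> dict:
    """AUC, AUPR and thresholded accuracy from pooled score lists.

    AUC is the Mann-Whitney statistic (ties contribute one half), identical
    to the area under the trapezoidal ROC curve.  AUPR is the
    average-precision form of the precision-recall area.  ACC thresholds the
    test positives against an equal-size negative sample (seeded via
    ``acc_rng``; all negatives if ``acc_rng`` is None and sizes permit).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = np.concatenate([pos, neg])
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    if acc_rng is not None and neg.size > pos.size:
        neg_acc = neg[acc_rng.choice(neg.size, size=pos.size, replace=False)]
    else:
        neg_acc = neg
    acc = float(
        ((pos >= threshold).sum() + (neg_acc < threshold).sum()) / (pos.size + neg_acc.size)
    )
    return {"auc": auc, "aupr": aupr, "acc": acc}


def _rank_and_contribution(score: float, candidates: np.ndarray) -> tuple[int, float]:
    """1-based rank of ``score`` among ``candidates`` and its AUC contribution."""
    wins = int((candidates < score).sum())
    ties = int((candidates == score).sum())
    rank = candidates.size - wins - ties + 1  # beaten by the strictly greater ones
    contribution = (wins + 0.5 * ties) / candidates.size if candidates.size else 1.0
    return rank, contribution


def _candidate_mask(matrix: np.ndarray) -> np.ndarray:
    return matrix == 0


def global_loocv(
    dataset: AssociationData, trainer: Trainer, protocol: CVProtocol | None = None
) -> RankingResult:
    """Leave-one-out over positives, ranked against all unverified pairs pooled."""
    return _loocv(dataset, trainer, protocol or CVProtocol(mode="global_loocv"), local=False)


def local_loocv(
    dataset: AssociationData, trainer: Trainer, protocol: CVProtocol | None = None
) -> RankingResult:
    """Leave-one-out over positives, ranked within the held-out pair's disease."""
    return _loocv(dataset, trainer, protocol or CVProtocol(mode="local_loocv"), local=True)


def _loocv(
    dataset: AssociationData, trainer: Trainer, protocol: CVProtocol, local: bool
) -> RankingResult:
    positives = dataset.positives
    if not positives:
        raise ValueError("dataset has no verified associations to hold out")
    cand_mask = _candidate_mask(dataset.matrix)
    if local:
        empty = [j for j in range(dataset.shape[1]) if dataset.matrix[:, j].sum() == 0]
        if empty:
            logger.warning("diseases without positives skipped in local LOOCV: %s", empty)
    frozen = None if protocol.retrain else trainer(dataset.matrix.copy())
    result = RankingResult()
    contributions = []
    for (i, j) in positives:
        scores = trainer(dataset.masked([(i, j)]).matrix) if protocol.retrain else frozen
        cands = scores[:, j][cand_mask[:, j]] if local else scores[cand_mask]
        rank, contrib = _rank_and_contribution(float(scores[i, j]), np.asarray(cands).ravel())
        result.ranks.append(rank)
        result.candidate_sizes.append(int(np.asarray(cands).size))
        contributions.append(contrib)
        result.pos_scores.append(float(scores[i, j]))
    # pool candidate scores (frozen model, or the last retrained one) for AUPR/ACC
    source = frozen if frozen is not None else scores
    result.neg_scores = list(np.asarray(source[cand_mask]).ravel())
    result.auc = float(np.mean(contributions))
    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, 99]))
    extra = compute_metrics(result.pos_scores, result.neg_scores, acc_rng=rng)
    result.aupr = extra["aupr"]
    result.acc = extra["acc"]
    return result


def _partition(n_pos: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random near-equal partition of ``range(n_pos)`` into k disjoint groups."""
    perm = rng.permutation(n_pos)
    return [np.sort(perm[f::k]) for f in range(k)]


def kfold_cv(
    dataset: AssociationData, trainer: Trainer, protocol: CVProtocol | None = None
) -> RankingResult:
    """Repeated k-fold CV over positives; metrics averaged over folds and repeats."""
    protocol = protocol or CVProtocol(mode="kfold")
    positives = dataset.positives
    if not positives:
        raise ValueError("dataset has no verified associations")
    if protocol.k > len(positives):
        raise ValueError(f"k={protocol.k} exceeds the {len(positives)} positives")
    cand_mask = _candidate_mask(dataset.matrix)
    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, 7]))
    acc_rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, 99]))
    result = RankingResult()
    fold_aucs = []
    for rep in range(protocol.repeats):
        for fold_idx in _partition(len(positives), protocol.k, rng):
            held = [positives[t] for t in fold_idx]
            scores = trainer(dataset.masked(held).matrix)
            contribs = []
            pos_fold = []
            for (i, j) in held:
                cands = scores[cand_mask]
                rank, contrib = _rank_and_contribution(float(scores[i, j]), cands)
                result.ranks.append(rank)
                result.candidate_sizes.append(int(cands.size))
                contribs.append(contrib)
                pos_fold.append(float(scores[i, j]))
            neg_fold = list(scores[cand_mask])
            fm = compute_metrics(pos_fold, neg_fold, acc_rng=acc_rng)
            fm["auc_rank"] = float(np.mean(contribs))
            fm["repeat"] = rep
            result.fold_metrics.append(fm)
            fold_aucs.append(fm["auc_rank"])
            result.pos_scores.extend(pos_fold)
    result.auc = float(np.mean(fold_aucs))
    result.auc_sd = float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
    result.aupr = float(np.mean([fm["aupr"] for fm in result.fold_metrics]))
    result.acc = float(np.mean([fm["acc"] for fm in result.fold_metrics]))
    return result


def rank_candidates(
    scores: np.ndarray,
    disease: str,
    assoc: AssociationData,
    top_k: int = 50,
) -> list[tuple[str, float]]:
    """Top-k candidate miRNAs for one disease, known associations excluded.

    Ties are broken by stable input order; ``top_k`` larger than the
    candidate count returns the full list.
    """
    if disease not in assoc.disease_names:
        raise KeyError(f"unknown disease {disease!r}")
    j = assoc.disease_names.index(disease)
    cand = [i for i in range(assoc.shape[0]) if assoc.matrix[i, j] == 0]
    order = sorted(cand, key=lambda i: -scores[i, j])
    return [(assoc.mirna_names[i], float(scores[i, j])) for i in order[:top_k]]
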