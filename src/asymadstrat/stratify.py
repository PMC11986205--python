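"""Proximity-based sub-typing of AsymAD subjects.

The selected peptide panel is reduced to two dimensions with t-SNE; each
AsymAD subject is labelled Control-like or AD-like by majority vote of its
k nearest Control/AD neighbours in the embedding. Because t-SNE is
initialization-sensitive, the embedding + labelling is repeated and the
per-subject fraction of AD-like calls is reported as an assignment
probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.model_selection import train_test_split

from .cohort import (
    GROUP_AD,
    GROUP_ASYMAD,
    GROUP_CONTROL,
    SUBTYPE_AD_LIKE,
    SUBTYPE_CONTROL_LIKE,
    CohortError,
    CohortTable,
)
from .metrics import MetricsReport, confusion_counts, kfold_cv, \
    rates_from_confusion, roc_auc
from .panel import Scaler, _rows

log = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    n_components: int = 2
    perplexity: float = 30.0
    n_repeats: int = 100
    k_neighbors: int = 5
    tsne_max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors % 2 == 0:
            raise CohortError("k_neighbors must be odd for a strict majority")
        if self.n_repeats < 1:
            raise CohortError("n_repeats must be >= 1")
        if self.perplexity <= 0:
            raise CohortError("perplexity must be positive")


@dataclass
class StratificationResult:
    subject_ids: list[str]              # AsymAD subjects
    consensus: list[str]                # ControlLike / ADLike per subject
    p_adlike: np.ndarray                # fraction of repeats labelled ADLike
    repeat_labels: np.ndarray           # (n_asymad, n_repeats) of 0/1 AD-like
    embedding: np.ndarray               # canonical (repeat 0) coords, all subjects
    embedding_ids: list[str]
    embedding_groups: list[str]
    ties: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids,
                             "consensus_label": self.consensus,
                             "p_adlike": self.p_adlike})


def embed_2d(X: np.ndarray, config: EmbeddingConfig, repeat_seed: int
             ) -> np.ndarray:
    """One t-SNE embedding to 2-D; deterministic given `repeat_seed`."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < 4:
        raise CohortError("need at least 4 subjects to embed")
    perplexity = config.perplexity
    if n < 3 * perplexity:
        perplexity = max(2.0, (n - 1) / 3.0)
        log.warning("perplexity shrunk to %.1f for n=%d", perplexity, n)
    tsne = TSNE(n_components=config.n_components, perplexity=perplexity,
                max_iter=config.tsne_max_iter, init="random",
                random_state=repeat_seed)
    return tsne.fit_transform(X)


def knn_label(coords: np.ndarray, is_ad_reference: np.ndarray,
              reference_idx: Sequence[int], query_idx: Sequence[int],
              k: int = 5) -> np.ndarray:
    """Majority k-NN vote in embedding space.

    Only reference points are eligible neighbours. Returns 1 (AD-like) where
    at least ceil(k/2) of the k nearest references are AD. Distance ties are
    broken by lower reference index.
    """
    reference_idx = np.asarray(reference_idx, dtype=int)
    query_idx = np.asarray(query_idx, dtype=int)
    if len(reference_idx) < k:
        raise CohortError(f"need >= {k} reference points, have "
                          f"{len(reference_idx)}")
    is_ad = np.asarray(is_ad_reference, dtype=bool)
    ref = coords[reference_idx]
    out = np.empty(len(query_idx), dtype=int)
    need = int(np.ceil(k / 2))
    for i, q in enumerate(query_idx):
        d = np.linalg.norm(ref - coords[q], axis=1)
        order = np.lexsort((reference_idx, d))[:k]
        out[i] = int(is_ad[order].sum() >= need)
    return out


def stability_stratify(table: CohortTable, panel: Sequence[str],
                       scaler: Scaler, config: EmbeddingConfig
                       ) -> StratificationResult:
    """Repeat embed + k-NN labelling; report per-subject AD-like fraction.

    Repeat seeds are spawned from the master seed; the canonical embedding
    is repeat 0. A consensus tie (p_adlike exactly 0.5) resolves to AD-like
    and is flagged.
    """
    sub = table.by_group(GROUP_CONTROL, GROUP_AD, GROUP_ASYMAD)
    ids = list(sub.subject_ids)
    groups = list(sub.group_labels)
    idx = [scaler.columns.index(p) for p in panel]
    X = scaler.transform(_rows(sub, ids))[:, idx]

    ref_idx = [i for i, g in enumerate(groups) if g in (GROUP_CONTROL, GROUP_AD)]
    query_idx = [i for i, g in enumerate(groups) if g == GROUP_ASYMAD]
    is_ad_ref = np.array([groups[i] == GROUP_AD for i in ref_idx])
    if not query_idx:
        raise CohortError("no AsymAD subjects to stratify")

    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_repeats)
    repeat_labels = np.empty((len(query_idx), config.n_repeats), dtype=int)
    canonical = None
    for r in range(config.n_repeats):
        coords = embed_2d(X, config, int(seeds[r] % (2 ** 31 - 1)))
        if r == 0:
            canonical = coords
        repeat_labels[:, r] = knn_label(coords, is_ad_ref, ref_idx,
                                        query_idx, config.k_neighbors)
    p_adlike = repeat_labels.mean(axis=1)
    consensus, ties = [], []
    for sid, p in zip((ids[i] for i in query_idx), p_adlike):
        if p == 0.5:
            ties.append(sid)
            log.warning("consensus tie for %s resolved to ADLike", sid)
        consensus.append(SUBTYPE_AD_LIKE if p >= 0.5 else SUBTYPE_CONTROL_LIKE)
    return StratificationResult(
        [ids[i] for i in query_idx], consensus, p_adlike, repeat_labels,
        canonical, ids, groups, ties)


def apoe_enrichment(subtypes: Sequence[str], genotypes: Sequence[str]
                    ) -> dict:
    """APOE e4 enrichment between AsymAD subgroups.

    Primary test: 2x2 Fisher exact on e4 allele counts (two alleles per
    subject) by subgroup. A genotype-level 2x3 table (0/1/2 e4 alleles) with
    a chi-square test is also reported.
    """
    subtypes = np.asarray(subtypes, dtype=object)
    e4_counts = np.array([g.split("/").count("e4") for g in genotypes])
    masks = {s: subtypes == s for s in (SUBTYPE_AD_LIKE, SUBTYPE_CONTROL_LIKE)}
    if not all(m.any() for m in masks.values()):
        raise CohortError("both subgroups must be non-empty")

    allele_table = np.array([
        [e4_counts[m].sum(), 2 * m.sum() - e4_counts[m].sum()]
        for m in masks.values()])
    degenerate = bool((allele_table.sum(axis=0) == 0).any()
                      or (allele_table.sum(axis=1) == 0).any())
    if degenerate:
        p_allele = 1.0
    else:
        p_allele = float(stats.fisher_exact(allele_table,
                                            alternative="two-sided")[1])

    genotype_table = np.array([
        [int((e4_counts[m] == j).sum()) for j in (0, 1, 2)]
        for m in masks.values()])
    keep = genotype_table.sum(axis=0) > 0
    gt = genotype_table[:, keep]
    if gt.shape[1] < 2 or (gt.sum(axis=1) == 0).any():
        chi2, p_genotype = 0.0, 1.0
    else:
        chi2, p_genotype = stats.chi2_contingency(gt, correction=False)[:2]
    return {"allele_table": allele_table, "p_allele": p_allele,
            "genotype_table": genotype_table, "chi2_genotype": float(chi2),
            "p_genotype": float(p_genotype), "degenerate": degenerate}


def subgroup_classifier_eval(table: CohortTable, panel: Sequence[str],
                             scaler: Scaler, subtypes: pd.Series,
                             mode: str = "kfold", k: int = 6,
                             train_fraction: float = 109 / 130,
                             seed: int = 0, c: float = 1.0) -> MetricsReport:
    """Classify AsymAD subgroups from the panel.

    ``heldout`` mode fits once on a stratified split; ``kfold`` mode pools
    out-of-fold predictions of a stratified k-fold into one confusion matrix
    and one AUC.
    """
    ids = [sid for sid in table.subject_ids if sid in set(subtypes.index)]
    X = scaler.transform(_rows(table, ids))[
        :, [scaler.columns.index(p) for p in panel]]
    y = (subtypes.loc[ids] == SUBTYPE_AD_LIKE).to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise CohortError("both subgroup labels required")

    if mode == "kfold":
        return kfold_cv(X, y, k=k, seed=seed, C=c)
    if mode != "heldout":
        raise CohortError(f"unknown mode {mode!r}")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed)
    from sklearn.linear_model import LogisticRegression
    clf = LogisticRegression(C=c, max_iter=2000)
    clf.fit(X_tr, y_tr)
    conf = confusion_counts(y_te, clf.predict(X_te))
    return MetricsReport(conf, rates_from_confusion(conf),
                         roc_auc(clf.decision_function(X_te), y_te), seed=seed)
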