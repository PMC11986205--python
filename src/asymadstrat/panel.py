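"""Discriminative peptide panel selection.

Implements the dual-classifier backward-selection scheme: recursive feature
elimination run independently under a linear SVM and an L2 logistic
regression, panel = intersection of the two survivor sets, evaluated on a
held-out split that plays no role in scaling, selection or training. The
panel is quantified against a permutation null of random same-size peptide
sets and against a Kendall tau-b ranking of peptides versus cognition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
import warnings

from .cohort import GROUP_AD, GROUP_CONTROL, CohortError, CohortTable
from .metrics import (
    MetricsReport,
    confusion_counts,
    rates_from_confusion,
    roc_auc,
)

log = logging.getLogger(__name__)

SVM = "svm"
LOGISTIC = "logistic"


class EmptyPanelError(CohortError):
    """Intersection of the two RFE survivor sets is empty."""


@dataclass
class SelectionConfig:
    train_fraction: float = 0.80
    rfe_stop_size: int = 14
    rfe_step: int = 1
    regularization_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise CohortError("train_fraction must be in (0, 1)")
        if self.rfe_stop_size < 1:
            raise CohortError("rfe_stop_size must be >= 1")
        if self.rfe_step < 1:
            raise CohortError("rfe_step must be >= 1")


@dataclass
class Scaler:
    """Per-peptide train-set mean/sd; columns with zero variance excluded."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.columns].to_numpy(dtype=float)
        return (X - self.means) / self.sds


@dataclass
class PanelResult:
    svm_panel: list[str]
    logistic_panel: list[str]
    svm_elimination_order: list[str]
    logistic_elimination_order: list[str]
    final_panel: list[str]
    scaler: Scaler
    heldout_metrics: MetricsReport | None = None
    config: SelectionConfig | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "svm_panel": self.svm_panel,
            "logistic_panel": self.logistic_panel,
            "final_panel": self.final_panel,
            "scaler": {"columns": self.scaler.columns,
                       "means": self.scaler.means.tolist(),
                       "sds": self.scaler.sds.tolist(),
                       "excluded": self.scaler.excluded},
        }
        if self.heldout_metrics is not None:
            payload["heldout_metrics"] = {
                "confusion": self.heldout_metrics.confusion,
                "rates": self.heldout_metrics.rates,
                "roc_auc": self.heldout_metrics.roc_auc,
            }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelResult":
        payload = json.loads(Path(path).read_text())
        scaler = Scaler(payload["scaler"]["columns"],
                        np.asarray(payload["scaler"]["means"]),
                        np.asarray(payload["scaler"]["sds"]),
                        payload["scaler"]["excluded"])
        return cls(payload["svm_panel"], payload["logistic_panel"],
                   [], [], payload["final_panel"], scaler)


@dataclass
class PermutationNull:
    n_draws: int
    distributions: dict[str, np.ndarray]
    observed: dict[str, float]
    p_values: dict[str, float]
    seed: int


@dataclass
class CognitionRanking:
    taus: pd.Series                # peptide -> tau-b, descending
    panel_ranks: dict[str, int]    # 1-based rank positions of panel members


# -- splitting & scaling ---------------------------------------------------

def split_train_test(table: CohortTable, config: SelectionConfig,
                     labels: tuple[str, str] = (GROUP_CONTROL, GROUP_AD),
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/held-out split of subject ids; seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    train_ids, test_ids = [], []
    for label in labels:
        ids = table.data.loc[table.data["group_label"] == label,
                             "subject_id"].astype(str).to_numpy()
        if len(ids) < 2:
            raise CohortError(f"group {label!r} too small to stratify")
        perm = rng.permutation(len(ids))
        n_train = int(round(config.train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.append(ids[perm[:n_train]])
        test_ids.append(ids[perm[n_train:]])
    return np.concatenate(train_ids), np.concatenate(test_ids)


def fit_scaler(table: CohortTable, train_ids: Sequence[str],
               columns: Sequence[str] | None = None) -> Scaler:
    """Mean/unit-variance scaler from training rows only."""
    cols = list(columns) if columns is not None else list(table.peptide_columns)
    df = table.data.set_index(table.data["subject_id"].astype(str))
    X = df.loc[list(train_ids), cols].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    keep = sds > 0
    excluded = [c for c, k in zip(cols, keep) if not k]
    if excluded:
        log.warning("excluding zero-variance peptides: %s", excluded)
    cols = [c for c, k in zip(cols, keep) if k]
    return Scaler(cols, means[keep], sds[keep], excluded)


def _rows(table: CohortTable, ids: Sequence[str]) -> pd.DataFrame:
    df = table.data.set_index(table.data["subject_id"].astype(str))
    return df.loc[list(ids)]


def _binary_labels(df: pd.DataFrame,
                   labels: tuple[str, str] = (GROUP_CONTROL, GROUP_AD),
                   ) -> np.ndarray:
    return (df["group_label"] == labels[1]).to_numpy().astype(int)


# -- RFE -------------------------------------------------------------------

def _make_classifier(kind: str, c: float):
    if kind == SVM:
        return LinearSVC(C=c, dual=True, max_iter=20000, random_state=0)
    if kind == LOGISTIC:
        return LogisticRegression(C=c, max_iter=2000)
    raise CohortError(f"unknown classifier kind {kind!r}")


def _fit_weights(kind: str, c: float, X: np.ndarray, y: np.ndarray
                 ) -> np.ndarray:
    for attempt, c_eff in enumerate((c, c / 10.0, c / 100.0)):
        clf = _make_classifier(kind, c_eff)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X, y)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            if attempt:
                log.warning("%s converged after lowering C to %g", kind, c_eff)
            return clf.coef_.ravel()
    log.warning("%s did not converge even at C=%g; using last fit", kind, c_eff)
    return clf.coef_.ravel()


def rfe_select(X: np.ndarray, y: np.ndarray, classifier_kind: str,
               stop_size: int, step: int = 1, c: float = 1.0,
               feature_names: Sequence[str] | None = None,
               ) -> tuple[list, list]:
    """Recursive feature elimination under a linear classifier.

    Repeatedly fits the classifier and removes the `step` features with the
    smallest absolute weight until `stop_size` remain. Weight-magnitude ties
    are broken by eliminating the lower feature index first. Returns the
    surviving features and the elimination order (first-eliminated first).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n_features = X.shape[1]
    if len(np.unique(y)) < 2:
        raise CohortError("rfe_select requires two classes")
    if stop_size > n_features:
        raise CohortError("stop_size exceeds feature count")
    names = list(feature_names) if feature_names is not None \
        else list(range(n_features))

    active = list(range(n_features))
    eliminated: list[int] = []
    while len(active) > stop_size:
        w = _fit_weights(classifier_kind, c, X[:, active], y)
        n_drop = min(step, len(active) - stop_size)
        # stable argsort on |w| -> among ties the lower index goes first
        drop_local = np.argsort(np.abs(w), kind="stable")[:n_drop]
        for j in sorted(drop_local, reverse=True):
            eliminated.append(active.pop(j))
    return [names[i] for i in active], [names[i] for i in eliminated]


def intersect_panels(set_a: Sequence, set_b: Sequence) -> list:
    """Stable-order intersection of the two survivor sets."""
    inter = [p for p in sorted(set(set_a) & set(set_b))]
    if not inter:
        raise EmptyPanelError("RFE survivor sets have empty intersection")
    return inter


def select_panel(table: CohortTable, config: SelectionConfig,
                 labels: tuple[str, str] = (GROUP_CONTROL, GROUP_AD),
                 ) -> PanelResult:
    """End-to-end dual-RFE panel selection with held-out evaluation."""
    train_ids, test_ids = split_train_test(table, config, labels)
    scaler = fit_scaler(table, train_ids)
    train_df, test_df = _rows(table, train_ids), _rows(table, test_ids)
    X_train = scaler.transform(train_df)
    y_train = _binary_labels(train_df, labels)

    svm_panel, svm_elim = rfe_select(
        X_train, y_train, SVM, config.rfe_stop_size, config.rfe_step,
        config.regularization_c, scaler.columns)
    log_panel, log_elim = rfe_select(
        X_train, y_train, LOGISTIC, config.rfe_stop_size, config.rfe_step,
        config.regularization_c, scaler.columns)
    final = intersect_panels(svm_panel, log_panel)
    if len(final) < 2:
        raise EmptyPanelError(
            f"intersection has {len(final)} peptide(s); >= 2 required")

    result = PanelResult(svm_panel, log_panel, svm_elim, log_elim, final,
                         scaler, config=config)
    result.heldout_metrics = evaluate_panel(
        final, table, train_ids, test_ids, scaler,
        c=config.regularization_c, labels=labels)
    return result


# -- evaluation ------------------------------------------------------------

def evaluate_panel(panel: Sequence[str], table: CohortTable,
                   train_ids: Sequence[str], test_ids: Sequence[str],
                   scaler: Scaler, c: float = 1.0,
                   labels: tuple[str, str] = (GROUP_CONTROL, GROUP_AD),
                   ) -> MetricsReport:
    """Logistic regression on the panel, fit on train, scored on held-out."""
    if not panel:
        raise EmptyPanelError("panel is empty")
    idx = [scaler.columns.index(p) for p in panel]
    train_df, test_df = _rows(table, train_ids), _rows(table, test_ids)
    X_train = scaler.transform(train_df)[:, idx]
    X_test = scaler.transform(test_df)[:, idx]
    y_train = _binary_labels(train_df, labels)
    y_test = _binary_labels(test_df, labels)
    clf = LogisticRegression(C=c, max_iter=2000)
    clf.fit(X_train, y_train)
    scores = clf.decision_function(X_test)
    conf = confusion_counts(y_test, clf.predict(X_test))
    return MetricsReport(conf, rates_from_confusion(conf),
                         roc_auc(scores, y_test))


def permutation_test(panel: Sequence[str], table: CohortTable,
                     train_ids: Sequence[str], test_ids: Sequence[str],
                     scaler: Scaler, n_draws: int = 100_000, seed: int = 0,
                     c: float = 1.0, plus_one: bool = False,
                     labels: tuple[str, str] = (GROUP_CONTROL, GROUP_AD),
                     ) -> PermutationNull:
    """Permutation null over random same-size peptide subsets.

    Each draw picks a uniform random subset of the peptide universe of the
    panel's size (draws may coincide with the observed panel), trains a
    logistic model on the training rows and scores the held-out rows. The
    p-value per metric is the plain fraction of draws performing at least as
    well as the observed panel (``plus_one`` switches to (b+1)/(N+1)).
    """
    universe = list(scaler.columns)
    if len(universe) <= len(panel):
        raise CohortError("peptide universe must exceed the panel size")
    if n_draws < 100:
        log.warning("n_draws=%d < 100: permutation p-values unstable", n_draws)

    train_df, test_df = _rows(table, train_ids), _rows(table, test_ids)
    X_train_all = scaler.transform(train_df)
    X_test_all = scaler.transform(test_df)
    y_train = _binary_labels(train_df, labels)
    y_test = _binary_labels(test_df, labels)

    def metrics_for(cols: Sequence[int]) -> dict[str, float]:
        clf = LogisticRegression(C=c, max_iter=2000)
        clf.fit(X_train_all[:, cols], y_train)
        pred = clf.predict(X_test_all[:, cols])
        conf = confusion_counts(y_test, pred)
        rates = rates_from_confusion(conf)
        return {"accuracy": rates["accuracy"],
                "precision": rates["precision"],
                "recall": rates["recall"],
                "auc": roc_auc(clf.decision_function(X_test_all[:, cols]),
                               y_test)}

    observed = metrics_for([universe.index(p) for p in panel])
    rng = np.random.default_rng(seed)
    dists = {k: np.empty(n_draws) for k in observed}
    for d in range(n_draws):
        cols = rng.choice(len(universe), size=len(panel), replace=False)
        m = metrics_for(cols)
        for k in dists:
            dists[k][d] = m[k]
    p_values = {}
    for k in dists:
        b = int(np.sum(dists[k] >= observed[k] - 1e-12))
        p_values[k] = (b + 1) / (n_draws + 1) if plus_one else b / n_draws
    return PermutationNull(n_draws, dists, observed, p_values, seed)


def kendall_moca_ranking(table: CohortTable,
                         panel: Sequence[str] | None = None,
                         ) -> CognitionRanking:
    """Kendall tau-b of every peptide against the MoCA score, all groups."""
    moca = pd.to_numeric(table.data["moca"], errors="coerce")
    mask = moca.notna()
    if mask.sum() < 3:
        raise CohortError("too few MoCA values")
    if moca[mask].nunique() == 1:
        raise CohortError("MoCA constant; Kendall tau undefined")
    taus = {}
    for col in table.peptide_columns:
        x = pd.to_numeric(table.data[col], errors="coerce")
        ok = mask & x.notna()
        taus[col] = stats.kendalltau(x[ok], moca[ok]).statistic
    series = pd.Series(taus).sort_values(ascending=False)
    ranks = {p: int(series.index.get_loc(p)) + 1 for p in (panel or [])}
    return CognitionRanking(series, ranks)


def volcano_stats(table: CohortTable, groups: tuple[str, str] = (
        GROUP_CONTROL, GROUP_AD)) -> pd.DataFrame:
    """Per-peptide log2 fold change (group2/group1 linear means) and
    two-sided Mann-Whitney p-value."""
    a = table.by_group(groups[0])
    b = table.by_group(groups[1])
    if a.n_subjects < 3 or b.n_subjects < 3:
        raise CohortError("both groups need >= 3 subjects")
    rows = []
    for col in table.peptide_columns:
        xa = a.data[col].dropna().to_numpy(dtype=float)
        xb = b.data[col].dropna().to_numpy(dtype=float)
        ma, mb = xa.mean(), xb.mean()
        flagged = ma <= 0 or mb <= 0
        log2fc = np.nan if flagged else np.log2(mb / ma)
        p = stats.mannwhitneyu(xb, xa, alternative="two-sided").pvalue
        rows.append((col, log2fc, p, flagged))
    return pd.DataFrame(rows, columns=["peptide", "log2fc", "p_value",
                                       "flagged"]).set_index("peptide")
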