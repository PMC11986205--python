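"""Biomarker positivity cut-offs and diagnostic group assignment.

Two cut-off derivations are supported: a two-component Gaussian mixture on a
CSF analyte ratio (positivity = posterior of the upper component above 0.5)
and a Youden-index cut-off on an ROC curve of PET SUVR scores. Group
assignment combines a cut-off with cognitive status; matched group triplets
are built greedily within exact sex/race strata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import (
    GROUP_AD,
    GROUP_ASYMAD,
    GROUP_CONTROL,
    CohortError,
    CohortTable,
)

log = logging.getLogger(__name__)

GREATER_IS_POSITIVE = "greater_is_positive"
LESS_IS_POSITIVE = "less_is_positive"


@dataclass
class MixtureCutoff:
    """Two-component Gaussian mixture fit and the derived positivity cutoff."""

    component_means: tuple[float, float]
    component_sds: tuple[float, float]
    component_weights: tuple[float, float]
    cutoff: float | None
    log_scale_used: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if abs(sum(self.component_weights) - 1.0) > 1e-9:
                raise CohortError("mixture weights must sum to 1")
            if self.component_means[0] > self.component_means[1]:
                raise CohortError("component means must be sorted ascending")
            if self.cutoff is not None and not (
                    self.component_means[0] < self.cutoff < self.component_means[1]):
                raise CohortError("cutoff must lie strictly between the means")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class RocCutoff:
    """Youden-index ROC threshold."""

    threshold: float
    direction: str
    youden_j: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if abs(self.youden_j - (self.sensitivity + self.specificity - 1)) > 1e-9:
            raise CohortError("youden_j inconsistent with sensitivity/specificity")

    def is_positive(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if self.direction == GREATER_IS_POSITIVE:
            return scores > self.threshold
        return scores < self.threshold

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class MatchedCohort:
    triplets: list[tuple[str, str, str]]
    matching_keys: list[str]
    calipers: Mapping[str, float]
    unmatched: list[str] = field(default_factory=list)


def _em_univariate(x: np.ndarray, mu: np.ndarray, sd: np.ndarray,
                   w: np.ndarray, tol: float = 1e-6, max_iter: int = 500):
    """EM for a two-component univariate Gaussian mixture."""
    ll_old = -np.inf
    for _ in range(max_iter):
        dens = w[None, :] * stats.norm.pdf(x[:, None], mu[None, :], sd[None, :])
        total = dens.sum(axis=1)
        total = np.maximum(total, 1e-300)
        ll = np.log(total).sum()
        resp = dens / total[:, None]
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0)
        sd = np.sqrt(np.maximum(var / np.maximum(nk, 1e-12), 1e-12))
        if ll - ll_old < tol:
            break
        ll_old = ll
    return mu, sd, w, ll


def fit_ratio_mixture(values: Sequence[float], use_log: bool = False,
                      n_restarts: int = 5, seed: int = 0) -> MixtureCutoff:
    """Fit a 2-component Gaussian mixture to a biomarker ratio by EM.

    The cutoff is the point between the component means where the posterior
    responsibility of the upper component crosses 0.5. A weight below 0.01
    or a collapsed standard deviation flags the fit as degenerate and no
    cutoff is reported.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 20:
        raise CohortError("need at least 20 finite values to fit a mixture")
    if use_log:
        if (x <= 0).any():
            raise CohortError("log-scale fit requires strictly positive values")
        x = np.log(x)
    data_sd = x.std()
    if data_sd == 0:
        return MixtureCutoff((float(x[0]),) * 2, (0.0, 0.0), (0.5, 0.5),
                             None, use_log, degenerate=True)

    rng = np.random.default_rng(seed)
    q25, q75 = np.percentile(x, [25, 75])
    best = None
    for r in range(n_restarts):
        if r == 0:
            mu = np.array([q25, q75], dtype=float)
        else:
            mu = np.sort(rng.normal([q25, q75], 0.25 * data_sd))
        if mu[1] - mu[0] < 1e-9:
            mu[1] = mu[0] + 0.1 * data_sd
        sd = np.full(2, 0.5 * data_sd)
        w = np.array([0.5, 0.5])
        fit = _em_univariate(x, mu, sd, w)
        if best is None or fit[3] > best[3]:
            best = fit
    mu, sd, w, _ = best
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]

    degenerate = bool(w.min() < 0.01 or sd.min() < 1e-3 * data_sd
                      or mu[1] - mu[0] < 1e-6 * data_sd)
    cutoff = None
    if not degenerate:
        def posterior_upper(t: float) -> float:
            d = w * stats.norm.pdf(t, mu, sd)
            return d[1] / d.sum() - 0.5

        lo, hi = mu[0], mu[1]
        if posterior_upper(lo) < 0 < posterior_upper(hi):
            cutoff = float(optimize.brentq(posterior_upper, lo, hi,
                                           xtol=1e-10))
        else:
            degenerate = True
            log.warning("no posterior-0.5 crossing between component means")
    return MixtureCutoff(tuple(map(float, mu)), tuple(map(float, sd)),
                         tuple(map(float, w)), cutoff, use_log, degenerate)


def youden_cutoff(scores: Sequence[float], labels: Sequence[int],
                  direction: str = GREATER_IS_POSITIVE) -> RocCutoff:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores. Ties on J are broken by higher sensitivity, then by smaller
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores.shape != y.shape:
        raise CohortError("scores and labels must have equal length")
    classes = np.unique(y)
    if len(classes) != 2:
        raise CohortError("youden_cutoff requires both classes present")
    if direction not in (GREATER_IS_POSITIVE, LESS_IS_POSITIVE):
        raise CohortError(f"unknown direction {direction!r}")

    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise CohortError("all scores identical; no threshold exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    pos = y == y.max()
    n_pos, n_neg = pos.sum(), (~pos).sum()

    best = None
    for t in candidates:
        pred = scores > t if direction == GREATER_IS_POSITIVE else scores < t
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, float(t), float(j), float(sens), float(spec))
    _, t, j, sens, spec = best
    return RocCutoff(t, direction, j, sens, spec)


def assign_groups(
    table: CohortTable,
    cognitive_status: Sequence[str],
    ratio_cutoff: float | MixtureCutoff | None = None,
    suvr_cutoff: RocCutoff | None = None,
) -> pd.DataFrame:
    """Assign diagnostic groups from cognitive status and biomarker positivity.

    CN & biomarker-negative -> Control; CN & positive -> AsymAD;
    symptomatic & positive -> AD; symptomatic & negative -> excluded.
    Positivity is a strict inequality against the cutoff. Returns a frame
    with columns ``subject_id, assignment, reason``; assignment is one of
    Control/AsymAD/AD/excluded/unassignable.
    """
    status = np.asarray(cognitive_status, dtype=object)
    if len(status) != table.n_subjects:
        raise CohortError("cognitive_status length mismatch")
    if (ratio_cutoff is None) == (suvr_cutoff is None):
        raise CohortError("provide exactly one of ratio_cutoff / suvr_cutoff")

    if ratio_cutoff is not None:
        cut = ratio_cutoff.cutoff if isinstance(ratio_cutoff, MixtureCutoff) \
            else float(ratio_cutoff)
        if cut is None:
            raise CohortError("degenerate mixture cutoff cannot assign groups")
        score = table.ratio()
        positive = score > cut
    else:
        score = table.data["av45_suvr"].to_numpy(dtype=float)
        positive = suvr_cutoff.is_positive(score)

    rows = []
    for sid, st, sc, p in zip(table.subject_ids, status, score, positive):
        if not np.isfinite(sc):
            rows.append((sid, "unassignable", "missing biomarker"))
        elif st == "CN":
            rows.append((sid, GROUP_ASYMAD if p else GROUP_CONTROL, ""))
        else:
            if p:
                rows.append((sid, GROUP_AD, ""))
            else:
                rows.append((sid, "excluded",
                             "symptomatic but biomarker-negative"))
    return pd.DataFrame(rows, columns=["subject_id", "assignment", "reason"])


def match_groups(
    table: CohortTable,
    calipers: Mapping[str, float] | None = None,
) -> MatchedCohort:
    """Greedy 1:1:1 Control/AsymAD/AD matching.

    Matching is exact on sex and race, nearest-age within the age caliper and
    within the education caliper. AsymAD subjects (sorted by age) pick the
    closest-age unused Control and AD from their stratum.
    """
    calipers = dict(calipers or {"age": 5.0, "education": 3.0})
    df = table.data
    groups = {g: df[df["group_label"] == g] for g in
              (GROUP_CONTROL, GROUP_ASYMAD, GROUP_AD)}
    for g, sub in groups.items():
        if sub.empty:
            raise CohortError(f"cannot match: group {g!r} is empty")

    used: dict[str, set[int]] = {GROUP_CONTROL: set(), GROUP_AD: set()}
    triplets: list[tuple[str, str, str]] = []
    unmatched: list[str] = []

    def pick(pool: pd.DataFrame, row: pd.Series, group: str) -> int | None:
        cand = pool[(pool["sex"] == row["sex"]) & (pool["race"] == row["race"])]
        cand = cand[~cand.index.isin(used[group])]
        if "education" in calipers:
            cand = cand[(cand["education"] - row["education"]).abs()
                        <= calipers["education"]]
        if "age" in calipers:
            cand = cand[(cand["age"] - row["age"]).abs() <= calipers["age"]]
        if cand.empty:
            return None
        return (cand["age"] - row["age"]).abs().idxmin()

    for _, row in groups[GROUP_ASYMAD].sort_values("age").iterrows():
        ctrl = pick(groups[GROUP_CONTROL], row, GROUP_CONTROL)
        ad = pick(groups[GROUP_AD], row, GROUP_AD)
        if ctrl is None or ad is None:
            unmatched.append(str(row["subject_id"]))
            if ctrl is None or ad is None:
                log.warning("no match in stratum sex=%s race=%s for %s",
                            row["sex"], row["race"], row["subject_id"])
            continue
        used[GROUP_CONTROL].add(ctrl)
        used[GROUP_AD].add(ad)
        triplets.append((str(df.loc[ctrl, "subject_id"]),
                         str(row["subject_id"]),
                         str(df.loc[ad, "subject_id"])))
    return MatchedCohort(triplets, ["age", "sex", "race", "education"],
                         calipers, unmatched)
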