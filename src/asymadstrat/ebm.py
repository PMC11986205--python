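"""Scaled event-based disease-progression model.

Biomarkers are partitioned into equal-size clusters that become abnormal
together; a disease stage s means the biomarkers of the first s clusters in
the event ordering are drawn from their abnormal distribution. The model
jointly infers the cluster ordering and the balanced biomarker-to-cluster
assignment by Metropolis MCMC over a likelihood that marginalizes each
subject's stage under a uniform prior. Per-biomarker normal/abnormal
components are two-component Gaussian mixtures anchored on the labelled
Control / AD rows.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import CohortError

log = logging.getLogger(__name__)


@dataclass
class EbmConfig:
    n_clusters: int = 4
    cluster_size: int = 2
    implicit_feature_exclusion: int = 0
    mcmc_iterations: int = 500_000
    burn_in: int = 300_000
    greedy_starts: int = 30
    greedy_iterations: int = 800
    greedy_candidates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.implicit_feature_exclusion != 0:
            raise CohortError(
                "implicit_feature_exclusion != 0 is not supported; "
                "only the value 0 has defined semantics here")
        if self.burn_in >= self.mcmc_iterations:
            raise CohortError("burn_in must be < mcmc_iterations")
        if self.n_clusters < 1 or self.cluster_size < 1:
            raise CohortError("n_clusters and cluster_size must be >= 1")

    @property
    def n_biomarkers(self) -> int:
        return self.n_clusters * self.cluster_size


def fast_config(**overrides) -> EbmConfig:
    """Reduced-schedule profile for tests: 5e4 MCMC iterations."""
    defaults = dict(mcmc_iterations=50_000, burn_in=30_000,
                    greedy_starts=8, greedy_iterations=200)
    defaults.update(overrides)
    return EbmConfig(**defaults)


@dataclass
class BiomarkerMixture:
    """Per-biomarker normal/abnormal Gaussian components."""

    names: list[str]
    normal_mean: np.ndarray
    normal_sd: np.ndarray
    abnormal_mean: np.ndarray
    abnormal_sd: np.ndarray
    weight_normal: np.ndarray     # mixing weight of the normal component
    direction: np.ndarray         # sign of (abnormal - normal) mean
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.normal_sd <= 0).any() or (self.abnormal_sd <= 0).any():
            raise CohortError("mixture sds must be positive")
        if ((self.weight_normal <= 0) | (self.weight_normal >= 1)).any():
            raise CohortError("mixing weights must be in (0, 1)")


@dataclass(frozen=True)
class EbmState:
    """Cluster ordering plus balanced biomarker-to-cluster assignment."""

    cluster_order: tuple[int, ...]
    cluster_assignment: tuple[int, ...]   # biomarker index -> cluster
    log_likelihood: float = float("nan")

    def validate(self, n_clusters: int, cluster_size: int) -> None:
        if sorted(self.cluster_order) != list(range(n_clusters)):
            raise CohortError("cluster_order is not a permutation")
        counts = Counter(self.cluster_assignment)
        if any(counts.get(c, 0) != cluster_size for c in range(n_clusters)):
            raise CohortError("assignment is not a balanced partition")


@dataclass
class EbmFit:
    config: EbmConfig
    mixtures: BiomarkerMixture
    samples: list[tuple[tuple[int, ...], tuple[int, ...]]]
    modal_state: EbmState
    positional_variance: np.ndarray             # clusters x positions
    biomarker_positional_variance: np.ndarray   # biomarkers x positions
    acceptance_rate: float

    def __post_init__(self) -> None:
        expect = self.config.mcmc_iterations - self.config.burn_in
        if len(self.samples) != expect:
            raise CohortError("retained sample count != iterations - burn_in")


@dataclass
class StagePosterior:
    probabilities: np.ndarray   # subjects x (n_clusters + 1)
    ml_stage: np.ndarray
    incomplete: np.ndarray      # subjects staged on partial biomarker data

    def __post_init__(self) -> None:
        sums = self.probabilities.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise CohortError("stage posteriors must sum to 1")


# -- mixtures --------------------------------------------------------------

def _anchored_em(x: np.ndarray, mu: np.ndarray, sd: np.ndarray,
                 w0: float, sd_floor: float, direction: float,
                 clamp_normal: np.ndarray | None = None,
                 clamp_abnormal: np.ndarray | None = None,
                 max_iter: int = 200, tol: float = 1e-8):
    """Two-component EM keeping component means ordered along `direction`.

    Rows flagged in `clamp_normal` / `clamp_abnormal` are held in their
    component (responsibility fixed), anchoring the fit on labelled rows;
    unlabelled rows get free posterior responsibilities.
    """
    w = np.array([w0, 1.0 - w0])
    ll_old = -np.inf
    for _ in range(max_iter):
        dens = w[None, :] * stats.norm.pdf(x[:, None], mu[None, :], sd[None, :])
        tot = np.maximum(dens.sum(axis=1), 1e-300)
        ll = np.log(tot).sum()
        resp = dens / tot[:, None]
        if clamp_normal is not None:
            resp[clamp_normal, 0] = 1.0
            resp[clamp_normal, 1] = 0.0
        if clamp_abnormal is not None:
            resp[clamp_abnormal, 0] = 0.0
            resp[clamp_abnormal, 1] = 1.0
        nk = np.maximum(resp.sum(axis=0), 1e-12)
        w = nk / len(x)
        mu_new = (resp * x[:, None]).sum(axis=0) / nk
        # keep the abnormal mean on its side of the normal mean
        if direction * (mu_new[1] - mu_new[0]) < 0:
            mid = mu_new.mean()
            mu_new = np.array([mid - 1e-6 * direction, mid + 1e-6 * direction])
        mu = mu_new
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
        if ll - ll_old < tol:
            break
        ll_old = ll
    return mu, sd, w


def fit_mixtures(X: np.ndarray, labels: Sequence[str] | np.ndarray,
                 names: Sequence[str] | None = None,
                 control_label: str = "Control", ad_label: str = "AD",
                 ) -> BiomarkerMixture:
    """Fit per-biomarker normal/abnormal mixtures anchored on labels.

    The normal component is initialized from Control rows and the abnormal
    component from AD rows; EM then refines both on the pooled data while
    keeping the means ordered in the abnormality direction. Collapsing
    standard deviations are floored at 1e-3 of the per-biomarker data sd.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    ctrl, ad = labels == control_label, labels == ad_label
    if not ctrl.any() or not ad.any():
        raise CohortError("both Control and AD rows are required")
    n_bio = X.shape[1]
    names = list(names) if names is not None else [f"b{i}" for i in range(n_bio)]

    out = {k: np.empty(n_bio) for k in
           ("nm", "ns", "am", "asd", "w", "dirn")}
    degenerate = np.zeros(n_bio, dtype=bool)
    for b in range(n_bio):
        x = X[:, b]
        keep = np.isfinite(x)
        x = x[keep]
        clamp_n, clamp_a = ctrl[keep], ad[keep]
        xc, xa = X[ctrl, b], X[ad, b]
        xc, xa = xc[np.isfinite(xc)], xa[np.isfinite(xa)]
        data_sd = max(x.std(), 1e-12)
        sd_floor = 1e-3 * data_sd
        direction = np.sign(xa.mean() - xc.mean()) or 1.0
        if abs(xa.mean() - xc.mean()) < 1e-9 * data_sd:
            degenerate[b] = True
        mu0 = np.array([xc.mean(), xa.mean()])
        sd0 = np.maximum(np.array([xc.std(), xa.std()]), sd_floor)
        if (sd0 == sd_floor).any():
            log.warning("sd floored for biomarker %s", names[b])
        mu, sd, w = _anchored_em(x, mu0, sd0, len(xc) / (len(xc) + len(xa)),
                                 sd_floor, direction, clamp_normal=clamp_n,
                                 clamp_abnormal=clamp_a)
        out["nm"][b], out["am"][b] = mu
        out["ns"][b], out["asd"][b] = sd
        out["w"][b] = np.clip(w[0], 1e-6, 1 - 1e-6)
        out["dirn"][b] = direction
    return BiomarkerMixture(names, out["nm"], out["ns"], out["am"],
                            out["asd"], out["w"], out["dirn"],
                            degenerate if degenerate.any() else None)


# -- likelihood ------------------------------------------------------------

class _LikelihoodCache:
    """Precomputed per-subject log densities for fast state evaluation.

    Missing biomarker values contribute nothing (log density 0 under either
    component), which marginalizes them out of the stage likelihood.
    """

    def __init__(self, X: np.ndarray, mixtures: BiomarkerMixture,
                 n_clusters: int):
        X = np.asarray(X, dtype=float)
        ln = stats.norm.logpdf(X, mixtures.normal_mean, mixtures.normal_sd)
        la = stats.norm.logpdf(X, mixtures.abnormal_mean, mixtures.abnormal_sd)
        missing = ~np.isfinite(X)
        self.incomplete = missing.any(axis=1)
        ln = np.where(missing, 0.0, ln)
        la = np.where(missing, 0.0, la)
        finite = np.isfinite(ln) & np.isfinite(la)
        if not finite.all():
            bad = int(np.argmin(finite.all(axis=0)))
            raise CohortError(f"non-finite density for biomarker index {bad}")
        self.delta = la - ln                  # subjects x biomarkers
        self.base = ln.sum(axis=1)            # subjects
        self.n_clusters = n_clusters
        self.n = len(X)

    def cluster_deltas(self, assignment: Sequence[int]) -> np.ndarray:
        """Per-subject delta summed within each cluster (subjects x clusters)."""
        a = np.asarray(assignment)
        D = np.zeros((self.n, self.n_clusters))
        for c in range(self.n_clusters):
            D[:, c] = self.delta[:, a == c].sum(axis=1)
        return D

    def stage_loglik(self, order: Sequence[int], D: np.ndarray) -> np.ndarray:
        """Per-subject per-stage log p(x | stage), stages 0..K (no prior)."""
        cum = np.zeros((self.n, self.n_clusters + 1))
        np.cumsum(D[:, list(order)], axis=1, out=cum[:, 1:])
        return cum + self.base[:, None]

    def loglik(self, order: Sequence[int], D: np.ndarray) -> float:
        per_stage = self.stage_loglik(order, D)
        m = per_stage.max(axis=1, keepdims=True)
        lse = np.log(np.exp(per_stage - m).sum(axis=1)) + m[:, 0]
        return float(lse.sum() - self.n * np.log(self.n_clusters + 1))


def state_log_likelihood(state: EbmState, X: np.ndarray,
                         mixtures: BiomarkerMixture) -> float:
    """Marginal log-likelihood of the data under one state.

    Each subject's stage is marginalized with a uniform prior over
    0..n_clusters; biomarkers of clusters at ordering positions <= stage use
    the abnormal component, the rest the normal component.
    """
    n_clusters = len(state.cluster_order)
    cluster_size = len(state.cluster_assignment) // n_clusters
    state.validate(n_clusters, cluster_size)
    cache = _LikelihoodCache(X, mixtures, n_clusters)
    D = cache.cluster_deltas(state.cluster_assignment)
    return cache.loglik(state.cluster_order, D)


# -- inference -------------------------------------------------------------

def _random_state(rng: np.random.Generator, config: EbmConfig
                  ) -> tuple[np.ndarray, np.ndarray]:
    order = rng.permutation(config.n_clusters)
    assignment = np.repeat(np.arange(config.n_clusters), config.cluster_size)
    rng.shuffle(assignment)
    return order, assignment


def greedy_init(X: np.ndarray, mixtures: BiomarkerMixture,
                config: EbmConfig) -> EbmState:
    """Greedy hill-climb from random starts.

    Each iteration evaluates a sampled set of candidate moves (cluster-order
    swaps and cross-cluster biomarker swaps) and accepts the best if it
    improves the likelihood. The best state over all starts is returned.
    """
    cache = _LikelihoodCache(X, mixtures, config.n_clusters)
    rng = np.random.default_rng(config.seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(config.greedy_starts, 1)):
        order, assignment = _random_state(rng, config)
        D = cache.cluster_deltas(assignment)
        ll = cache.loglik(order, D)
        for _ in range(config.greedy_iterations):
            cand_best = None
            for _ in range(config.greedy_candidates):
                o2, a2, D2 = _propose(rng, order, assignment, D, cache, config)
                ll2 = cache.loglik(o2, D2)
                if cand_best is None or ll2 > cand_best[0]:
                    cand_best = (ll2, o2, a2, D2)
            if cand_best[0] > ll:
                ll, order, assignment, D = cand_best
        if best is None or ll > best[0]:
            best = (ll, order, assignment)
    ll, order, assignment = best
    return EbmState(tuple(int(i) for i in order),
                    tuple(int(i) for i in assignment), ll)


def _propose(rng, order, assignment, D, cache, config):
    """Symmetric proposal: order swap or cross-cluster biomarker swap."""
    if config.n_clusters == 1:
        return order, assignment, D
    if config.cluster_size == 1 or rng.random() < 0.5:
        i, j = rng.choice(config.n_clusters, size=2, replace=False)
        o2 = order.copy()
        o2[i], o2[j] = o2[j], o2[i]
        return o2, assignment, D
    # swap two biomarkers between different clusters
    n_bio = len(assignment)
    while True:
        b1, b2 = rng.choice(n_bio, size=2, replace=False)
        if assignment[b1] != assignment[b2]:
            break
    a2 = assignment.copy()
    a2[b1], a2[b2] = a2[b2], a2[b1]
    c1, c2 = assignment[b1], assignment[b2]
    D2 = D.copy()
    shift = cache.delta[:, b2] - cache.delta[:, b1]
    D2[:, c1] += shift
    D2[:, c2] -= shift
    return order, a2, D2


def mcmc_sample(init: EbmState, X: np.ndarray, mixtures: BiomarkerMixture,
                config: EbmConfig) -> EbmFit:
    """Metropolis sampling over (cluster order, balanced assignment).

    Proposals are symmetric (uniform order-position swap or cross-cluster
    biomarker swap) accepted with probability min(1, exp(delta logL)).
    Post-burn-in states are retained; the modal state is the most frequent
    sampled state, ties broken by likelihood.
    """
    init.validate(config.n_clusters, config.cluster_size)
    cache = _LikelihoodCache(X, mixtures, config.n_clusters)
    rng = np.random.default_rng(config.seed + 1)
    order = np.asarray(init.cluster_order)
    assignment = np.asarray(init.cluster_assignment)
    D = cache.cluster_deltas(assignment)
    ll = cache.loglik(order, D)

    samples: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    counts: Counter = Counter()
    state_ll: dict = {}
    pv = np.zeros((config.n_clusters, config.n_clusters))
    bpv = np.zeros((len(assignment), config.n_clusters))
    accepted = 0
    for it in range(config.mcmc_iterations):
        o2, a2, D2 = _propose(rng, order, assignment, D, cache, config)
        ll2 = cache.loglik(o2, D2)
        if ll2 >= ll or rng.random() < np.exp(ll2 - ll):
            order, assignment, D, ll = o2, a2, D2, ll2
            accepted += 1
        if it >= config.burn_in:
            key = (tuple(int(i) for i in order),
                   tuple(int(i) for i in assignment))
            samples.append(key)
            counts[key] += 1
            state_ll.setdefault(key, ll)
            pos_of_cluster = np.empty(config.n_clusters, dtype=int)
            pos_of_cluster[order] = np.arange(config.n_clusters)
            pv[np.arange(config.n_clusters), pos_of_cluster] += 1
            bpv[np.arange(len(assignment)), pos_of_cluster[assignment]] += 1

    rate = accepted / config.mcmc_iterations
    if not 0.01 <= rate <= 0.99:
        log.warning("MCMC acceptance rate %.3f outside [0.01, 0.99]", rate)
    top = max(counts, key=lambda k: (counts[k], state_ll[k]))
    modal = EbmState(top[0], top[1], state_ll[top])
    n_kept = len(samples)
    return EbmFit(config, mixtures, samples, modal, pv / n_kept,
                  bpv / n_kept, rate)


def fit_ebm(X: np.ndarray, labels: Sequence[str], config: EbmConfig,
            names: Sequence[str] | None = None) -> EbmFit:
    """Convenience wrapper: mixtures -> greedy init -> MCMC."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != config.n_biomarkers:
        raise CohortError(
            f"expected {config.n_biomarkers} biomarkers, got {X.shape[1]}")
    mixtures = fit_mixtures(X, labels, names)
    init = greedy_init(X, mixtures, config)
    return mcmc_sample(init, X, mixtures, config)


# -- staging ---------------------------------------------------------------

def stage_subjects(fit: EbmFit, X: np.ndarray,
                   mixtures: BiomarkerMixture | None = None) -> StagePosterior:
    """Posterior over stages under the modal state, uniform stage prior.

    Subjects with missing biomarker values are staged over the observed
    biomarkers only and flagged. ML stage ties resolve to the lower stage.
    """
    mixtures = mixtures if mixtures is not None else fit.mixtures
    cache = _LikelihoodCache(X, mixtures, fit.config.n_clusters)
    D = cache.cluster_deltas(fit.modal_state.cluster_assignment)
    per_stage = cache.stage_loglik(fit.modal_state.cluster_order, D)
    per_stage = per_stage - per_stage.max(axis=1, keepdims=True)
    probs = np.exp(per_stage)
    probs /= probs.sum(axis=1, keepdims=True)
    ml = probs.argmax(axis=1)   # argmax returns the lowest index on ties
    if cache.incomplete.any():
        log.warning("%d subject(s) staged on partial biomarker data",
                    int(cache.incomplete.sum()))
    return StagePosterior(probs, ml, cache.incomplete)


def recalibrate(fit: EbmFit, X_external: np.ndarray,
                labels: Sequence[str] | None = None,
                names: Sequence[str] | None = None) -> BiomarkerMixture:
    """Re-fit mixture parameters on an external cohort.

    The event ordering and cluster assignment stay fixed; only the
    per-biomarker component parameters move. With labels the components are
    anchored as in :func:`fit_mixtures`; without labels an unconstrained EM
    is initialized from the training parameters.
    """
    X_external = np.asarray(X_external, dtype=float)
    if names is not None:
        missing = [n for n in fit.mixtures.names if n not in list(names)]
        if missing:
            raise CohortError(f"external cohort missing biomarkers: {missing}")
        idx = [list(names).index(n) for n in fit.mixtures.names]
        X_external = X_external[:, idx]
    if X_external.shape[1] != len(fit.mixtures.names):
        raise CohortError("external biomarker count mismatch")

    if labels is not None:
        return fit_mixtures(X_external, labels, fit.mixtures.names)

    m = fit.mixtures
    nm = np.empty_like(m.normal_mean)
    ns, am, asd, w = (np.empty_like(nm) for _ in range(4))
    for b in range(len(m.names)):
        x = X_external[:, b]
        x = x[np.isfinite(x)]
        sd_floor = 1e-3 * max(x.std(), 1e-12)
        mu, sd, wk = _anchored_em(
            x, np.array([m.normal_mean[b], m.abnormal_mean[b]]),
            np.array([m.normal_sd[b], m.abnormal_sd[b]]),
            float(m.weight_normal[b]), sd_floor, float(m.direction[b]))
        nm[b], am[b] = mu
        ns[b], asd[b] = sd
        w[b] = np.clip(wk[0], 1e-6, 1 - 1e-6)
    return BiomarkerMixture(list(m.names), nm, ns, am, asd, w,
                            m.direction.copy())


def planted_order_distance(state: EbmState, planted_ordering: Sequence[int],
                           planted_clusters: Sequence[Sequence[int]]) -> float:
    """Cluster-level Kendall distance between a state and a planted cascade.

    Works at the biomarker level so it is meaningful even when the recovered
    partition differs from the planted one: counts biomarker pairs from
    different planted clusters whose relative event order disagrees, scaled
    by the planted cluster size squared. Equals the plain Kendall distance
    between cluster orders when the partitions coincide.
    """
    n_clusters = len(state.cluster_order)
    pos_of_cluster = np.empty(n_clusters, dtype=int)
    pos_of_cluster[list(state.cluster_order)] = np.arange(n_clusters)
    got = pos_of_cluster[list(state.cluster_assignment)]

    n_bio = len(state.cluster_assignment)
    planted_pos = np.empty(n_bio, dtype=int)
    for p, cluster in enumerate(planted_ordering):
        for b in planted_clusters[cluster]:
            planted_pos[b] = p
    size = len(planted_clusters[0])
    discordant = 0
    for i in range(n_bio):
        for j in range(i + 1, n_bio):
            if planted_pos[i] == planted_pos[j]:
                continue
            di, dj = planted_pos[i] - planted_pos[j], got[i] - got[j]
            if di * dj < 0 or (dj == 0 and di != 0):
                discordant += 0.5 if dj == 0 else 1.0
    return discordant / size ** 2


def stage_distribution_test(stages: Sequence[int], groups: Sequence[str]
                            ) -> tuple[float, float]:
    """Pearson chi-square on the group x stage contingency table.

    Stage columns with an all-zero margin are dropped before the test.
    """
    stages = np.asarray(stages)
    groups = np.asarray(groups, dtype=object)
    uniq_groups = sorted(set(groups))
    if len(uniq_groups) < 2:
        raise CohortError("stage comparison requires >= 2 groups")
    uniq_stages = sorted(set(stages))
    table = np.array([[int(((groups == g) & (stages == s)).sum())
                       for s in uniq_stages] for g in uniq_groups])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 0.0, 1.0
    chi2, p = stats.chi2_contingency(table, correction=False)[:2]
    return float(chi2), float(p)
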