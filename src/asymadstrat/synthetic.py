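"""Synthetic cohort generation.

Two generators are provided:

* :func:`generate_cohort` builds a three-group cohort (Control / AsymAD / AD)
  whose statistical structure matches what the analysis pipeline assumes —
  a latent severity continuum, a handful of informative peptides with
  monotone effects, a bimodal tTau:Abeta42 ratio, group-specific APOE e4
  allele frequencies and a severity-coupled MoCA score.
* :func:`generate_event_cascade` builds a biomarker cascade with a planted
  cluster-level event ordering, used as a recovery oracle for the
  event-based staging model.

Peptide abundances are generated on the log scale and exported linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    GROUP_AD,
    GROUP_ASYMAD,
    GROUP_CONTROL,
    GROUP_UNLABELLED,
    SUBTYPE_AD_LIKE,
    SUBTYPE_CONTROL_LIKE,
    CohortError,
    CohortTable,
    GroundTruth,
    peptide_name,
)

# per-group log-normal (median, log-scale sd) for the three CSF analytes;
# medians/IQR-derived sigmas chosen to give a clearly bimodal tTau:Abeta42
# ratio between biomarker-negative and biomarker-positive subjects
DEFAULT_ANALYTE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    GROUP_CONTROL: {"abeta42": (1412.0, 0.14), "ttau": (167.6, 0.13),
                    "ptau": (14.8, 0.15)},
    GROUP_ASYMAD: {"abeta42": (740.1, 0.16), "ttau": (242.0, 0.18),
                   "ptau": (22.8, 0.18)},
    GROUP_AD: {"abeta42": (540.7, 0.18), "ttau": (343.2, 0.22),
               "ptau": (33.9, 0.24)},
}

DEFAULT_APOE_E4_FREQ = {GROUP_CONTROL: 0.08, GROUP_ASYMAD: 0.40, GROUP_AD: 0.50}

_RACES = ("Caucasian", "AfricanAmerican", "Asian")
_RACE_P = (0.925, 0.067, 0.008)


@dataclass
class CohortConfig:
    """Configuration for :func:`generate_cohort`."""

    n_control: int = 134
    n_asymad: int = 134
    n_ad: int = 134
    n_peptides: int = 75
    #: peptide index -> signed log-scale shift per unit latent severity
    informative_peptides: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.4
    analyte_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_ANALYTE_PARAMS)
    apoe_e4_freq: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_APOE_E4_FREQ))
    moca_slope: float = 11.0
    moca_noise_sd: float = 1.5
    #: AsymAD latent severity band; both subtypes occur by construction
    asymad_severity_range: tuple[float, float] = (0.15, 0.85)
    include_suvr: bool = False
    #: probability of masking each peptide cell (missing completely at random)
    mcar_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_asymad", "n_ad", "n_peptides"):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be >= 0")
        if self.noise_sd <= 0:
            raise CohortError("noise_sd must be positive")
        for g, f in self.apoe_e4_freq.items():
            if not 0.0 <= f <= 1.0:
                raise CohortError(f"apoe_e4_freq[{g!r}] outside [0, 1]")
        for idx, eff in self.informative_peptides.items():
            if not np.isfinite(eff):
                raise CohortError(f"effect size for peptide {idx} not finite")
            if not 0 <= idx < self.n_peptides:
                raise CohortError(f"informative peptide index {idx} out of range")
        if len(self.informative_peptides) > self.n_peptides:
            raise CohortError("more informative peptides than peptides")
        if not 0.0 <= self.mcar_fraction < 1.0:
            raise CohortError("mcar_fraction must be in [0, 1)")


def default_config(**overrides) -> CohortConfig:
    """Config with eight planted informative peptides of alternating sign."""
    effects = {i: (1.5 if i % 2 == 0 else -1.5) for i in range(8)}
    overrides.setdefault("informative_peptides", effects)
    return CohortConfig(**overrides)


def _draw_apoe(rng: np.random.Generator, e4_freq: float, n: int) -> list[str]:
    alleles = np.where(rng.random((n, 2)) < e4_freq, "e4",
                       np.where(rng.random((n, 2)) < 0.06, "e2", "e3"))
    return ["/".join(sorted(a)) for a in alleles]


def generate_cohort(config: CohortConfig) -> tuple[CohortTable, GroundTruth]:
    """Generate a three-group synthetic cohort; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    groups = ([GROUP_CONTROL] * config.n_control
              + [GROUP_ASYMAD] * config.n_asymad
              + [GROUP_AD] * config.n_ad)
    n = len(groups)
    group_arr = np.array(groups, dtype=object)

    lo, hi = config.asymad_severity_range
    severity = np.empty(n)
    # Control and AD occupy fixed low/high bands; AsymAD spans the middle
    severity[group_arr == GROUP_CONTROL] = rng.uniform(
        0.0, 0.15, (group_arr == GROUP_CONTROL).sum())
    severity[group_arr == GROUP_ASYMAD] = rng.uniform(
        lo, hi, (group_arr == GROUP_ASYMAD).sum())
    severity[group_arr == GROUP_AD] = rng.uniform(
        0.85, 1.0, (group_arr == GROUP_AD).sum())

    # peptides: log-scale baseline per peptide + monotone severity effect
    baselines = rng.normal(7.0, 0.5, config.n_peptides)
    effects = np.zeros(config.n_peptides)
    for idx, eff in config.informative_peptides.items():
        effects[idx] = eff
    log_pep = (baselines[None, :] + severity[:, None] * effects[None, :]
               + rng.normal(0.0, config.noise_sd, (n, config.n_peptides)))
    peptides = np.exp(log_pep)
    if config.mcar_fraction > 0:
        mask = rng.random(peptides.shape) < config.mcar_fraction
        peptides = np.where(mask, np.nan, peptides)

    age = np.clip(rng.normal(66.0, 6.0, n), 45, 90).round(1)
    sex = np.where(rng.random(n) < 0.746, "F", "M")
    race = rng.choice(_RACES, size=n, p=_RACE_P)
    education = np.clip(rng.normal(16.5, 2.2, n), 8, 22).round(0)
    moca = np.clip(np.rint(28.0 - config.moca_slope * severity
                           + rng.normal(0.0, config.moca_noise_sd, n)), 0, 30)

    analytes = {k: np.empty(n) for k in ("abeta42", "ttau", "ptau")}
    apoe = np.empty(n, dtype=object)
    for g in (GROUP_CONTROL, GROUP_ASYMAD, GROUP_AD):
        idx = np.flatnonzero(group_arr == g)
        if not len(idx):
            continue
        for analyte in analytes:
            med, sig = config.analyte_params[g][analyte]
            analytes[analyte][idx] = np.exp(
                rng.normal(np.log(med), sig, len(idx)))
        apoe[idx] = _draw_apoe(rng, config.apoe_e4_freq.get(g, 0.0), len(idx))

    data = pd.DataFrame({
        "subject_id": [f"S{i + 1:05d}" for i in range(n)],
        "group_label": group_arr,
        "age": age, "sex": sex, "race": race, "education": education,
        "moca": moca, "apoe": apoe,
        "abeta42": analytes["abeta42"], "ttau": analytes["ttau"],
        "ptau": analytes["ptau"],
    })
    if config.include_suvr:
        data["av45_suvr"] = (1.0 + 0.45 * severity
                             + rng.normal(0, 0.08, n)).round(4)
        data["fdg_suvr"] = (1.35 - 0.25 * severity
                            + rng.normal(0, 0.07, n)).round(4)
    pep_cols = [peptide_name(i) for i in range(config.n_peptides)]
    data = pd.concat([data, pd.DataFrame(peptides, columns=pep_cols)], axis=1)

    subtype = np.where(group_arr == GROUP_ASYMAD,
                       np.where(severity > 0.5, SUBTYPE_AD_LIKE,
                                SUBTYPE_CONTROL_LIKE), None)
    truth = GroundTruth(pd.DataFrame({
        "subject_id": data["subject_id"],
        "group_label": group_arr,
        "latent_severity": severity,
        "true_asymad_subtype": subtype,
    }))
    return CohortTable(data, pep_cols), truth


def generate_event_cascade(
    n_subjects: int,
    ordering: Sequence[int],
    mixtures: Sequence[tuple[float, float, float, float]],
    stage_dist: Sequence[float],
    seed: int = 0,
    clusters: Sequence[Sequence[int]] | None = None,
) -> tuple[CohortTable, GroundTruth]:
    """Generate a biomarker cascade with a planted cluster event ordering.

    Parameters
    ----------
    ordering:
        Permutation of cluster indices; ``ordering[p]`` is the cluster whose
        biomarkers become abnormal at stage ``p + 1``.
    mixtures:
        Per biomarker ``(normal_mean, normal_sd, abnormal_mean, abnormal_sd)``.
    stage_dist:
        Stage probabilities over ``0 .. n_clusters`` (must sum to 1).
    clusters:
        Biomarker indices per cluster; defaults to consecutive equal-size
        chunks.

    Subjects at stage ``s`` draw biomarkers of the first ``s`` clusters in
    the ordering from their abnormal component, the rest from normal.
    """
    n_clusters = len(ordering)
    if sorted(ordering) != list(range(n_clusters)):
        raise CohortError("ordering must be a permutation of cluster indices")
    stage_dist = np.asarray(stage_dist, dtype=float)
    if len(stage_dist) != n_clusters + 1:
        raise CohortError("stage_dist must have n_clusters + 1 entries")
    if not np.isclose(stage_dist.sum(), 1.0):
        raise CohortError("stage_dist must sum to 1")
    n_bio = len(mixtures)
    if clusters is None:
        size, rem = divmod(n_bio, n_clusters)
        if rem:
            raise CohortError("biomarker count not divisible by cluster count")
        clusters = [list(range(c * size, (c + 1) * size))
                    for c in range(n_clusters)]
    covered = sorted(b for cl in clusters for b in cl)
    if covered != list(range(n_bio)):
        raise CohortError("clusters must partition the biomarker indices")

    rng = np.random.default_rng(seed)
    stages = rng.choice(n_clusters + 1, size=n_subjects, p=stage_dist)
    # abnormal_at[b] = stage at which biomarker b turns abnormal
    abnormal_at = np.empty(n_bio, dtype=int)
    for pos, cluster in enumerate(ordering):
        for b in clusters[cluster]:
            abnormal_at[b] = pos + 1
    mix = np.asarray(mixtures, dtype=float)
    abnormal = stages[:, None] >= abnormal_at[None, :]
    means = np.where(abnormal, mix[:, 2], mix[:, 0])
    sds = np.where(abnormal, mix[:, 3], mix[:, 1])
    values = rng.normal(means, sds)

    labels = np.where(stages == 0, GROUP_CONTROL,
                      np.where(stages == n_clusters, GROUP_AD,
                               GROUP_UNLABELLED))
    pep_cols = [peptide_name(i) for i in range(n_bio)]
    data = pd.DataFrame({
        "subject_id": [f"E{i + 1:05d}" for i in range(n_subjects)],
        "group_label": labels,
    })
    data = pd.concat([data, pd.DataFrame(values, columns=pep_cols)], axis=1)
    truth = GroundTruth(
        pd.DataFrame({"subject_id": data["subject_id"],
                      "group_label": labels,
                      "true_stage": stages}),
        true_event_ordering=list(ordering),
    )
    return CohortTable(data, pep_cols), truth
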