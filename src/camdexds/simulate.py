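"""Synthetic cohorts with the structure the analysis pipeline assumes.

The study population this generator emulates is a cohort of adults with
Down syndrome in four clinician-assigned diagnostic groups --
asymptomatic (n=49), mental-health condition without Alzheimer's disease
(n=15), prodromal Alzheimer's disease (n=10) and Alzheimer's disease
dementia (n=11) -- with an imaging subcohort (n=39) whose regional
amyloid binding rises, and cortical thickness falls, with interview
severity.

Item responses are drawn independently per item from a group-by-section
probability triple over the levels {0, 1, 2}; the default triples are
calibrated so that group mean totals sit near 1/5/10/30, severity is
ordered asymptomatic < mentalhealth < prodromal < dementia, the
mental-health group is elevated only in Sections C1/C2 (behavioural
overlap with dementia), and the population-optimal total-score
cut-offs land near the instrument's published ones.  An optional shared
latent-severity tilt induces within-participant item correlation;
it is off by default because the true item covariance is unknown.

Because item responses are independent given the group, the exact
distribution of any section or total score is a 54-fold convolution of
three-point distributions; :func:`planted_boundary` uses this to report
the population-optimal (maximum Youden) cut-off implied by a
configuration, which parameter-recovery tests compare against cut-offs
re-derived from finite generated cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .scoring import (
    DIAGNOSTIC_GROUPS,
    SECTION_SIZES,
    InterviewRecord,
    Section,
    default_codification,
)

__all__ = [
    "CohortConfig",
    "ImagingConfig",
    "generate_cohort",
    "generate_imaging",
    "total_score_pmf",
    "planted_boundary",
    "DEFAULT_REGIONS",
]

_PROB_TOL = 1e-9

# Calibrated per-item response-level probabilities (p0, p1, p2) by
# group and section.  See docs/methods.md for the calibration targets.
DEFAULT_ITEM_LEVEL_PROBS: dict[str, dict[str, tuple[float, float, float]]] = {
    "asymptomatic": {
        "A": (0.966, 0.032, 0.002),
        "B": (0.966, 0.032, 0.002),
        "C1": (0.966, 0.032, 0.002),
        "C2": (0.966, 0.032, 0.002),
    },
    "mentalhealth": {
        "A": (0.966, 0.032, 0.002),
        "B": (0.927, 0.065, 0.008),
        "C1": (0.888, 0.100, 0.012),
        "C2": (0.888, 0.100, 0.012),
    },
    "prodromal": {
        "A": (0.950, 0.048, 0.002),
        "B": (0.700, 0.280, 0.020),
        "C1": (0.860, 0.130, 0.010),
        "C2": (0.940, 0.055, 0.005),
    },
    "dementia": {
        "A": (0.500, 0.300, 0.200),
        "B": (0.250, 0.300, 0.450),
        "C1": (0.630, 0.250, 0.120),
        "C2": (0.815, 0.155, 0.030),
    },
}

# Age structure: prodromal and dementia groups are older (years).
DEFAULT_AGE_PARAMS: dict[str, tuple[float, float, int, int]] = {
    "asymptomatic": (38.0, 9.0, 19, 60),
    "mentalhealth": (38.0, 9.0, 19, 60),
    "prodromal": (51.0, 6.0, 36, 65),
    "dementia": (54.0, 5.0, 40, 65),
}

DEFAULT_GROUP_SIZES = {
    "asymptomatic": 49,
    "mentalhealth": 15,
    "prodromal": 10,
    "dementia": 11,
}

DEFAULT_SEX_BALANCE = {g: 0.5 for g in DIAGNOSTIC_GROUPS}

# Only mild and moderate intellectual disability occur by default,
# mirroring the population the instrument was characterised in.
DEFAULT_ID_LEVEL_PROBS = {
    g: {"mild": 0.4, "moderate": 0.6, "severe": 0.0} for g in DIAGNOSTIC_GROUPS
}

# Probability that Part 3 screening flags a mental-health condition.
DEFAULT_MENTAL_HEALTH_PROB = {
    "asymptomatic": 0.0,
    "mentalhealth": 1.0,
    "prodromal": 0.3,
    "dementia": 0.3,
}


def _check_triple(probs, where: str) -> tuple[float, float, float]:
    p = tuple(float(v) for v in probs)
    if len(p) != 3 or any(v < 0 for v in p) or abs(sum(p) - 1.0) > _PROB_TOL:
        raise ValueError(
            f"{where}: probabilities {probs} must be 3 non-negative values summing to 1"
        )
    return p


@dataclass
class CohortConfig:
    """Generator settings for the interview cohort."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    item_level_probs: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {
            g: dict(sec) for g, sec in DEFAULT_ITEM_LEVEL_PROBS.items()
        }
    )
    age_params: dict[str, tuple[float, float, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_PARAMS)
    )
    sex_balance: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_BALANCE))
    id_level_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_ID_LEVEL_PROBS.items()}
    )
    mental_health_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MENTAL_HEALTH_PROB)
    )
    latent_severity_sd: float = 0.0  # 0 disables the shared severity tilt
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in DIAGNOSTIC_GROUPS:
                raise ValueError(f"unknown diagnostic group {g!r}")
            if n < 0:
                raise ValueError(f"group size for {g!r} must be >= 0, got {n}")
        if sum(self.group_sizes.values()) < 2:
            raise ValueError("total cohort size must be at least 2")
        for g in self.group_sizes:
            for s in Section:
                _check_triple(
                    self.item_level_probs[g][s.value], f"item_level_probs[{g}][{s.value}]"
                )
            idp = self.id_level_probs[g]
            if abs(sum(idp.values()) - 1.0) > _PROB_TOL or any(v < 0 for v in idp.values()):
                raise ValueError(f"id_level_probs[{g}] must be a probability vector")
        if self.latent_severity_sd < 0:
            raise ValueError("latent_severity_sd must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        cfg = cls(**{k: v for k, v in d.items()})
        # tuples arrive as lists from YAML/JSON
        cfg.item_level_probs = {
            g: {s: tuple(p) for s, p in sec.items()}
            for g, sec in cfg.item_level_probs.items()
        }
        cfg.age_params = {g: tuple(v) for g, v in cfg.age_params.items()}
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _tilted(probs: tuple[float, float, float], z: float) -> np.ndarray:
    """Tilt a response triple by a latent severity z (log-odds shift)."""
    w = np.exp(z)
    raw = np.array([probs[0], probs[1] * w, probs[2] * w * w])
    return raw / raw.sum()


def _truncated_normal_int(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return int(round(v))
    return int(round(np.clip(mean, lo, hi)))


def generate_cohort(config: CohortConfig | None = None) -> list[InterviewRecord]:
    """Draw a labelled cohort of interview records (reproducible by seed)."""
    config = config if config is not None else CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    codification = default_codification()
    item_ids = [it.item_id for it in codification]
    item_sections = [Section(it.section) for it in codification]
    records: list[InterviewRecord] = []
    counter = 0
    for group in DIAGNOSTIC_GROUPS:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        sec_probs = {s: np.asarray(_check_triple(config.item_level_probs[group][s.value], group))
                     for s in Section}
        mean, sd, lo, hi = config.age_params[group]
        idp = config.id_level_probs[group]
        id_names = list(idp.keys())
        id_p = np.array([idp[k] for k in id_names], dtype=float)
        id_p /= id_p.sum()
        z = (
            rng.normal(0.0, config.latent_severity_sd, size=n)
            if config.latent_severity_sd > 0
            else np.zeros(n)
        )
        # per-participant cumulative level probabilities, (n, n_items, 2)
        cum = np.empty((n, len(codification), 2))
        for j, s in enumerate(item_sections):
            if config.latent_severity_sd > 0:
                p = np.stack([_tilted(sec_probs[s], zi) for zi in z])
            else:
                p = np.broadcast_to(sec_probs[s], (n, 3))
            cum[:, j, 0] = p[:, 0]
            cum[:, j, 1] = p[:, 0] + p[:, 1]
        u = rng.random((n, len(codification)))
        levels = (u[:, :, None] >= cum).sum(axis=2)  # 0, 1 or 2
        ages = np.array([_truncated_normal_int(rng, mean, sd, lo, hi) for _ in range(n)])
        female = rng.random(n) < config.sex_balance[group]
        id_idx = rng.choice(len(id_names), size=n, p=id_p)
        mh = rng.random(n) < config.mental_health_prob[group]
        for i in range(n):
            counter += 1
            records.append(
                InterviewRecord(
                    participant_id=f"P{counter:03d}",
                    age=int(ages[i]),
                    sex="female" if female[i] else "male",
                    id_level=id_names[int(id_idx[i])],
                    mental_health_flag=bool(mh[i]),
                    diagnostic_group=group,
                    responses={
                        item_ids[j]: int(levels[i, j]) for j in range(len(item_ids))
                    },
                )
            )
    return records


# ---------------------------------------------------------------------------
# Exact score distributions implied by a configuration

def total_score_pmf(
    config: CohortConfig, group: str, sections: Sequence[Section] | None = None
) -> np.ndarray:
    """Exact pmf of the (section or total) score for one group.

    With items independent given the group, the score is a sum of
    three-point variables; the pmf is their discrete convolution.  Only
    valid for ``latent_severity_sd = 0`` (the default); with the latent
    tilt the marginal pmf is a continuous mixture, so this raises.
    """
    if config.latent_severity_sd > 0:
        raise ValueError("exact pmf undefined with a latent severity tilt")
    if sections is None:
        sections = list(Section)
    pmf = np.array([1.0])
    for s in sections:
        triple = np.asarray(_check_triple(config.item_level_probs[group][s.value], group))
        for _ in range(SECTION_SIZES[s]):
            pmf = np.convolve(pmf, triple)
    return pmf


def planted_boundary(
    config: CohortConfig,
    positive_group: str,
    negative_group: str,
    sections: Sequence[Section] | None = None,
) -> float:
    """Population-optimal cut-off implied by the generator configuration.

    Maximises the population Youden index J(c) = F_neg(c) - F_pos(c)
    over half-integer cut-offs, with the same smallest-cut-off tie rule
    the empirical derivation uses.
    """
    pmf_pos = total_score_pmf(config, positive_group, sections)
    pmf_neg = total_score_pmf(config, negative_group, sections)
    support = max(len(pmf_pos), len(pmf_neg))
    f_pos = np.cumsum(np.pad(pmf_pos, (0, support - len(pmf_pos))))
    f_neg = np.cumsum(np.pad(pmf_neg, (0, support - len(pmf_neg))))
    j = f_neg - f_pos  # J at cut-off k + 0.5
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return best + 0.5


# ---------------------------------------------------------------------------
# Imaging subcohort

# Desikan-Killiany cortical parcellation, hemisphere-qualified (68 regions).
_DK_NAMES = [
    "bankssts", "caudal anterior cingulate", "caudal middle frontal", "cuneus",
    "entorhinal", "frontal pole", "fusiform", "inferior parietal",
    "inferior temporal", "insula", "isthmus cingulate", "lateral occipital",
    "lateral orbitofrontal", "lingual", "medial orbitofrontal", "middle temporal",
    "paracentral", "parahippocampal", "pars opercularis", "pars orbitalis",
    "pars triangularis", "pericalcarine", "postcentral", "posterior cingulate",
    "precentral", "precuneus", "rostral anterior cingulate",
    "rostral middle frontal", "superior frontal", "superior parietal",
    "superior temporal", "supramarginal", "temporal pole", "transverse temporal",
]
DEFAULT_REGIONS = [f"{hemi} {name}" for name in _DK_NAMES for hemi in ("left", "right")]

DEFAULT_BP_SIGNAL_REGIONS = (
    "right medial orbitofrontal",
    "left superior temporal",
    "right superior temporal",
)
# Temporoparietal thinning carries a weaker signal, mirroring the weaker
# thickness associations seen in this population.
DEFAULT_THICKNESS_SIGNAL_REGIONS = (
    "left inferior parietal",
    "right precuneus",
    "left middle temporal",
)


@dataclass
class ImagingConfig:
    """Generator settings for the imaging subcohort."""

    n_imaging: int = 39
    regions: tuple[str, ...] = tuple(DEFAULT_REGIONS)
    bp_signal_regions: tuple[str, ...] = DEFAULT_BP_SIGNAL_REGIONS
    thickness_signal_regions: tuple[str, ...] = DEFAULT_THICKNESS_SIGNAL_REGIONS
    bp_slope: float = 0.60          # BP_ND units per SD of total score
    thickness_slope: float = -0.08  # mm per SD of total score
    bp_noise_sd: float = 0.12
    thickness_noise_sd: float = 0.12
    bp_baseline: float = 0.60
    thickness_baseline: float = 2.5
    seed: int = 0

    def validate(self, n_records: int | None = None) -> None:
        if self.n_imaging < 1:
            raise ValueError("n_imaging must be >= 1")
        if n_records is not None and self.n_imaging > n_records:
            raise ValueError(
                f"n_imaging={self.n_imaging} exceeds cohort size {n_records}"
            )
        for name, sig in (
            ("bp_signal_regions", self.bp_signal_regions),
            ("thickness_signal_regions", self.thickness_signal_regions),
        ):
            unknown = set(sig) - set(self.regions)
            if unknown:
                raise ValueError(f"{name} not in region list: {sorted(unknown)}")
        if self.bp_noise_sd <= 0 or self.thickness_noise_sd <= 0:
            raise ValueError("noise SDs must be > 0")
        if self.bp_slope < 0 or self.thickness_slope > 0:
            raise ValueError("bp_slope must be >= 0 and thickness_slope <= 0")


def generate_imaging(records, config: ImagingConfig | None = None):
    """Simulate regional BP_ND and thickness tables for a subcohort.

    Subsamples ``n_imaging`` participants; signal regions get
    baseline + slope * z(total score) + noise, noise-only regions get
    baseline + noise.  Returns ``(bp_table, thickness_table)``.
    """
    from .imaging import RegionalTable  # local import to avoid a cycle
    from .scoring import score_interview

    config = config if config is not None else ImagingConfig()
    config.validate(n_records=len(records))
    rng = np.random.default_rng(config.seed)
    chosen = sorted(rng.choice(len(records), size=config.n_imaging, replace=False))
    subset = [records[i] for i in chosen]
    totals = np.array([score_interview(r).total for r in subset], dtype=float)
    sd = totals.std()
    z = (totals - totals.mean()) / (sd if sd > 0 else 1.0)
    ids = [r.participant_id for r in subset]

    import pandas as pd

    tables = []
    for measure, signal, slope, noise_sd, baseline in (
        ("bp_nd", config.bp_signal_regions, config.bp_slope,
         config.bp_noise_sd, config.bp_baseline),
        ("thickness", config.thickness_signal_regions, config.thickness_slope,
         config.thickness_noise_sd, config.thickness_baseline),
    ):
        data = {}
        for region in config.regions:
            eff = slope * z if region in signal else 0.0
            values = baseline + eff + rng.normal(0.0, noise_sd, size=len(subset))
            if measure == "thickness":
                values = np.maximum(values, 0.2)  # keep thickness physical
            else:
                values = np.maximum(values, -0.45)  # noise floor for BP_ND
            data[region] = values
        tables.append(RegionalTable(measure, pd.DataFrame(data, index=pd.Index(ids, name="participant_id"))))
    return tables[0], tables[1]
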