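"""Seeded generators emulating the lifespan study's data-generating structure.

The generator produces:

* Gompertz lifespans — hazard h(t) = a * exp(b t), sampled by inverse CDF
  and rounded to whole days, with the genotype entering as a proportional
  scaling of the baseline hazard ``a`` (proportional hazards);
* ulcerative-dermatitis euthanasia flags at the study's per-stratum
  incidences, independent of mortality by default (a correlation knob
  exists);
* tumour status whose probability rises logistically with age at death,
  with 1-3 findings drawn from a categorical tumour-type/organ table, and
  a per-stratum count of mice without necropsy;
* negative-binomial count matrices (variance m + phi * m^2, so
  CV^2 ~ 1/m + phi) with gene-wise means log-uniform over a range and a
  planted subset of genes whose dispersion is inflated in designated
  "old" groups — the ground truth is returned for recovery testing.

Defaults reproduce the study's conditions: 50 mice per arm, a wild-type
female median near 623 days, a mutant hazard ratio giving roughly +20%
median survival, UD incidences 38/52/30/20 percent and necropsy dropouts
0/2/3/5 across the four sex-by-genotype strata, and n = 6 samples per
expression group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import Cohort, MouseRecord, TumourFinding
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "CountSimulation",
    "sample_gompertz",
    "gompertz_median_days",
    "simulate_cohort",
    "simulate_study",
    "simulate_counts",
]

#: categorical (tumour_type, organ) table with sampling weights
TUMOUR_TABLE: tuple[tuple[str, str, float], ...] = (
    ("lymphoma", "spleen", 0.22),
    ("lymphoma", "liver", 0.12),
    ("lymphoma", "lymph node", 0.10),
    ("hepatocellular carcinoma", "liver", 0.24),
    ("histiocytic sarcoma", "spleen", 0.10),
    ("histiocytic sarcoma", "liver", 0.08),
    ("histiocytic sarcoma", "lung", 0.06),
    ("haemangiosarcoma", "liver", 0.04),
    ("adenocarcinoma", "lung", 0.04),
)

STRATA = ("female/wt", "female/mutant", "male/wt", "male/mutant")


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters (all rates per day).

    ``gompertz_a`` is chosen so the wild-type median sits near 623 days at
    ``gompertz_b`` = 0.012/day; ``hazard_ratio_mutant`` scales ``a`` for
    the mutant arm (values < 1 extend life; the default gives about +20%
    median survival). UD probabilities and necropsy dropouts are keyed by
    ``sex/genotype``.
    """

    n_per_arm: int = 50
    gompertz_a: float = 4.71e-6
    gompertz_b: float = 0.012
    hazard_ratio_mutant: float = 0.214
    ud_prob_per_stratum: dict = field(
        default_factory=lambda: {
            "female/wt": 0.38,
            "female/mutant": 0.52,
            "male/wt": 0.30,
            "male/mutant": 0.20,
        }
    )
    ud_mortality_correlation: float = 0.0
    necropsy_dropout_per_stratum: dict = field(
        default_factory=lambda: {
            "female/wt": 0,
            "female/mutant": 2,
            "male/wt": 3,
            "male/mutant": 5,
        }
    )
    tumour_logistic_intercept: float = -3.0
    tumour_logistic_slope: float = 0.006
    nb_mean_range: tuple[float, float] = (1.0, 5000.0)
    nb_dispersion_young: float = 0.1
    nb_dispersion_old: float = 0.6
    planted_variable_genes: int = 100
    samples_per_group: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValidationError("Gompertz a and b must be positive")
        if self.hazard_ratio_mutant <= 0:
            raise ValidationError("hazard_ratio_mutant must be positive")
        for k, p in self.ud_prob_per_stratum.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"UD probability out of [0,1] for {k}: {p}")
        if self.nb_dispersion_young <= 0 or self.nb_dispersion_old <= 0:
            raise ValidationError("NB dispersions must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nb_mean_range"] = list(self.nb_mean_range)
        return d


@dataclass
class CountSimulation:
    """Simulated count matrix with its ground truth."""

    counts: pd.DataFrame
    library_sizes: pd.Series
    sample_groups: dict[str, str]
    planted_genes: list[str]
    gene_means: pd.Series


def gompertz_median_days(a: float, b: float) -> float:
    """Closed-form Gompertz median: (1/b) ln(1 + (b/a) ln 2)."""
    return (1.0 / b) * math.log(1.0 + (b / a) * math.log(2.0))


def sample_gompertz(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator | None = None,
    hazard_scale: float = 1.0,
) -> np.ndarray:
    """Sample n Gompertz lifespans rounded to whole days (minimum 1).

    Inverse-CDF sampling: t = (1/b) ln(1 + (b/a) (-ln U)), U uniform(0,1),
    with the baseline hazard ``a`` multiplied by ``hazard_scale``.
    """
    rng = config.rng() if rng is None else rng
    a = config.gompertz_a * hazard_scale
    b = config.gompertz_b
    u = rng.uniform(size=n)
    t = (1.0 / b) * np.log1p((b / a) * (-np.log(u)))
    return np.maximum(1, np.rint(t).astype(int))


def _stratum_key(stratum) -> tuple[str, str]:
    if isinstance(stratum, str):
        parts = stratum.split("/")
    else:
        parts = list(stratum)
    if len(parts) != 2:
        raise ValidationError(f"stratum must be sex/genotype, got {stratum!r}")
    sex, genotype = parts
    if sex not in ("female", "male") or genotype not in ("wt", "mutant"):
        raise ValidationError(
            f"stratum must combine sex in (female, male) and genotype in "
            f"(wt, mutant), got {stratum!r}"
        )
    return sex, genotype


def simulate_cohort(
    config: SimulationConfig,
    stratum,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Simulate one sex-by-genotype arm of the lifespan study.

    Lifespans are Gompertz with the mutant hazard ratio applied to the
    baseline hazard; UD flags are Bernoulli at the stratum incidence
    (optionally rank-correlated with short lifespans through
    ``ud_mortality_correlation``); tumour status follows the
    logistic-in-age model and bearing mice receive 1-3 distinct findings
    from the type/organ table; the stratum's necropsy dropout count marks
    that many mice (chosen at random) as not necropsied, with no tumour
    data.
    """
    sex, genotype = _stratum_key(stratum)
    key = f"{sex}/{genotype}"
    rng = config.rng() if rng is None else rng
    n = config.n_per_arm
    scale = 1.0 if genotype == "wt" else config.hazard_ratio_mutant
    lifespans = sample_gompertz(config, n, rng=rng, hazard_scale=scale)

    p_ud = config.ud_prob_per_stratum.get(key, 0.0)
    ud = rng.uniform(size=n) < p_ud
    corr = config.ud_mortality_correlation
    if corr != 0.0:
        # move UD flags toward the shortest-lived mice with probability |corr|
        k = int(ud.sum())
        aligned = np.zeros(n, dtype=bool)
        order = np.argsort(lifespans if corr > 0 else -lifespans, kind="stable")
        aligned[order[:k]] = True
        use_aligned = rng.uniform(size=n) < abs(corr)
        ud = np.where(use_aligned, aligned, ud)

    logit = config.tumour_logistic_intercept + config.tumour_logistic_slope * lifespans
    p_tum = 1.0 / (1.0 + np.exp(-logit))
    bearing = rng.uniform(size=n) < p_tum

    dropout = int(config.necropsy_dropout_per_stratum.get(key, 0))
    no_necropsy = np.zeros(n, dtype=bool)
    if dropout > 0:
        no_necropsy[rng.choice(n, size=min(dropout, n), replace=False)] = True

    weights = np.array([w for _, _, w in TUMOUR_TABLE])
    weights = weights / weights.sum()
    records = []
    prefix = f"{sex[0]}{'mu' if genotype == 'mutant' else 'wt'}"
    for i in range(n):
        findings: tuple[TumourFinding, ...] = ()
        if bearing[i] and not no_necropsy[i]:
            n_find = 1 + int(rng.choice(3, p=[0.6, 0.3, 0.1]))
            picks = rng.choice(len(TUMOUR_TABLE), size=n_find, replace=False, p=weights)
            findings = tuple(
                TumourFinding(TUMOUR_TABLE[j][0], TUMOUR_TABLE[j][1]) for j in picks
            )
        records.append(
            MouseRecord(
                mouse_id=f"{prefix}-{i:03d}",
                genotype=genotype,
                sex=sex,
                lifespan_days=int(lifespans[i]),
                event_observed=True,
                ud_case=bool(ud[i]),
                necropsy_performed=not bool(no_necropsy[i]),
                tumour_findings=findings,
            )
        )
    return Cohort(records, stratum_label=key)


def simulate_study(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, Cohort]:
    """Simulate all four sex-by-genotype arms from one seeded stream."""
    rng = config.rng() if rng is None else rng
    return {s: simulate_cohort(config, s, rng=rng) for s in STRATA}


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, phi: float | np.ndarray
) -> np.ndarray:
    """Negative binomial with variance mean + phi * mean^2 (gamma-Poisson)."""
    shape = 1.0 / np.asarray(phi, dtype=float)
    lam = rng.gamma(shape, np.asarray(mean) / shape)
    return rng.poisson(lam)


def simulate_counts(
    config: SimulationConfig,
    n_genes: int,
    groups: dict[str, int] | None = None,
    old_groups: set[str] | None = None,
    inflate_groups: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> CountSimulation:
    """Simulate an NB count matrix with planted high-dispersion genes.

    ``groups`` maps group label to its number of samples (default: four
    groups young_wt/old_wt/young_mutant/old_mutant with
    ``samples_per_group`` each). Groups named in ``old_groups`` (default:
    labels starting with "old") use ``nb_dispersion_old`` on the planted
    gene subset; ``inflate_groups`` restricts the inflation to a subset of
    the old groups. All other gene/group combinations use
    ``nb_dispersion_young``. Gene means are log-uniform over
    ``nb_mean_range`` and shared across groups; library sizes are the
    column totals.
    """
    rng = config.rng() if rng is None else rng
    if groups is None:
        groups = {
            g: config.samples_per_group
            for g in ("young_wt", "old_wt", "young_mutant", "old_mutant")
        }
    if old_groups is None:
        old_groups = {g for g in groups if g.startswith("old")}
    if inflate_groups is None:
        inflate_groups = set(old_groups)
    unknown = inflate_groups - set(groups)
    if unknown:
        raise ValidationError(f"inflate_groups not in design: {sorted(unknown)}")

    lo, hi = config.nb_mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    n_planted = min(config.planted_variable_genes, n_genes)
    planted_idx = np.sort(rng.choice(n_genes, size=n_planted, replace=False))
    planted = [gene_ids[i] for i in planted_idx]

    cols: dict[str, np.ndarray] = {}
    sample_groups: dict[str, str] = {}
    for group, n_samples in groups.items():
        phi = np.full(n_genes, config.nb_dispersion_young)
        if group in inflate_groups:
            phi[planted_idx] = config.nb_dispersion_old
        for j in range(n_samples):
            sid = f"{group}_s{j + 1}"
            cols[sid] = _nb_draw(rng, means, phi)
            sample_groups[sid] = group
    counts = pd.DataFrame(cols, index=gene_ids)
    return CountSimulation(
        counts=counts,
        library_sizes=counts.sum(axis=0),
        sample_groups=sample_groups,
        planted_genes=planted,
        gene_means=pd.Series(means, index=gene_ids, name="true_mean"),
    )
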