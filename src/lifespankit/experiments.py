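"""Monte-Carlo calibration and recovery experiments.

These drive the package's self-checks: type-I-error calibration of the
survival tests under a null Gompertz simulator, Kaplan-Meier recovery of
the closed-form Gompertz median, power of the log-rank design at the
default (~20% median separation) effect, and recovery of planted
high-dispersion genes by the CV-ratio rule.

For the two discrete tests the exact attainable size at a given alpha is
also computed by enumeration (over the hypergeometric support of the
decile-membership table, and over the pair of binomial death counts for
the single-day chi-square), because discrete tests cannot reject at the
nominal rate: Fisher's exact test is conservative by construction. A
Monte-Carlo rejection rate is correctly calibrated when it matches the
exact size, not the nominal level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort, MouseRecord
from .expression import compare_cv, filter_by_mean, fpm_normalize
from .simulate import (
    SimulationConfig,
    gompertz_median_days,
    sample_gompertz,
    simulate_counts,
)
from .survival import (
    TieWarning,
    fisher_exact_2x2,
    kaplan_meier,
    logrank_test,
    max_lifespan_test,
    median_survival,
    pearson_chi2_2x2,
)

__all__ = [
    "CalibrationResult",
    "null_calibration",
    "decile_fisher_exact_size",
    "median_day_chi2_exact_size",
    "km_median_recovery",
    "logrank_power",
    "cv_recovery",
]


def _cohort_from_lifespans(days: np.ndarray, prefix: str) -> Cohort:
    return Cohort(
        [
            MouseRecord(mouse_id=f"{prefix}{i:04d}", genotype="wt", sex="female",
                        lifespan_days=int(d))
            for i, d in enumerate(days)
        ]
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Null rejection rates with the matching exact sizes where enumerable."""

    n_reps: int
    alpha: float
    logrank_rate: float
    decile_fisher_rate: float
    decile_fisher_exact_size: float
    median_day: int
    median_day_chi2_rate: float
    median_day_chi2_exact_size: float


def decile_fisher_exact_size(
    n_per_arm: int, k: int, alpha: float = 0.05
) -> float:
    """Exact size of the decile-membership Fisher test under the null.

    Membership of one arm in the pooled top-k set is hypergeometric with
    equal arms; the size is the null probability mass of tables whose
    two-sided Fisher p is <= alpha.
    """
    n = 2 * n_per_arm
    denom = math.comb(n, k)
    size = 0.0
    for x in range(max(0, k - n_per_arm), min(k, n_per_arm) + 1):
        p = fisher_exact_2x2(
            [[x, n_per_arm - x], [k - x, n_per_arm - (k - x)]]
        ).p_value
        if p <= alpha:
            size += math.comb(n_per_arm, x) * math.comb(n_per_arm, k - x) / denom
    return size


def _death_prob_by_day(config: SimulationConfig, day: int) -> float:
    """P(rounded Gompertz lifespan <= day) for the wild-type baseline."""
    a, b = config.gompertz_a, config.gompertz_b
    t = day + 0.5  # integer days arise by rounding the continuous lifetime
    return 1.0 - math.exp(-(a / b) * (math.exp(b * t) - 1.0))


def median_day_chi2_exact_size(
    config: SimulationConfig, day: int, alpha: float = 0.05
) -> float:
    """Exact size of the single-day Pearson chi-square under the null.

    Both arms' death counts by ``day`` are Binomial(n, F(day)); the size
    sums the joint pmf over count pairs whose chi-square p is <= alpha.
    """
    n = config.n_per_arm
    f = _death_prob_by_day(config, day)
    pk = stats.binom.pmf(np.arange(n + 1), n, f)
    size = 0.0
    for k1 in range(n + 1):
        for k2 in range(n + 1):
            if pearson_chi2_2x2(k1, n - k1, k2, n - k2)[1] <= alpha:
                size += pk[k1] * pk[k2]
    return float(size)


def null_calibration(
    config: SimulationConfig | None = None,
    n_reps: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Type-I calibration of log-rank, decile Fisher and the day chi-square.

    Two arms of ``n_per_arm`` Gompertz lifespans are drawn from identical
    parameters per replicate; each test's rejection rate at ``alpha`` is
    returned together with the enumerated exact size of the two discrete
    tests. The chi-square is evaluated at the day nearest the closed-form
    median (where both margins are informative).
    """
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(seed)
    n = config.n_per_arm
    day = int(round(gompertz_median_days(config.gompertz_a, config.gompertz_b)))

    rej_logrank = rej_fisher = rej_chi2 = 0
    for _ in range(n_reps):
        t_a = sample_gompertz(config, n, rng=rng)
        t_b = sample_gompertz(config, n, rng=rng)
        a = _cohort_from_lifespans(t_a, "a")
        b = _cohort_from_lifespans(t_b, "b")
        if logrank_test(a, b).p_value <= alpha:
            rej_logrank += 1
        with warnings.catch_warnings():
            # ties at the cutoff are routine with integer-day lifespans
            warnings.simplefilter("ignore", TieWarning)
            if max_lifespan_test(a, b).fisher.p_value <= alpha:
                rej_fisher += 1
        k1 = int(np.sum(t_a <= day))
        k2 = int(np.sum(t_b <= day))
        if pearson_chi2_2x2(k1, n - k1, k2, n - k2)[1] <= alpha:
            rej_chi2 += 1

    k = int(math.floor(0.10 * 2 * n))
    return CalibrationResult(
        n_reps=n_reps,
        alpha=alpha,
        logrank_rate=rej_logrank / n_reps,
        decile_fisher_rate=rej_fisher / n_reps,
        decile_fisher_exact_size=decile_fisher_exact_size(n, k, alpha),
        median_day=day,
        median_day_chi2_rate=rej_chi2 / n_reps,
        median_day_chi2_exact_size=median_day_chi2_exact_size(config, day, alpha),
    )


def km_median_recovery(
    config: SimulationConfig | None = None, n: int = 100_000, seed: int = 0
) -> dict:
    """Relative error (%) of the KM median of n Gompertz samples vs closed form."""
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(seed)
    days = sample_gompertz(config, n, rng=rng)
    km_med = median_survival(kaplan_meier(_cohort_from_lifespans(days, "m")))
    closed = gompertz_median_days(config.gompertz_a, config.gompertz_b)
    return {
        "n": n,
        "km_median_days": km_med,
        "closed_form_days": closed,
        "relative_error_percent": 100.0 * abs(km_med - closed) / closed,
    }


def logrank_power(
    config: SimulationConfig | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Power of the log-rank test at the configured mutant hazard ratio."""
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(seed)
    n = config.n_per_arm
    rej = 0
    for _ in range(n_reps):
        t_a = sample_gompertz(config, n, rng=rng)
        t_b = sample_gompertz(config, n, rng=rng,
                              hazard_scale=config.hazard_ratio_mutant)
        a = _cohort_from_lifespans(t_a, "a")
        b = _cohort_from_lifespans(t_b, "b")
        if logrank_test(a, b).p_value <= alpha:
            rej += 1
    med_wt = gompertz_median_days(config.gompertz_a, config.gompertz_b)
    med_mu = gompertz_median_days(
        config.gompertz_a * config.hazard_ratio_mutant, config.gompertz_b
    )
    return {
        "n_reps": n_reps,
        "n_per_arm": n,
        "median_separation_percent": 100.0 * (med_mu - med_wt) / med_wt,
        "power": rej / n_reps,
    }


def cv_recovery(
    config: SimulationConfig | None = None,
    n_genes: int = 300,
    seed: int = 0,
    mean_range: tuple[float, float] = (50.0, 5000.0),
    ratio_threshold: float = 2.0,
) -> dict:
    """Recovery of planted high-dispersion genes by the CV-ratio rule.

    Simulates a young/old two-group design (n = ``samples_per_group``
    each) where the planted genes carry ``nb_dispersion_old`` (six times
    the young value under the defaults) in the old group, FPM-normalises,
    filters at 1 FPM, and selects genes with old CV > threshold x young
    CV. Returns sensitivity on the planted set and the false-discovery
    proportion of the selection.
    """
    config = SimulationConfig() if config is None else config
    config = SimulationConfig(**{**config.to_dict(),
                                 "nb_mean_range": tuple(mean_range)})
    rng = np.random.default_rng(seed)
    sim = simulate_counts(
        config,
        n_genes=n_genes,
        groups={"young": config.samples_per_group, "old": config.samples_per_group},
        old_groups={"old"},
        rng=rng,
    )
    mat = filter_by_mean(
        fpm_normalize(sim.counts, sim.library_sizes, sim.sample_groups), 1.0
    )
    comp = compare_cv(mat, "young", "old", ratio_threshold=ratio_threshold)
    selected = comp.highvar_in_2  # higher CV in the old group
    planted = set(sim.planted_genes) & set(mat.gene_ids)
    tp = len(selected & planted)
    fp = len(selected - planted)
    return {
        "n_genes": n_genes,
        "n_planted": len(planted),
        "n_selected": len(selected),
        "sensitivity": tp / len(planted) if planted else math.nan,
        "false_discovery_proportion": fp / len(selected) if selected else 0.0,
        "dispersion_inflation": config.nb_dispersion_old / config.nb_dispersion_young,
        "samples_per_group": config.samples_per_group,
    }
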