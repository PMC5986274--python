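import math
from fractions import Fraction

import numpy as np
import pytest

from lifespankit.cohort import Cohort, MouseRecord, TumourFinding


def make_cohort(lifespans, prefix="m", genotype="wt", sex="female",
                events=None, ud=None, necropsy=None, findings=None,
                label=""):
    """Build a cohort from plain lifespan lists for tests."""
    n = len(lifespans)
    events = [True] * n if events is None else events
    ud = [False] * n if ud is None else ud
    necropsy = [True] * n if necropsy is None else necropsy
    findings = [()] * n if findings is None else findings
    findings = [
        tuple(
            f if isinstance(f, TumourFinding) else TumourFinding(*f)
            for f in per_mouse
        )
        for per_mouse in findings
    ]
    return Cohort(
        [
            MouseRecord(
                mouse_id=f"{prefix}{i:03d}",
                genotype=genotype,
                sex=sex,
                lifespan_days=int(lifespans[i]),
                event_observed=bool(events[i]),
                ud_case=bool(ud[i]),
                necropsy_performed=bool(necropsy[i]),
                tumour_findings=tuple(findings[i]),
            )
            for i in range(n)
        ],
        label,
    )


def fisher_two_sided_oracle(a, b, c, d):
    """Exact-rational enumeration of the minimum-likelihood two-sided p."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {
        x: Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs))


def hypergeom_upper_tail_oracle(overlap, universe, term, query):
    """Exact-rational P(X >= overlap) for X hypergeometric."""
    denom = math.comb(universe, query)
    total = Fraction(0)
    for k in range(overlap, min(term, query) + 1):
        total += Fraction(
            math.comb(term, k) * math.comb(universe - term, query - k), denom
        )
    return float(min(total, Fraction(1)))


def bh_oracle(pvals):
    """Hand Benjamini-Hochberg: q_i = min_{j>=i} (m * p_(j) / j), capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = running
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tumour_mouse():
    def make(findings, mouse_id="t000"):
        return MouseRecord(
            mouse_id=mouse_id,
            genotype="wt",
            sex="female",
            lifespan_days=700,
            tumour_findings=tuple(TumourFinding(t, o) for t, o in findings),
        )

    return make
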