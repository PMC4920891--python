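import numpy as np
import pandas as pd
import pytest

from asreg import calling, normalization as norm, synth


@pytest.fixture(scope="session")
def small_panel():
    return synth.generate_gene_panel(10, 10, 5, seed=42)


@pytest.fixture(scope="session")
def screen_sc(small_panel):
    """One-condition screen with planted 2-fold effects on 6 genes."""
    params = synth.SimParams(conditions=("SC",), seed=42, frac_regulated=0.25,
                             onoff_fraction=0.0)
    cells, truth = synth.simulate_screen(small_panel, params)
    return cells, truth, params


@pytest.fixture(scope="session")
def called_screen(screen_sc):
    """Normalization + caller output for the small planted screen."""
    cells, truth, params = screen_sc
    wells = norm.normalize_wells(cells)
    theta = norm.null_reference_threshold(cells, seed=42)
    qc = norm.qc_filter(wells, theta=theta)
    expr = norm.expression_calls(qc.passing(), theta)
    calls = calling.call_screen(qc.passing(), expr, theta)
    return {"wells": qc.passing(), "theta": theta, "expr": expr,
            "calls": calls, "truth": truth}


def brute_force_category(gene):
    """Interval-overlap oracle for the TSS-overlap classification."""
    if gene.as_start is None:
        return "NO_AS"
    covered = any(
        pos == gene.sense_tss for pos in range(gene.as_start, gene.as_end)
    )
    return "TSS_OVERLAP" if covered else "NO_TSS_OVERLAP"


def exact_ranksum_p(x, y):
    """Full-enumeration two-sided rank-sum p (no ties expected)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    obs = ranks[:n1].sum()
    sums = np.array([sum(c) for c in combinations(ranks, n1)])
    mean = sums.mean()
    return np.mean(np.abs(sums - mean) >= abs(obs - mean) - 1e-9)


def enumerate_fisher_p(table):
    """Hypergeometric enumeration oracle for the two-sided Fisher test."""
    from math import comb

    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
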