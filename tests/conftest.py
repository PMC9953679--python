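import numpy as np
import pandas as pd
import pytest

from capmort import (
    CohortConfig,
    ExpressionConfig,
    generate_cohort,
    generate_expression,
    generate_survival,
)


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample cohort with exactly 10 deaths, 3 batches."""
    return generate_cohort(
        CohortConfig(n_samples=60, exact_deaths=10, n_batches=3, seed=11)
    )


@pytest.fixture(scope="session")
def small_expression(small_cohort):
    """300-gene matrix with 20 planted DE genes (effect 1.5, sd 0.5)."""
    matrix, truth = generate_expression(
        small_cohort,
        ExpressionConfig(
            n_genes=300, n_de=20, effect_size=1.5, gene_sd=0.5, batch_sd=0.2, seed=12
        ),
    )
    return matrix, truth


@pytest.fixture(scope="session")
def small_survival(small_cohort):
    return generate_survival(small_cohort, max_follow_days=30.0, seed=13)


def naive_enrichment_walk(ranked_genes, metric_values, gene_set, weight_p):
    """Independent brute-force running-sum oracle for the enrichment score.

    Walks the ranked list one gene at a time, recomputing the hit/miss
    increments from first principles.
    """
    gene_set = set(gene_set)
    n = len(ranked_genes)
    n_hit = sum(1 for g in ranked_genes if g in gene_set)
    assert 0 < n_hit < n
    n_r = sum(
        abs(m) ** weight_p if weight_p else 1.0
        for g, m in zip(ranked_genes, metric_values)
        if g in gene_set
    )
    if n_r == 0:
        n_r = float(n_hit)
        weights = {g: 1.0 for g in ranked_genes if g in gene_set}
    else:
        weights = {
            g: (abs(m) ** weight_p if weight_p else 1.0)
            for g, m in zip(ranked_genes, metric_values)
            if g in gene_set
        }
    running = []
    total = 0.0
    for g in ranked_genes:
        if g in gene_set:
            total += weights[g] / n_r
        else:
            total -= 1.0 / (n - n_hit)
        running.append(total)
    best = max(running, key=abs)
    return best, running
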