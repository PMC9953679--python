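"""Synthetic CAP cohort, expression-matrix, and survival-time generation.

The generator emulates the structure of a whole-blood microarray mortality
study: a hospitalized cohort with a small death fraction (defaults: 198
arrays, 13 deaths), ~20k gene-level log2 expression features with batch
structure, a configurable set of truly differentially expressed (DE) genes,
and in-hospital survival times with discharge censoring.  Ground-truth DE
labels are returned alongside the matrix so recovery can be tested.

Expression is generated directly on the log2 (RMA output) scale:

    x_gs = baseline_g + batch_offset_{g,b(s)} + died_s * delta_g + eps_gs

with ``delta_g = sign_g * effect_size`` for DE genes (0 otherwise),
``eps ~ N(0, gene_sd^2)``, and additive per-(gene, batch) Gaussian offsets
with standard deviation ``batch_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "ExpressionConfig",
    "generate_cohort",
    "generate_expression",
    "generate_survival",
    "write_tsv",
]

DIED = "died"
SURVIVED = "survived"

#: Clinical covariate marginals of the default cohort (hospitalized CAP):
#: septic shock 7.5%, PSI high-risk classes IV-V 64%, age median 75 y.
DEFAULT_COVARIATE_MARGINALS = {
    "septic_shock": 0.075,
    "psi_high_risk": 0.64,
    "age_median": 75.0,
    "age_iqr": (62.5, 84.0),
}


@dataclass
class CohortConfig:
    """Configuration of a synthetic hospitalized cohort.

    Defaults mirror a processed whole-blood CAP cohort: 198 arrays of
    which 13 came from patients who died in hospital.
    """

    n_samples: int = 198
    mortality_rate: float = 13.0 / 198.0
    n_batches: int = 4
    seed: int = 0
    #: fix the death count exactly instead of Binomial(n, rate) sampling
    exact_deaths: int | None = None
    #: 'random' or 'round_robin' batch assignment
    batch_assignment: str = "round_robin"
    covariate_marginals: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINALS)
    )

    def validate(self) -> None:
        if not 0.0 <= self.mortality_rate <= 1.0:
            raise ValueError(
                f"mortality_rate must be in [0, 1], got {self.mortality_rate}"
            )
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.n_samples < self.n_batches:
            raise ValueError("n_samples must be >= n_batches")
        if self.exact_deaths is not None and not (
            0 <= self.exact_deaths <= self.n_samples
        ):
            raise ValueError("exact_deaths must be in [0, n_samples]")


@dataclass
class ExpressionConfig:
    """Configuration of the synthetic log2 expression matrix."""

    n_genes: int = 20893
    n_de: int = 0
    effect_size: float = 1.0  # mean log2 died-vs-survived difference
    gene_sd: float = 0.5  # within-group residual SD (log2)
    batch_sd: float = 0.0  # SD of additive per-(gene, batch) offsets (log2)
    #: probability a DE gene is up-regulated in the died group
    prob_up: float = 0.75
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_de <= self.n_genes:
            raise ValueError("n_de must satisfy 0 <= n_de <= n_genes")
        if self.gene_sd <= 0:
            raise ValueError("gene_sd must be > 0")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")
        if not 0.0 <= self.prob_up <= 1.0:
            raise ValueError("prob_up must be in [0, 1]")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a per-sample annotation table.

    Returns a DataFrame indexed by sample ID with columns ``outcome``
    ('died'/'survived'), ``batch``, clinical covariates (``age``,
    ``septic_shock``, ``psi_high_risk``) and empty survival fields
    (``time_days``, ``event``) to be filled by :func:`generate_survival`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    if config.exact_deaths is not None:
        outcome = np.array([SURVIVED] * n, dtype=object)
        died_idx = rng.choice(n, size=config.exact_deaths, replace=False)
        outcome[died_idx] = DIED
    else:
        outcome = np.where(
            rng.random(n) < config.mortality_rate, DIED, SURVIVED
        ).astype(object)

    if config.batch_assignment == "round_robin":
        batch = np.arange(n) % config.n_batches + 1
    elif config.batch_assignment == "random":
        batch = rng.integers(1, config.n_batches + 1, size=n)
    else:
        raise ValueError(f"unknown batch_assignment {config.batch_assignment!r}")

    marg = config.covariate_marginals
    q25, q75 = marg["age_iqr"]
    # Normal with matching median and IQR, clipped to adult range.
    age_sd = (q75 - q25) / 1.349
    age = np.clip(rng.normal(marg["age_median"], age_sd, size=n), 18, 105)

    ann = pd.DataFrame(
        {
            "outcome": outcome,
            "batch": batch,
            "age": np.round(age, 1),
            "septic_shock": rng.random(n) < marg["septic_shock"],
            "psi_high_risk": rng.random(n) < marg["psi_high_risk"],
            "time_days": np.nan,
            "event": np.nan,
        },
        index=pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id"),
    )
    return ann


def generate_expression(
    annotation: pd.DataFrame, config: ExpressionConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a genes x samples log2 matrix plus its ground-truth table.

    Returns ``(matrix, truth)``; truth has one row per gene with columns
    ``is_de`` (bool), ``true_effect`` (signed log2 shift in the died group)
    and ``direction`` (+1/-1/0).
    """
    config.validate()
    if annotation.empty:
        raise ValueError("annotation must be non-empty")
    outcome = annotation["outcome"].to_numpy()
    if config.n_de > 0 and len(np.unique(outcome)) < 2:
        raise ValueError("both outcome levels required when n_de > 0")

    rng = np.random.default_rng(config.seed)
    g, n = config.n_genes, len(annotation)

    genes = pd.Index([f"G{i + 1:05d}" for i in range(g)], name="gene")
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=g)

    de_idx = rng.choice(g, size=config.n_de, replace=False)
    sign = np.zeros(g)
    sign[de_idx] = np.where(rng.random(config.n_de) < config.prob_up, 1.0, -1.0)
    effect = sign * config.effect_size

    died = (outcome == DIED).astype(float)
    x = baseline[:, None] + effect[:, None] * died[None, :]

    if config.batch_sd > 0:
        batches = annotation["batch"].to_numpy()
        levels = np.unique(batches)
        offsets = rng.normal(0.0, config.batch_sd, size=(g, len(levels)))
        col_of = {b: j for j, b in enumerate(levels)}
        x = x + offsets[:, [col_of[b] for b in batches]]

    x = x + rng.normal(0.0, config.gene_sd, size=(g, n))

    matrix = pd.DataFrame(x, index=genes, columns=annotation.index)
    truth = pd.DataFrame(
        {
            "is_de": sign != 0,
            "true_effect": effect,
            "direction": np.sign(effect).astype(int),
        },
        index=genes,
    )
    return matrix, truth


def generate_survival(
    annotation: pd.DataFrame,
    max_follow_days: float = 30.0,
    seed: int = 0,
    *,
    mean_event_day: float = 10.0,
    mean_discharge_day: float = 9.0,
    hazard_gene: str | None = None,
    hazard_coef: float = 0.0,
    expression: pd.DataFrame | None = None,
    base_event_rate: float | None = None,
) -> pd.DataFrame:
    """Fill in in-hospital survival times (days) and event flags.

    Without a hazard link, samples with outcome 'died' receive ``event=1``
    and an event time drawn from an exponential distribution (mean
    ``mean_event_day``) truncated at ``max_follow_days``; survivors are
    censored at a discharge time (exponential, mean ``mean_discharge_day``)
    capped at ``max_follow_days``.

    With ``hazard_gene`` set, times come from a proportional-hazards
    simulation: each sample's hazard is ``r0 * exp(hazard_coef * z)`` where
    ``z`` is the standardized expression of the gene; latent times beyond
    ``max_follow_days`` are censored there.  The ``outcome`` and ``event``
    columns are re-derived from the simulated events in this mode, so the
    event pattern is consistent with the planted expression effect.
    """
    if max_follow_days <= 0:
        raise ValueError("max_follow_days must be > 0")
    if "outcome" not in annotation.columns:
        raise ValueError("outcome must be assigned before generate_survival")

    rng = np.random.default_rng(seed)
    ann = annotation.copy()
    n = len(ann)

    if hazard_gene is not None:
        if expression is None:
            raise ValueError("expression matrix required for hazard link")
        expr = expression.loc[hazard_gene, ann.index].to_numpy(dtype=float)
        z = (expr - expr.mean()) / expr.std(ddof=0)
        if base_event_rate is None:
            base_event_rate = (ann["outcome"] == DIED).mean() or 0.05
        # r0 such that baseline (z=0) event probability over follow-up
        # approximates base_event_rate.
        r0 = -np.log(max(1.0 - base_event_rate, 1e-12)) / max_follow_days
        rate = r0 * np.exp(hazard_coef * z)
        latent = rng.exponential(1.0 / rate)
        event = (latent <= max_follow_days).astype(int)
        time = np.minimum(latent, max_follow_days)
        ann["outcome"] = np.where(event == 1, DIED, SURVIVED)
        ann["time_days"] = np.round(time, 3)
        ann["event"] = event
        return ann

    died = (ann["outcome"] == DIED).to_numpy()
    time = np.empty(n)
    # truncated exponential: inverse-CDF sampling within [0, max_follow]
    u = rng.random(n)
    cap = 1.0 - np.exp(-max_follow_days / mean_event_day)
    time[died] = -mean_event_day * np.log(1.0 - u[died] * cap)
    discharge = rng.exponential(mean_discharge_day, size=n)
    time[~died] = np.minimum(discharge[~died], max_follow_days)
    ann["time_days"] = np.round(np.maximum(time, 0.01), 3)
    ann["event"] = died.astype(int)
    return ann


def generate_gene_sets(
    genes,
    n_sets: int = 50,
    set_size: tuple[int, int] = (15, 60),
    seed: int = 0,
    planted: list[str] | None = None,
    planted_name: str = "HALLMARK_SYNTH_PLANTED",
):
    """Random Hallmark-style gene-set collection over a gene universe.

    Draws ``n_sets`` sets of uniformly random size in ``set_size`` from
    ``genes``; if ``planted`` is given, it replaces the first set under
    ``planted_name`` (for signal-recovery tests).  Returns a
    :class:`capmort.gsea.GeneSetCollection`.
    """
    from capmort.gsea import GeneSetCollection

    rng = np.random.default_rng(seed)
    genes = list(genes)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        k = int(rng.integers(set_size[0], set_size[1] + 1))
        members = list(rng.choice(genes, size=min(k, len(genes)), replace=False))
        sets[f"HALLMARK_SYNTH_{i + 1:03d}"] = members
    if planted is not None:
        first = next(iter(sets))
        del sets[first]
        sets = {planted_name: list(planted), **sets}
    return GeneSetCollection(sets)


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a table as TSV (index as first column)."""
    df.to_csv(path, sep="\t", index=True, index_label=index_label)
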