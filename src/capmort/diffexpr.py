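"""Moderated linear-model differential expression with subsampling stability selection.

The "double strategy" for calling mortality-associated genes from a
genes x samples log2 matrix:

1. An empirical-Bayes moderated t-test per gene: ordinary least squares on
   a design with intercept, outcome indicator (died = 1) and batch
   indicator columns; per-gene residual variances are shrunk toward a
   common prior estimated by moment matching on the scaled-F distribution
   of the sample variances, and the t-statistic gains the prior degrees of
   freedom.

2. Stability selection: the same moderated model is refitted on many
   (default 1000) random outcome-balanced subsamples, each covering a
   fraction of the cohort drawn uniformly from [0.55, 0.77], and each gene
   is scored by how often its p-value falls below a per-model threshold.

Genes are finally gated on both the full-data p-value and the selection
count ("top differentially expressed").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "build_design",
    "ModeratedDEModel",
    "ModeratedDEResults",
    "SubsamplingConfig",
    "signed_fold_change",
    "stability_selection",
    "select_top_genes",
]


def build_design(
    annotation: pd.DataFrame,
    batch: bool = True,
    outcome_col: str = "outcome",
    died_label: str = "died",
    batch_col: str = "batch",
) -> pd.DataFrame:
    """Samples x covariates design: intercept, outcome (died=1), batch one-hot.

    The first batch level is the reference; batch levels constant within
    the supplied annotation produce no column (relevant for subsamples).
    """
    cols = {"intercept": np.ones(len(annotation))}
    cols["outcome"] = (annotation[outcome_col] == died_label).astype(float).to_numpy()
    if batch and batch_col in annotation.columns:
        levels = sorted(pd.unique(annotation[batch_col]))
        for lev in levels[1:]:
            cols[f"batch_{lev}"] = (annotation[batch_col] == lev).astype(float).to_numpy()
    design = pd.DataFrame(cols, index=annotation.index)
    return design


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to sample variances.

    Assuming ``s2 ~ s0^2 * F(df, df0)``, estimates the prior variance
    ``s0^2`` and prior degrees of freedom ``df0`` from the mean and
    variance of ``log s2`` (genes with zero variance are excluded by the
    caller).  Returns ``(s2_prior, df_prior)``; ``df_prior`` may be inf.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return (float(s2.mean()) if s2.size else 1.0, np.inf)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        df0 = 2.0 * _trigamma_inverse(evar)
        s20 = np.exp(emean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0))
    else:
        df0 = np.inf
        s20 = np.exp(emean)
    return float(s20), float(df0)


def signed_fold_change(log2_effect):
    """Signed linear fold change from a log2 effect.

    Maps x >= 0 to 2**x and x < 0 to -(2**-x), so magnitudes are always
    >= 1 and the sign encodes direction (the convention of reported
    DE tables).
    """
    x = np.asarray(log2_effect, dtype=float)
    fc = np.where(x >= 0, np.exp2(x), -np.exp2(-x))
    return float(fc) if np.isscalar(log2_effect) or x.ndim == 0 else fc


class ModeratedDEResults:
    """Per-gene moderated differential-expression estimates.

    Attributes
    ----------
    effect : pandas.Series
        Fitted log2 outcome effect (died minus survived) per gene.
    t, p_value : pandas.Series
        Moderated t-statistic and its two-sided p-value.
    sigma2, s2_post : pandas.Series
        Residual and posterior (shrunk) variances.
    df_residual, df_prior, s2_prior : float
        Residual df of the fit and the empirical-Bayes hyperparameters.
    zero_variance : pandas.Series of bool
        Genes whose residual variance is exactly zero; their p-value is
        set to 1 by convention.
    """

    def __init__(self, model, effect, sigma2, s2_post, t, p_value,
                 df_residual, df_prior, s2_prior, zero_variance):
        self.model = model
        self.effect = effect
        self.sigma2 = sigma2
        self.s2_post = s2_post
        self.t = t
        self.p_value = p_value
        self.df_residual = df_residual
        self.df_prior = df_prior
        self.s2_prior = s2_prior
        self.zero_variance = zero_variance

    @property
    def fold_change(self) -> pd.Series:
        return pd.Series(
            signed_fold_change(self.effect.to_numpy()),
            index=self.effect.index, name="FoldChange",
        )

    def summary(self, sort: bool = True) -> pd.DataFrame:
        """Per-gene table: Symbol, log2 effect, t, p-Value, FoldChange."""
        out = pd.DataFrame(
            {
                "Symbol": self.effect.index,
                "log2_effect": self.effect.to_numpy(),
                "t": self.t.to_numpy(),
                "p-Value": self.p_value.to_numpy(),
                "FoldChange": self.fold_change.to_numpy(),
            }
        ).set_index("Symbol")
        if sort:
            out = out.sort_values("p-Value", kind="stable")
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ModeratedDEResults: {len(self.effect)} genes, "
            f"df_residual={self.df_residual:g}, df_prior={self.df_prior:g}>"
        )


class ModeratedDEModel:
    """Moderated linear model for a genes x samples log2 expression matrix.

    Parameters
    ----------
    matrix
        Genes x samples DataFrame of log2 expression.
    design
        Samples x covariates DataFrame (see :func:`build_design`); must be
        full column rank and row-aligned with ``matrix`` columns.
    coef
        Name of the design column whose effect is tested (default
        'outcome').
    """

    def __init__(self, matrix: pd.DataFrame, design: pd.DataFrame, coef: str = "outcome"):
        if list(matrix.columns) != list(design.index):
            design = design.reindex(matrix.columns)
            if design.isna().any().any():
                raise ValueError("design rows do not align with matrix samples")
        x = design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if x.shape[0] - x.shape[1] < 1:
            raise ValueError("residual degrees of freedom < 1")
        if coef not in design.columns:
            raise ValueError(f"coefficient {coef!r} not in design")
        self.matrix = matrix
        self.design = design
        self.coef = coef

    @classmethod
    def from_annotation(
        cls, matrix: pd.DataFrame, annotation: pd.DataFrame, batch: bool = True
    ) -> "ModeratedDEModel":
        design = build_design(annotation.loc[matrix.columns], batch=batch)
        return cls(matrix, design)

    def fit(self, prior_df: float | None = None) -> ModeratedDEResults:
        """OLS per gene, then empirical-Bayes variance moderation.

        ``prior_df=None`` estimates the prior df and variance by moment
        matching; ``prior_df=0`` disables shrinkage (ordinary t);
        ``prior_df=inf`` replaces every variance by the prior variance.
        """
        x = self.design.to_numpy(dtype=float)
        y = self.matrix.to_numpy(dtype=float).T  # samples x genes
        n, k = x.shape
        df_resid = n - k

        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ y  # k x G
        resid = y - x @ beta
        sigma2 = (resid**2).sum(axis=0) / df_resid

        j = list(self.design.columns).index(self.coef)
        effect = beta[j]
        su = np.sqrt(xtx_inv[j, j])  # unscaled stderr

        # residual variance indistinguishable from zero at double precision
        zero_var = sigma2 <= 1e-13 * np.maximum(1.0, (y**2).mean(axis=0))
        if prior_df is None:
            s2_prior, df_prior = fit_f_dist(sigma2[~zero_var], df_resid)
        else:
            df_prior = float(prior_df)
            s2_valid = sigma2[~zero_var]
            if s2_valid.size:
                z = np.log(s2_valid)
                s2_prior = float(
                    np.exp(z.mean() - special.digamma(df_resid / 2.0)
                           + np.log(df_resid / 2.0))
                )
            else:
                s2_prior = 1.0

        if np.isinf(df_prior):
            s2_post = np.full_like(sigma2, s2_prior)
            df_total = np.inf
        elif df_prior == 0:
            s2_post = sigma2.copy()
            df_total = float(df_resid)
        else:
            s2_post = (df_prior * s2_prior + df_resid * sigma2) / (df_prior + df_resid)
            df_total = df_resid + df_prior

        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / (su * np.sqrt(s2_post))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_total)

        t = np.where(zero_var & (s2_post <= 0), 0.0, t)
        p = np.where(zero_var, 1.0, p)

        genes = self.matrix.index
        return ModeratedDEResults(
            model=self,
            effect=pd.Series(effect, index=genes, name="log2_effect"),
            sigma2=pd.Series(sigma2, index=genes, name="sigma2"),
            s2_post=pd.Series(s2_post, index=genes, name="s2_post"),
            t=pd.Series(t, index=genes, name="t"),
            p_value=pd.Series(p, index=genes, name="p_value"),
            df_residual=float(df_resid),
            df_prior=float(df_prior),
            s2_prior=float(s2_prior),
            zero_variance=pd.Series(zero_var, index=genes, name="zero_variance"),
        )


@dataclass
class SubsamplingConfig:
    """Stability-selection settings: 1000 outcome-balanced subsamples each
    covering a uniformly drawn 55-77% of the cohort, selection at p < 0.05."""

    n_iter: int = 1000
    frac_min: float = 0.55
    frac_max: float = 0.77
    alpha: float = 0.05
    #: 'balanced' preserves the cohort's died:survived ratio (each group
    #: subsampled at the same fraction); 'equalized' takes the same
    #: absolute count from each group.
    strategy: str = "balanced"
    batch: bool = True
    prior_df: float | None = None
    seed: int = 0
    max_redraws: int = 100

    def validate(self) -> None:
        if not 0.0 < self.frac_min <= self.frac_max <= 1.0:
            raise ValueError("need 0 < frac_min <= frac_max <= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if self.strategy not in ("balanced", "equalized"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def _draw_subsample(rng, died_idx, surv_idx, cfg: SubsamplingConfig):
    frac = rng.uniform(cfg.frac_min, cfg.frac_max)
    if cfg.strategy == "balanced":
        n_d = int(round(frac * died_idx.size))
        n_s = int(round(frac * surv_idx.size))
    else:
        m = int(round(frac * min(died_idx.size, surv_idx.size)))
        n_d = n_s = m
    if n_d < 2 or n_s < 2:
        return None
    take_d = rng.choice(died_idx, size=n_d, replace=False)
    take_s = rng.choice(surv_idx, size=n_s, replace=False)
    return np.sort(np.concatenate([take_d, take_s]))


def stability_selection(
    matrix: pd.DataFrame, annotation: pd.DataFrame, config: SubsamplingConfig
) -> pd.Series:
    """Per-gene count of subsample models calling the gene at p < alpha.

    Each iteration draws an outcome-stratified subsample (fraction uniform
    in [frac_min, frac_max]), rebuilds the design with the batch covariate
    restricted to levels present in the subsample, refits the moderated
    model, and increments the count of every gene with p < alpha.
    Degenerate subsamples (an outcome group below 2) are redrawn, up to
    ``max_redraws`` times per iteration.
    """
    config.validate()
    ann = annotation.loc[matrix.columns]
    outcome = ann["outcome"].to_numpy()
    died_idx = np.flatnonzero(outcome == "died")
    surv_idx = np.flatnonzero(outcome != "died")
    if died_idx.size < 2 or surv_idx.size < 2:
        raise ValueError("both outcome groups need >= 2 samples")

    rng = np.random.default_rng(config.seed)
    counts = np.zeros(matrix.shape[0], dtype=int)
    for _ in range(config.n_iter):
        sub = None
        for _ in range(config.max_redraws):
            sub = _draw_subsample(rng, died_idx, surv_idx, config)
            if sub is not None:
                break
        if sub is None:
            raise ValueError(
                "could not draw a subsample with >= 2 samples per group"
            )
        sub_ann = ann.iloc[sub]
        sub_mat = matrix.iloc[:, sub]
        model = ModeratedDEModel.from_annotation(sub_mat, sub_ann, batch=config.batch)
        res = model.fit(prior_df=config.prior_df)
        counts += (res.p_value.to_numpy() < config.alpha).astype(int)
    return pd.Series(counts, index=matrix.index, name="Resampling_N")


def select_top_genes(
    records: pd.DataFrame,
    p_threshold: float = 0.05,
    min_count: int = 250,
) -> pd.DataFrame:
    """Gate genes on full-data p-value and selection count; sort by p.

    ``records`` must have columns ``p-Value`` and ``Resampling_N`` (and
    typically ``FoldChange``), indexed by gene symbol.  Returns the
    subset with p < ``p_threshold`` and count >= ``min_count``,
    ascending by p-value.
    """
    keep = (records["p-Value"] < p_threshold) & (records["Resampling_N"] >= min_count)
    return records.loc[keep].sort_values("p-Value", kind="stable")
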