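"""Gene set enrichment analysis: weighted running-sum ES, permutation NES/p/FDR.

Given a genes x samples matrix and a two-level phenotype (died vs
survived), genes are ranked by a correlation metric (signal-to-noise by
default); each gene set's enrichment score (ES) is the maximal deviation
of a weighted Kolmogorov-Smirnov-style running sum over the ranked list.
Significance comes from a permutation null (phenotype label permutation by
default, size-matched random gene sets as a fallback for small groups):
the normalized enrichment score (NES) divides ES by the mean same-sign
null ES, the nominal p-value is the same-sign tail fraction, and the FDR
q-value compares tail fractions of the pooled normalized null against the
observed NES values.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "rank_genes",
    "enrichment_score",
    "gsea_run",
    "filter_significant",
]


class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, optional descriptions."""

    def __init__(self, sets: dict[str, list[str]], descriptions: dict[str, str] | None = None):
        self.sets = {name: list(dict.fromkeys(genes)) for name, genes in sets.items()}
        self.descriptions = descriptions or {}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with the expression universe; drop empty sets."""
        uni = set(universe)
        kept = {
            name: [g for g in genes if g in uni]
            for name, genes in self.sets.items()
        }
        kept = {k: v for k, v in kept.items() if v}
        return GeneSetCollection(kept, self.descriptions)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, member genes...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def _metric_values(x: np.ndarray, in_group1: np.ndarray, metric: str) -> np.ndarray:
    g1 = x[:, in_group1]
    g2 = x[:, ~in_group1]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    if metric == "signal_to_noise":
        s1, s2 = g1.std(axis=1, ddof=1), g2.std(axis=1, ddof=1)
        # GSEA convention: floor each SD at 0.2*|mean| (0.2 if mean is 0)
        s1 = np.maximum(s1, np.where(m1 != 0, 0.2 * np.abs(m1), 0.2))
        s2 = np.maximum(s2, np.where(m2 != 0, 0.2 * np.abs(m2), 0.2))
        return (m1 - m2) / (s1 + s2)
    elif metric == "t_stat":
        v1 = g1.var(axis=1, ddof=1) / g1.shape[1]
        v2 = g2.var(axis=1, ddof=1) / g2.shape[1]
        denom = np.sqrt(v1 + v2)
        denom = np.where(denom > 0, denom, 1e-12)
        return (m1 - m2) / denom
    raise ValueError(f"unknown metric {metric!r}")


def rank_genes(
    matrix: pd.DataFrame,
    outcome,
    metric: str = "signal_to_noise",
    positive_label: str = "died",
) -> pd.Series:
    """Rank genes by a group-difference metric, descending.

    Positive values mean higher expression in ``positive_label`` samples.
    Ties break lexicographically by gene symbol for determinism.  Returns
    a Series (index = gene symbols in rank order, values = metric).
    """
    outcome = np.asarray(outcome)
    in1 = outcome == positive_label
    if in1.sum() < 2 or (~in1).sum() < 2:
        if metric == "signal_to_noise":
            raise ValueError(
                "signal_to_noise needs >= 2 samples per group; use metric='t_stat'"
            )
        raise ValueError("need >= 2 samples per group")
    vals = _metric_values(matrix.to_numpy(dtype=float), in1, metric)
    symbols = matrix.index.to_numpy(dtype=object)
    order = np.lexsort((symbols, -vals))
    return pd.Series(vals[order], index=pd.Index(symbols[order], name="gene"), name=metric)


def _es_walk(metric_abs: np.ndarray, hit: np.ndarray, weight_p: int) -> np.ndarray:
    """Full running sum over the ranked list (naive O(N) walk)."""
    n = metric_abs.size
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a non-empty proper subset of the universe")
    w = metric_abs**weight_p if weight_p else np.ones(n)
    inc = np.where(hit, w, 0.0)
    n_r = inc.sum()
    if n_r == 0:  # all hit metrics exactly zero under p=1
        inc = np.where(hit, 1.0, 0.0)
        n_r = inc.sum()
    step = inc / n_r - np.where(hit, 0.0, 1.0 / (n - n_hit))
    return np.cumsum(step)


def enrichment_score(
    ranked: pd.Series, gene_set, weight_p: int = 1
) -> tuple[float, np.ndarray, int]:
    """ES of one gene set against a ranked list.

    ``ranked`` is the output of :func:`rank_genes` (genes in rank order
    with metric values).  Hits increment the running sum by
    ``|metric|^p / N_R``; misses decrement by ``1/(N - N_hit)``.  Returns
    ``(ES, running_sum, peak_index)`` where ES is the running-sum value of
    maximal absolute deviation from zero.
    """
    genes = ranked.index.to_numpy(dtype=object)
    hit = np.isin(genes, list(gene_set))
    running = _es_walk(np.abs(ranked.to_numpy(dtype=float)), hit, weight_p)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


def _es_batch(metric: np.ndarray, symbols: np.ndarray, set_indices: list[np.ndarray],
              weight_p: int, rng=None, lexsort: bool = False) -> np.ndarray:
    """ES for many sets against one metric vector (positions-only, fast).

    ``set_indices`` holds integer gene positions (into ``symbols``) per set.
    """
    if lexsort:
        order = np.lexsort((symbols, -metric))
    else:
        order = np.argsort(-metric, kind="stable")
    rank_of = np.empty(metric.size, dtype=np.int64)
    rank_of[order] = np.arange(metric.size)
    m_abs = np.abs(metric[order])
    w_all = m_abs**weight_p if weight_p else np.ones(metric.size)
    n = metric.size

    out = np.empty(len(set_indices))
    for si, idx in enumerate(set_indices):
        pos = np.sort(rank_of[idx])
        k = pos.size
        w = w_all[pos]
        n_r = w.sum()
        if n_r == 0:
            w = np.ones(k)
            n_r = float(k)
        hit_cum = np.cumsum(w) / n_r
        d = 1.0 / (n - k)
        i = np.arange(k)
        after = hit_cum - (pos - i) * d  # running sum just after each hit
        before = np.concatenate(([0.0], hit_cum[:-1])) - (pos - i) * d
        hi = after.max()
        lo = min(before.min(), 0.0)
        out[si] = hi if hi >= -lo else lo
    return out


def gsea_run(
    matrix: pd.DataFrame,
    outcome,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    perm_type: str = "phenotype",
    seed: int = 0,
    metric: str = "signal_to_noise",
    weight_p: int = 1,
    positive_label: str = "died",
    min_group_warn: int = 7,
) -> pd.DataFrame:
    """Run GSEA over a collection; returns a per-set results table.

    Output DataFrame (index = set name): ``size``, ``ES``, ``NES``,
    ``nom_p``, ``fdr_q``, ``sign`` ('positive'/'negative').  Nominal
    p-values carry an add-one correction and are floored at
    ``1/(n_perm+1)``; q-values are clipped to [0, 1] and made monotone
    non-increasing in |NES| within each sign class.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    outcome = np.asarray(outcome)
    in1 = outcome == positive_label
    if perm_type == "phenotype" and min(in1.sum(), (~in1).sum()) < min_group_warn:
        warnings.warn(
            f"a phenotype group has fewer than {min_group_warn} samples; "
            "consider perm_type='gene_set'",
            UserWarning,
            stacklevel=2,
        )

    collection = collection.restrict(matrix.index)
    if len(collection) == 0:
        raise ValueError("no gene set overlaps the expression universe")
    names = list(collection)
    symbols = matrix.index.to_numpy(dtype=object)
    gene_pos = {g: i for i, g in enumerate(symbols)}
    set_indices = [
        np.array([gene_pos[g] for g in collection[nm]], dtype=np.int64)
        for nm in names
    ]

    x = matrix.to_numpy(dtype=float)
    obs_metric = _metric_values(x, in1, metric)
    es_obs = _es_batch(obs_metric, symbols, set_indices, weight_p, lexsort=True)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(names)))
    if perm_type == "phenotype":
        for b in range(n_perm):
            perm_in1 = rng.permutation(in1)
            pm = _metric_values(x, perm_in1, metric)
            null[b] = _es_batch(pm, symbols, set_indices, weight_p)
    elif perm_type == "gene_set":
        for si, idx in enumerate(set_indices):
            k = idx.size
            rand_sets = [
                rng.choice(x.shape[0], size=k, replace=False) for _ in range(n_perm)
            ]
            null[:, si] = _es_batch(
                obs_metric, symbols, rand_sets, weight_p, lexsort=True
            )
    else:
        raise ValueError(f"unknown perm_type {perm_type!r}")

    nes = np.empty(len(names))
    nes_null = np.full_like(null, np.nan)
    nom_p = np.empty(len(names))
    floor = 1.0 / (n_perm + 1)
    for si in range(len(names)):
        col = null[:, si]
        pos_mean = col[col > 0].mean() if (col > 0).any() else np.nan
        neg_mean = np.abs(col[col < 0].mean()) if (col < 0).any() else np.nan
        e = es_obs[si]
        denom = pos_mean if e >= 0 else neg_mean
        nes[si] = e / denom if np.isfinite(denom) and denom > 0 else 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_null[col > 0, si] = col[col > 0] / pos_mean
            nes_null[col < 0, si] = col[col < 0] / neg_mean
        same = col[col >= 0] if e >= 0 else col[col < 0]
        extreme = (same >= e).sum() if e >= 0 else (same <= e).sum()
        nom_p[si] = max((extreme + 1) / (same.size + 1), floor)

    pooled = nes_null[np.isfinite(nes_null)]
    fdr_q = np.empty(len(names))
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = pooled[pooled < 0]
    obs_pos = nes[nes >= 0]
    obs_neg = nes[nes < 0]
    for si in range(len(names)):
        v = nes[si]
        if v >= 0:
            num = (pooled_pos >= v).mean() if pooled_pos.size else 0.0
            den = (obs_pos >= v).mean() if obs_pos.size else 1.0
        else:
            num = (pooled_neg <= v).mean() if pooled_neg.size else 0.0
            den = (obs_neg <= v).mean() if obs_neg.size else 1.0
        fdr_q[si] = min(max(num / den if den > 0 else 1.0, 0.0), 1.0)

    # monotonicity: within a sign class, a more extreme |NES| never gets a
    # larger q than a less extreme one
    res = pd.DataFrame(
        {
            "size": [idx.size for idx in set_indices],
            "ES": es_obs,
            "NES": nes,
            "nom_p": nom_p,
            "fdr_q": fdr_q,
            "sign": np.where(es_obs >= 0, "positive", "negative"),
        },
        index=pd.Index(names, name="gene_set"),
    )
    for sign_val in ("positive", "negative"):
        mask = res["sign"] == sign_val
        if mask.any():
            sub = res.loc[mask].sort_values("NES", key=lambda s: -s.abs(), kind="stable")
            res.loc[sub.index, "fdr_q"] = np.minimum.accumulate(
                sub["fdr_q"].to_numpy()[::-1]
            )[::-1]
    return res


def filter_significant(
    results: pd.DataFrame,
    p_max: float = 0.05,
    q_max: float = 0.25,
    rule: str = "or",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the significance filter and partition by enrichment sign.

    Keeps sets with nominal p < ``p_max`` OR FDR q < ``q_max`` (rule='or',
    the default reading of "p < 0.05 and/or FDR < 25%"); rule='and'
    requires both.  Returns ``(positive, negative)`` tables sorted by
    |NES| descending.
    """
    if rule == "or":
        keep = (results["nom_p"] < p_max) | (results["fdr_q"] < q_max)
    elif rule == "and":
        keep = (results["nom_p"] < p_max) & (results["fdr_q"] < q_max)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    kept = results.loc[keep]
    pos = kept.loc[kept["NES"] >= 0].sort_values("NES", key=lambda s: -s.abs(), kind="stable")
    neg = kept.loc[kept["NES"] < 0].sort_values("NES", key=lambda s: -s.abs(), kind="stable")
    return pos, neg
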