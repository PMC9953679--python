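"""Published summary tables of the GSE188309 whole-blood CAP mortality cohort.

These are the printed study-level results (cohort counts, the 49-gene
differential-expression table, the 11 significant Hallmark gene sets)
shipped as plain-text package data.  They serve as reference inputs for
sanity checks and worked examples; the underlying expression data live in
the Gene Expression Omnibus under accession GSE188309 and are never
required by this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_cohort_summary",
    "load_table1_counts",
    "load_de_table",
    "load_gsea_table",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("capmort.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", **kwargs)


def load_cohort_summary() -> dict[str, int]:
    """Headline cohort counts: admissions, deaths, comorbidities, PSI risk,
    and the number of arrays processed."""
    df = _read("gse188309_cohort_summary.tsv")
    return dict(zip(df["quantity"], df["count"].astype(int)))


def load_table1_counts() -> pd.DataFrame:
    """Per-characteristic exposure counts by outcome group (died N=18,
    survived N=210)."""
    return _read("gse188309_table1_counts.tsv", index_col="characteristic")


def load_de_table() -> pd.DataFrame:
    """The 49 reported differentially expressed genes (died vs survived):
    p-value, signed fold change, subsampling selection count."""
    return _read("gse188309_de_genes.tsv", index_col="Symbol")


def load_gsea_table() -> pd.DataFrame:
    """The 11 reported Hallmark gene sets with NOM p, FDR q and NES."""
    return _read("gse188309_gsea_hallmark.tsv", index_col="gene_set")
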