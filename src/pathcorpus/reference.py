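"""Published summary tables of the curated TCGA pathology-report corpus.

The package bundles the released corpus's demographic breakdown and
per-cancer-type patient counts as plain TSVs. They serve as reference
inputs for sanity arithmetic (band totals, gender shares, prevalence
extremes) and for prevalence-ordered reporting without downloading
anything.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd


def load_demographics() -> pd.DataFrame:
    """Demographic characteristics of the released corpus: one row per
    (category, group) with patient count and published percentage."""
    with (files("pathcorpus.data") / "demographics.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_cancer_type_counts() -> pd.DataFrame:
    """Per-cancer-type patient counts of the released corpus, ordered by
    prevalence (descending)."""
    with (files("pathcorpus.data") / "cancer_type_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def age_band_total(demographics: pd.DataFrame | None = None) -> int:
    """Total patients across the age bands (equals the corpus size)."""
    df = demographics if demographics is not None else load_demographics()
    return int(df.loc[df["category"] == "age", "n_patients"].sum())


def gender_share(gender: str, demographics: pd.DataFrame | None = None) -> float:
    """Share (in %) of the given gender among patients with reported
    gender, rounded to one decimal as published."""
    df = demographics if demographics is not None else load_demographics()
    g = df[df["category"] == "gender"]
    total = g["n_patients"].sum()
    n = g.loc[g["group"] == gender, "n_patients"].sum()
    return round(100.0 * n / total, 1)


def prevalence_extremes(
    counts: pd.DataFrame | None = None,
) -> tuple[tuple[str, int], tuple[str, int]]:
    """((most prevalent label, n), (least prevalent label, n))."""
    df = counts if counts is not None else load_cancer_type_counts()
    hi = df.loc[df["n_patients"].idxmax()]
    lo = df.loc[df["n_patients"].idxmin()]
    return (hi["project_label"], int(hi["n_patients"])), (
        lo["project_label"], int(lo["n_patients"])
    )
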