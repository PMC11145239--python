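"""Vascularity keyword gene selection, CPM normalization, low-expression filter.

Gene selection is lexical: a gene is kept when any keyword from a fixed
vocabulary of vascular-biology terms occurs as a case-insensitive substring
of its annotation description (so "neovascularization" is caught by
"vascular"). Counts-per-million are computed against the full-library
sequencing depth, and genes whose median CPM across all samples does not
strictly exceed a floor (default 0.2) are excluded as too noisy to model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import CountMatrix
from .errors import ConfigurationError, DataError

#: Default vascularity vocabulary (15 terms).
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "vascular",
    "vasculature",
    "blood vessel",
    "microvessel",
    "angiogenesis",
    "hypoxia",
    "necrosis",
    "capillary",
    "glomerulus",
    "glomerular",
    "vasculogenesis",
    "venous",
    "artery",
    "circulatory",
    "coagulation",
)


@dataclass(frozen=True)
class KeywordSet:
    """A lowercase keyword vocabulary for description matching."""

    terms: tuple[str, ...] = DEFAULT_KEYWORDS

    def __post_init__(self) -> None:
        if not self.terms:
            raise ConfigurationError("keyword set must contain at least one term")
        object.__setattr__(
            self, "terms", tuple(t.strip().lower() for t in self.terms)
        )
        if any(not t for t in self.terms):
            raise ConfigurationError("keyword set contains an empty term")

    @classmethod
    def from_file(cls, path) -> "KeywordSet":
        with open(path) as fh:
            terms = [line.strip() for line in fh if line.strip()]
        return cls(tuple(terms))


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values on a declared scale (cpm or log2cpm)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str  # "cpm" | "log2cpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("cpm", "log2cpm"):
            raise ConfigurationError(f"unknown expression scale {self.scale!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError("expression matrix shape mismatch")
        if self.scale == "cpm" and self.values.size and self.values.min() < 0:
            raise DataError("CPM values must be nonnegative")

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise DataError(f"unknown gene ids: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=gene_ids,
            sample_ids=list(self.sample_ids),
            values=self.values[rows],
            scale=self.scale,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        return df


def keyword_filter(
    annotation: Mapping[str, str], keywords: KeywordSet | None = None
) -> list[str]:
    """Return gene ids whose description contains any keyword as a substring.

    Matching is case-insensitive and purely lexical; order of the input
    annotation is preserved in the output.
    """
    kw = keywords if keywords is not None else KeywordSet()
    retained = []
    for gene_id, description in annotation.items():
        text = (description or "").lower()
        if any(term in text for term in kw.terms):
            retained.append(gene_id)
    return retained


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts-per-million: count / full-library size x 1e6, per sample.

    The library size is the total depth over the complete pre-filter gene
    set, so per-sample CPM over that full set sums to exactly 1e6.
    """
    lib = np.asarray(counts.library_size, dtype=float)
    if (lib <= 0).any():
        bad = np.asarray(counts.sample_ids)[lib <= 0]
        raise DataError(f"zero library size for sample(s): {list(bad[:5])}")
    values = counts.counts / lib[np.newaxis, :] * 1e6
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=values,
        scale="cpm",
    )


def low_expression_exclusion(
    expr: ExpressionMatrix, min_median_cpm: float = 0.2
) -> list[str]:
    """Retain genes whose median CPM across all samples strictly exceeds the floor.

    Genes with median CPM <= ``min_median_cpm`` are excluded as dominated by
    counting noise. The median is taken over all samples, unstratified.
    """
    if expr.scale != "cpm":
        raise ConfigurationError("low_expression_exclusion expects a cpm-scale matrix")
    medians = np.median(expr.values, axis=1)
    return [g for g, m in zip(expr.gene_ids, medians) if m > min_median_cpm]


def retention_summary(n_initial: int, n_retained: int) -> dict:
    """Percentage bookkeeping for filter stages (rounded to 2 decimals)."""
    if n_initial <= 0:
        raise ConfigurationError("n_initial must be positive")
    pct = round(100.0 * n_retained / n_initial, 2)
    return {"initial": n_initial, "retained": n_retained, "percent": pct}
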