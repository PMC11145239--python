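"""Signature concordance scoring and expected-vascularity group assignment.

Each sample earns +1 per signature gene whose expression lies on the
signature's side of the per-gene cohort center (median by default): strictly
above the center for an "over" gene, strictly below for an "under" gene.
Ties contribute nothing. The total score (0 .. signature size) quantifies how
closely the sample's transcriptome matches the vascularity expression
pattern, and a cutoff on the score splits the cohort into Expected High
Vascularity (EHV) and Expected Moderate Vascularity (EMV) groups. For a
signature derived from the HV-vs--V contrast, high scores mean EHV; for a
signature from the MV-vs--V contrast the mapping is reversed, because there a
high score means similarity to the *moderate*-vascularity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import CONTRAST_HV, CONTRAST_MV, Signature
from .errors import ConfigurationError, DataError
from .filtering import ExpressionMatrix

GROUP_EHV = "EHV"
GROUP_EMV = "EMV"


@dataclass
class ScoreTable:
    sample_ids: list[str]
    scores: np.ndarray  # integer, 0 .. len(signature)
    contributions: pd.DataFrame  # genes x samples, 0/1
    signature: Signature
    center: str

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name="score")


@dataclass
class StratifiedCohort:
    sample_ids: list[str]
    expected_group: list[str]  # EHV / EMV per sample
    cutoff_used: int
    contrast_source: str

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.expected_group, index=self.sample_ids, name="expected_group"
        )


def score_samples(
    expr: ExpressionMatrix, signature: Signature, center: str = "median"
) -> ScoreTable:
    """Score every sample's concordance with the signature.

    The per-gene center (median or mean) is computed across *all* samples of
    the matrix, including the sample being scored. Strict inequalities: a
    sample exactly at the center earns no point for that gene.
    """
    if center not in ("median", "mean"):
        raise ConfigurationError(f"center must be 'median' or 'mean', got {center!r}")
    if len(signature) == 0:
        raise ConfigurationError("cannot score with an empty signature")
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in signature.gene_ids if g not in index]
    if missing:
        raise DataError(f"signature genes absent from expression matrix: {missing}")

    rows = [index[g] for g in signature.gene_ids]
    values = expr.values[rows]  # (n_sig, n_samples)
    centers = (
        np.median(values, axis=1) if center == "median" else values.mean(axis=1)
    )
    over = np.array([d == "over" for _, d in signature.entries])
    above = values > centers[:, np.newaxis]
    below = values < centers[:, np.newaxis]
    contrib = np.where(over[:, np.newaxis], above, below).astype(np.int64)
    scores = contrib.sum(axis=0)
    contributions = pd.DataFrame(
        contrib, index=signature.gene_ids, columns=expr.sample_ids
    )
    return ScoreTable(
        sample_ids=list(expr.sample_ids),
        scores=scores,
        contributions=contributions,
        signature=signature,
        center=center,
    )


def assign_expected_groups(
    scores: ScoreTable, cutoff: int, contrast_source: str | None = None
) -> StratifiedCohort:
    """Split samples at the score cutoff into EHV / EMV.

    HV-derived signature: score > cutoff -> EHV, else EMV. MV-derived
    signature: the mapping is reversed (high concordance with the moderate
    pattern means *expected moderate* vascularity).
    """
    source = contrast_source or scores.signature.contrast
    if source not in (CONTRAST_HV, CONTRAST_MV):
        raise ConfigurationError(f"unknown contrast source {source!r}")
    max_score = len(scores.signature)
    if not (0 <= cutoff < max_score):
        raise ConfigurationError(
            f"cutoff must satisfy 0 <= cutoff < {max_score}, got {cutoff}"
        )
    high_label, low_label = (
        (GROUP_EHV, GROUP_EMV) if source == CONTRAST_HV else (GROUP_EMV, GROUP_EHV)
    )
    labels = [high_label if s > cutoff else low_label for s in scores.scores]
    return StratifiedCohort(
        sample_ids=list(scores.sample_ids),
        expected_group=labels,
        cutoff_used=int(cutoff),
        contrast_source=source,
    )
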