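"""Intra-protein phosphosite co-occurrence.

For a pair of sites, the four co-regulation patterns UU, DD, UD, DU are
tallied over the differential datasets in which *both* sites are called up-
or down-regulated. The positive co-regulation ratio is
(nUU + nDD) / (nUD + nDU) and the negative ratio its reciprocal; higher
values indicate stronger coordinated (respectively opposed) regulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import (
    CALL_DOWN,
    CALL_NONE,
    CALL_UP,
    Corpus,
    FilterConfig,
    PhosphositeID,
    ValidationError,
    as_site,
)

__all__ = [
    "PatternCounts",
    "CooccurrenceResult",
    "call_matrix",
    "count_patterns",
    "coregulation_ratios",
    "cooccurrence_matrix",
]


@dataclass(frozen=True)
class PatternCounts:
    """Co-regulation pattern tallies for an ordered site pair.

    The first letter of each pattern refers to ``site1``; swapping the pair
    swaps nUD and nDU and fixes nUU and nDD.
    """

    site1: str
    site2: str
    nUU: int
    nDD: int
    nUD: int
    nDU: int

    def __post_init__(self) -> None:
        for name in ("nUU", "nDD", "nUD", "nDU"):
            if getattr(self, name) < 0:
                raise ValidationError(f"PatternCounts.{name} must be >= 0")

    @property
    def n_both(self) -> int:
        return self.nUU + self.nDD + self.nUD + self.nDU

    @property
    def concordant(self) -> int:
        return self.nUU + self.nDD

    @property
    def discordant(self) -> int:
        return self.nUD + self.nDU

    def swapped(self) -> "PatternCounts":
        return PatternCounts(self.site2, self.site1, self.nUU, self.nDD, self.nDU, self.nUD)


@dataclass(frozen=True)
class CooccurrenceResult:
    """Positive/negative co-regulation ratios for one pair.

    ``math.inf`` marks a zero denominator with nonzero numerator (infinite
    concordance or discordance); NaN marks 0/0 (no co-called data at all).
    """

    counts: PatternCounts
    positive_ratio: float
    negative_ratio: float

    @property
    def no_data(self) -> bool:
        return math.isnan(self.positive_ratio)


def call_matrix(corpus: Corpus, genes: Optional[list[str]] = None) -> pd.DataFrame:
    """Signed call matrix over all differential datasets.

    Index: every differential dataset_id in the corpus (including datasets
    with no called record). Columns: site tokens. Values: +1 for U, -1 for D,
    0 for uncalled/undetected.
    """
    diff = corpus.differential
    called = diff[diff["call"] != CALL_NONE]
    if genes is not None:
        called = called[called["gene"].isin(genes)]
    called = called.drop_duplicates(subset=["dataset_id", "site"], keep="first")
    sign = called["call"].map({CALL_UP: 1, CALL_DOWN: -1}).astype(np.int8)
    mat = (
        pd.DataFrame({"dataset_id": called["dataset_id"], "site": called["site"], "sign": sign})
        .pivot(index="dataset_id", columns="site", values="sign")
        .reindex(corpus.differential_dataset_ids)
        .fillna(0)
        .astype(np.int8)
    )
    mat.index.name = "dataset_id"
    return mat


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    nUU = int(((x == 1) & (y == 1)).sum())
    nDD = int(((x == -1) & (y == -1)).sum())
    nUD = int(((x == 1) & (y == -1)).sum())
    nDU = int(((x == -1) & (y == 1)).sum())
    return nUU, nDD, nUD, nDU


def count_patterns(
    site1: Union[str, PhosphositeID], site2: Union[str, PhosphositeID], corpus: Corpus
) -> PatternCounts:
    """Tally the four co-regulation patterns for a site pair.

    Each differential dataset in which both sites are called U or D
    contributes exactly one count; datasets where either site is undetected
    or uncalled are ignored.
    """
    s1, s2 = as_site(site1), as_site(site2)
    if s1 == s2:
        raise ValidationError(f"count_patterns requires two distinct sites, got {s1.token}")
    mat = call_matrix(corpus, genes=[s1.gene, s2.gene])
    x = mat[s1.token].to_numpy() if s1.token in mat.columns else np.zeros(len(mat), dtype=np.int8)
    y = mat[s2.token].to_numpy() if s2.token in mat.columns else np.zeros(len(mat), dtype=np.int8)
    nUU, nDD, nUD, nDU = _pair_counts(x, y)
    return PatternCounts(s1.token, s2.token, nUU, nDD, nUD, nDU)


def coregulation_ratios(counts: PatternCounts) -> CooccurrenceResult:
    """Positive and negative co-regulation ratios with sentinel handling."""
    conc, disc = counts.concordant, counts.discordant
    if conc == 0 and disc == 0:
        pos = neg = math.nan
    elif disc == 0:
        pos, neg = math.inf, 0.0
    elif conc == 0:
        pos, neg = 0.0, math.inf
    else:
        pos, neg = conc / disc, disc / conc
    return CooccurrenceResult(counts=counts, positive_ratio=pos, negative_ratio=neg)


def cooccurrence_matrix(
    corpus: Corpus, protein: str, cfg: Optional[FilterConfig] = None
) -> pd.DataFrame:
    """Long-format co-occurrence table over all ordered site pairs of one protein.

    Columns: site1, site2, nUU, nDD, nUD, nDU, positive_ratio,
    negative_ratio. The table is symmetric in positive_ratio (swapping the
    pair swaps nUD/nDU only); the diagonal is excluded. Sites considered are
    those of the protein with at least one U/D call.
    """
    protein = protein.upper()
    diff = corpus.differential
    tokens = sorted(
        diff.loc[(diff["gene"] == protein) & (diff["call"] != CALL_NONE), "site"].unique()
    )
    if len(tokens) < 2:
        warnings.warn(
            f"protein {protein!r} has fewer than two called sites; empty co-occurrence table"
        )
        return pd.DataFrame(
            columns=["site1", "site2", "nUU", "nDD", "nUD", "nDU", "positive_ratio", "negative_ratio"]
        )
    mat = call_matrix(corpus, genes=[protein])
    cols = {tok: mat[tok].to_numpy() for tok in tokens}
    rows = []
    for t1 in tokens:
        for t2 in tokens:
            if t1 == t2:
                continue
            nUU, nDD, nUD, nDU = _pair_counts(cols[t1], cols[t2])
            res = coregulation_ratios(PatternCounts(t1, t2, nUU, nDD, nUD, nDU))
            rows.append(
                {
                    "site1": t1,
                    "site2": t2,
                    "nUU": nUU,
                    "nDD": nDD,
                    "nUD": nUD,
                    "nDU": nDU,
                    "positive_ratio": res.positive_ratio,
                    "negative_ratio": res.negative_ratio,
                }
            )
    return pd.DataFrame(rows)
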