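"""Co-differential-regulation screen for phosphosites of other proteins (PsOPs).

For a designated predominant site, every called phosphosite on a different
protein is paired with it. Over all differential datasets of the corpus each
dataset falls in exactly one contingency cell:

* ``a`` — neither site called (up or down),
* ``b`` — exactly one of the two called,
* ``c`` — both called, discordantly (one up, one down),
* ``d`` — both called, concordantly (both up or both down).

A one-sided Fisher's exact test on the 2x2 table ``[[a, b], [c, d]]``
(conditioning on its row and column margins) scores positive co-regulation
(UUDD category, extremeness toward large ``d``) or negative co-regulation
(UDDU category, extremeness toward large ``c``). A pair is retained as
high-confidence when it passes four filters: raw FET p below ``fet_alpha``,
co-regulation frequency at least ``freq_ratio_min`` of the predominant
site's total differential frequency, and support from at least ``min_pmids``
distinct publications and ``min_codes`` distinct experimental conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Optional, Union

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

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
from .cooccurrence import PatternCounts, call_matrix, _pair_counts

__all__ = [
    "ContingencyTable",
    "classify_pattern",
    "build_contingency",
    "fisher_one_sided",
    "psop_screen",
    "PSOP_COLUMNS",
]

CATEGORY_POSITIVE = "UUDD"
CATEGORY_NEGATIVE = "UDDU"

PSOP_COLUMNS = [
    "site",
    "gene",
    "residue",
    "position",
    "category",
    "nUU",
    "nDD",
    "nUD",
    "nDU",
    "a",
    "b",
    "c",
    "d",
    "fet_p",
    "fet_bh",
    "coreg_freq",
    "freq_ratio",
    "pmid_count",
    "code_count",
    "passes",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Condition-level 2x2 contingency ``[[a, b], [c, d]]`` (see module docstring)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"contingency cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def classify_pattern(call_predominant: str, call_other: str) -> str:
    """Two-letter pattern code; first letter is the predominant site's status."""
    for call in (call_predominant, call_other):
        if call not in (CALL_UP, CALL_DOWN):
            raise ValidationError(f"classify_pattern requires calls in {{U, D}}, got {call!r}")
    return call_predominant + call_other


def build_contingency(
    predominant_site: Union[str, PhosphositeID],
    other_site: Union[str, PhosphositeID],
    corpus: Corpus,
) -> ContingencyTable:
    """Tally the contingency cells for a cross-protein pair.

    Only U/D calls count as "detected"; sub-threshold records fall in the
    undetected cells. ``n`` always equals the corpus's total number of
    differential datasets.
    """
    s1, s2 = as_site(predominant_site), as_site(other_site)
    if s1.gene == s2.gene:
        raise ValidationError(
            f"build_contingency requires sites on different proteins, got {s1.token} / {s2.token}"
            " (intra-protein pairs belong to the co-occurrence analysis)"
        )
    mat = call_matrix(corpus, genes=[s1.gene, s2.gene])
    n = len(mat)
    x = mat[s1.token].to_numpy() if s1.token in mat.columns else np.zeros(n, dtype=np.int8)
    y = mat[s2.token].to_numpy() if s2.token in mat.columns else np.zeros(n, dtype=np.int8)
    return _contingency_from_calls(x, y)


def _contingency_from_calls(x: np.ndarray, y: np.ndarray) -> ContingencyTable:
    det_x, det_y = x != 0, y != 0
    both = det_x & det_y
    d = int((both & (x == y)).sum())
    c = int((both & (x != y)).sum())
    b = int((det_x ^ det_y).sum())
    a = int((~det_x & ~det_y).sum())
    return ContingencyTable(a=a, b=b, c=c, d=d)


def fisher_one_sided(table: ContingencyTable, direction: str) -> float:
    """One-sided Fisher's exact p-value on ``[[a, b], [c, d]]``.

    Conditions on the table's margins; the hypergeometric family is indexed
    by the ``d`` cell. ``direction="positive"`` sums tables at least as
    extreme toward large ``d`` (concordance), ``direction="negative"`` toward
    large ``c`` (discordance). Computed with exact integer arithmetic; the
    result is in (0, 1].
    """
    if direction not in ("positive", "negative"):
        raise ValidationError(f"direction must be 'positive' or 'negative', got {direction!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    col2 = b + d
    n = r1 + r2
    if n == 0:
        return 1.0
    # d ranges over the hypergeometric support given the margins
    d_lo = max(0, col2 - r1)
    d_hi = min(r2, col2)
    if direction == "positive":
        span = range(d, d_hi + 1)
    else:
        span = range(d_lo, d + 1)
    numerator = sum(comb(r2, k) * comb(r1, col2 - k) for k in span)
    return numerator / comb(n, col2)


def psop_screen(
    predominant_site: Union[str, PhosphositeID],
    corpus: Corpus,
    cfg: Optional[FilterConfig] = None,
) -> pd.DataFrame:
    """Screen all other-protein phosphosites against one predominant site.

    Emits one row per (site, category) with nonzero co-regulation frequency;
    both passing and failing rows are retained with a ``passes`` flag.
    ``fet_bh`` is a Benjamini-Hochberg-adjusted column provided for
    reference; the ``passes`` flag uses the raw p-value, the frequency-ratio
    cutoff and the PMID / condition-code replication filters.
    """
    cfg = cfg or FilterConfig()
    pred = as_site(predominant_site)
    mat = call_matrix(corpus)
    if pred.token not in mat.columns:
        warnings.warn(
            f"predominant site {pred.token} has no differential calls; empty PsOP screen"
        )
        return pd.DataFrame(columns=PSOP_COLUMNS)

    meta = corpus.dataset_meta_lookup()
    pmids = mat.index.map(meta["pmid"]).to_numpy()
    codes = mat.index.map(meta["condition_code"]).to_numpy()

    x = mat[pred.token].to_numpy()
    det_x = x != 0
    pred_diff_count = int(det_x.sum())

    site_info = (
        corpus.differential.loc[
            corpus.differential["call"] != CALL_NONE, ["site", "gene", "residue", "position"]
        ]
        .drop_duplicates(subset="site")
        .set_index("site")
    )

    rows = []
    for token in mat.columns:
        info = site_info.loc[token]
        if info["gene"] == pred.gene:
            continue
        y = mat[token].to_numpy()
        nUU, nDD, nUD, nDU = _pair_counts(x, y)
        counts = PatternCounts(pred.token, token, nUU, nDD, nUD, nDU)
        table = _contingency_from_calls(x, y)
        both = det_x & (y != 0)
        conc_mask = both & (x == y)
        disc_mask = both & (x != y)
        for category, coreg_freq, mask, direction in (
            (CATEGORY_POSITIVE, table.d, conc_mask, "positive"),
            (CATEGORY_NEGATIVE, table.c, disc_mask, "negative"),
        ):
            if coreg_freq == 0:
                continue
            rows.append(
                {
                    "site": token,
                    "gene": info["gene"],
                    "residue": info["residue"],
                    "position": int(info["position"]),
                    "category": category,
                    "nUU": counts.nUU,
                    "nDD": counts.nDD,
                    "nUD": counts.nUD,
                    "nDU": counts.nDU,
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "fet_p": fisher_one_sided(table, direction),
                    "coreg_freq": coreg_freq,
                    "freq_ratio": coreg_freq / pred_diff_count if pred_diff_count else np.nan,
                    "pmid_count": int(pd.unique(pmids[mask]).size),
                    "code_count": int(pd.unique(codes[mask]).size),
                }
            )

    if not rows:
        return pd.DataFrame(columns=PSOP_COLUMNS)
    out = pd.DataFrame(rows)
    out["fet_bh"] = multipletests(out["fet_p"].to_numpy(), method="fdr_bh")[1]
    out["passes"] = (
        (out["fet_p"] < cfg.fet_alpha)
        & (out["freq_ratio"] >= cfg.freq_ratio_min)
        & (out["pmid_count"] >= cfg.min_pmids)
        & (out["code_count"] >= cfg.min_codes)
    )
    out = out.loc[:, PSOP_COLUMNS]
    out = out.sort_values(
        ["category", "fet_p", "site"], ascending=[True, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
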