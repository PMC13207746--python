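"""Detection-frequency ranking and predominant-site designation.

For a target protein, each Class-I site is counted once per profiling
dataset in which it is identified and once per differential dataset in which
it is called up- or down-regulated. Sites are ranked by total frequency;
*predominant* sites are those detected in both dataset types and replicated
in at least ``min_pmids`` distinct studies.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .model import CALL_DOWN, CALL_NONE, CALL_UP, Corpus, FilterConfig, ValidationError, is_class1

logger = logging.getLogger(__name__)

FREQ_COLUMNS = [
    "site",
    "gene",
    "residue",
    "position",
    "profiling_count",
    "differential_count",
    "up_count",
    "down_count",
    "study_count",
]


def site_frequencies(
    corpus: Corpus, protein: str, cfg: Optional[FilterConfig] = None
) -> pd.DataFrame:
    """Per-site detection frequencies for one protein.

    A dataset contributes at most one count per site. Profiling rows are
    restricted to Class-I localizations; differential rows count only when
    the call is U or D. ``study_count`` is the number of distinct PMIDs whose
    datasets (either type) detect the site.
    """
    cfg = cfg or FilterConfig()
    protein = protein.upper()
    meta = corpus.dataset_meta_lookup()

    prof = corpus.profiling[corpus.profiling["gene"] == protein]
    if len(prof):
        keep = prof.apply(lambda r: is_class1(r["loc_prob"], r["ascore"], cfg), axis=1)
        prof = prof[keep]
    diff = corpus.differential[
        (corpus.differential["gene"] == protein) & (corpus.differential["call"] != CALL_NONE)
    ]

    if not len(prof) and not len(diff):
        warnings.warn(f"protein {protein!r} absent from corpus; returning empty frequency table")
        return pd.DataFrame(columns=FREQ_COLUMNS)

    keys = ["site", "gene", "residue", "position"]
    prof_u = prof.drop_duplicates(subset=["site", "dataset_id"])
    diff_u = diff.drop_duplicates(subset=["site", "dataset_id"])

    prof_counts = prof_u.groupby(keys).size().rename("profiling_count")
    up_counts = (
        diff_u[diff_u["call"] == CALL_UP].groupby(keys).size().rename("up_count")
    )
    down_counts = (
        diff_u[diff_u["call"] == CALL_DOWN].groupby(keys).size().rename("down_count")
    )

    pmids = pd.concat(
        [
            prof_u[["site", "gene", "residue", "position", "dataset_id"]],
            diff_u[["site", "gene", "residue", "position", "dataset_id"]],
        ]
    )
    pmids["pmid"] = pmids["dataset_id"].map(meta["pmid"])
    study_counts = pmids.groupby(keys)["pmid"].nunique().rename("study_count")

    out = pd.concat([prof_counts, up_counts, down_counts, study_counts], axis=1).fillna(0)
    out = out.reset_index()
    for col in ("profiling_count", "up_count", "down_count", "study_count"):
        out[col] = out[col].astype(int)
    out["differential_count"] = out["up_count"] + out["down_count"]
    out = out.loc[:, FREQ_COLUMNS].sort_values("position").reset_index(drop=True)
    return out


def rank_predominant(freqs: pd.DataFrame, cfg: Optional[FilterConfig] = None) -> pd.DataFrame:
    """Rank sites and flag the predominant ones.

    Sort key: total detection frequency (profiling + differential)
    descending, ties broken by differential count descending, then position
    ascending. A site is predominant iff it is detected in both dataset types
    and replicated in >= ``min_pmids`` distinct studies.
    """
    cfg = cfg or FilterConfig()
    if not len(freqs):
        raise ValidationError("rank_predominant requires a nonempty frequency table")
    out = freqs.copy()
    out["total_count"] = out["profiling_count"] + out["differential_count"]
    out = out.sort_values(
        ["total_count", "differential_count", "position"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["predominant"] = (
        (out["profiling_count"] >= 1)
        & (out["differential_count"] >= 1)
        & (out["study_count"] >= cfg.min_pmids)
    )
    return out


def predominant_sites(freqs: pd.DataFrame, cfg: Optional[FilterConfig] = None) -> list[str]:
    """Tokens of the top-ranked predominant site(s): all sites sharing the
    highest total frequency among those meeting the predominance criteria."""
    ranked = rank_predominant(freqs, cfg)
    eligible = ranked[ranked["predominant"]]
    return eligible["site"].tolist()


def export_lollipop_table(
    freqs: pd.DataFrame, domain_annotations: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Plot-ready per-site rows for a lollipop figure.

    Heights: profiling count, up-regulated count, and down-regulated count
    emitted as a negative value (for below-axis lollipops). If a domain table
    (``domain``, ``start``, ``end``) is given, each site is labelled with the
    domain interval containing its position.
    """
    out = freqs.loc[:, ["site", "position", "profiling_count", "up_count", "down_count"]].copy()
    out = out.rename(
        columns={
            "profiling_count": "profiling_height",
            "up_count": "up_height",
        }
    )
    out["down_height"] = -out.pop("down_count")
    out["domain"] = ""
    if domain_annotations is not None and len(domain_annotations):
        bad = domain_annotations["start"] > domain_annotations["end"]
        if bad.any():
            row = domain_annotations[bad].iloc[0]
            raise ValidationError(
                f"domain {row['domain']!r} has start {row['start']} > end {row['end']}"
            )
        for _, dom in domain_annotations.iterrows():
            inside = (out["position"] >= dom["start"]) & (out["position"] <= dom["end"])
            out.loc[inside, "domain"] = dom["domain"]
    return out.sort_values("position").reset_index(drop=True)
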