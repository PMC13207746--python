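"""Cross-referencing passing PsOPs against curated annotation tables.

Kinase-substrate relationships (validated or predicted), protein-protein
interaction (PPI) support across databases, and descriptive biological-
process labels are consumed as pre-made TSV tables; this module only
intersects them with the co-regulation screen — it never invents an
annotation, and it performs no live database queries or enrichment
statistics.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import pandas as pd

from .model import PhosphositeID, ValidationError, as_site
from .psop import CATEGORY_POSITIVE

KINASE_COLUMNS = ["kinase", "substrate_gene", "residue", "position", "evidence", "source"]
PPI_COLUMNS = ["partner", "source_db"]
PROCESS_COLUMNS = ["gene", "residue", "position", "process"]


def _passing(psop_results: pd.DataFrame) -> pd.DataFrame:
    return psop_results[psop_results["passes"]]


def crossref_kinases(
    psop_results: pd.DataFrame,
    kinase_table: pd.DataFrame,
    target_site: Union[str, PhosphositeID],
) -> pd.DataFrame:
    """Kinases annotated on the target site whose own phosphosites co-regulate with it.

    A kinase is reported iff it annotates the target site in the curation
    table AND at least one of its own phosphosites appears among the passing
    PsOPs. Carries the evidence flag (validated/predicted), the co-regulation
    categories observed on its sites, and the best (smallest) FET p among
    them.
    """
    target = as_site(target_site)
    if not len(kinase_table):
        warnings.warn("empty kinase table; no kinases to cross-reference")
        return pd.DataFrame(
            columns=["kinase", "evidence", "sources", "coreg_sites", "categories", "best_fet_p"]
        )
    kin = kinase_table.copy()
    kin["position"] = kin["position"].astype(int)
    on_target = kin[
        (kin["substrate_gene"].str.upper() == target.gene)
        & (kin["residue"].str.upper() == target.residue)
        & (kin["position"] == target.position)
    ]
    passing = _passing(psop_results)
    rows = []
    for kinase, grp in on_target.groupby("kinase"):
        own = passing[passing["gene"] == kinase.upper()]
        if not len(own):
            continue
        rows.append(
            {
                "kinase": kinase,
                "evidence": ";".join(sorted(grp["evidence"].unique())),
                "sources": ";".join(sorted(grp["source"].unique())),
                "coreg_sites": ";".join(sorted(own["site"].unique())),
                "categories": ";".join(sorted(own["category"].unique())),
                "best_fet_p": float(own["fet_p"].min()),
            }
        )
    out = pd.DataFrame(
        rows, columns=["kinase", "evidence", "sources", "coreg_sites", "categories", "best_fet_p"]
    )
    return out.sort_values("kinase").reset_index(drop=True)


def crossref_interactors(
    psop_results: pd.DataFrame,
    ppi_tables: Union[pd.DataFrame, list[pd.DataFrame]],
    min_db_support: int = 2,
    all_partners: bool = False,
) -> pd.DataFrame:
    """Interaction partners with cross-database support and co-regulated sites.

    Partners supported by at least ``min_db_support`` distinct source
    databases are retained; for each, its phosphosites among the passing
    PsOPs are listed with their categories. Partners with no co-regulated
    site are included only when ``all_partners`` is set.
    """
    if min_db_support < 1:
        raise ValidationError(f"min_db_support must be >= 1, got {min_db_support}")
    if isinstance(ppi_tables, pd.DataFrame):
        ppi_tables = [ppi_tables]
    if not ppi_tables:
        raise ValidationError("at least one PPI table is required")
    ppi = pd.concat([t.loc[:, PPI_COLUMNS] for t in ppi_tables], ignore_index=True)
    ppi["partner"] = ppi["partner"].str.upper()
    support = ppi.groupby("partner")["source_db"].agg(lambda s: sorted(set(s)))
    passing = _passing(psop_results)
    rows = []
    for partner, sources in support.items():
        if len(sources) < min_db_support:
            continue
        own = passing[passing["gene"] == partner]
        if not len(own) and not all_partners:
            continue
        sites = sorted(own["site"].unique())
        rows.append(
            {
                "partner": partner,
                "n_sources": len(sources),
                "sources": ";".join(sources),
                "coreg_sites": ";".join(s.split("_", 1)[1] for s in sites),
                "categories": ";".join(sorted(own["category"].unique())),
            }
        )
    out = pd.DataFrame(rows, columns=["partner", "n_sources", "sources", "coreg_sites", "categories"])
    return out.sort_values("partner").reset_index(drop=True)


def group_by_process(
    psop_results: pd.DataFrame, process_table: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Long network-export table (process, site, sign) over passing PsOPs.

    Sign is ``positive`` for the UUDD category and ``negative`` for UDDU.
    Sites without a process annotation are routed to an ``unannotated``
    bucket. This is descriptive grouping, not enrichment.
    """
    passing = _passing(psop_results).copy()
    passing["sign"] = (passing["category"] == CATEGORY_POSITIVE).map(
        {True: "positive", False: "negative"}
    )
    if process_table is not None and len(process_table):
        proc = process_table.copy()
        proc["position"] = proc["position"].astype(int)
        proc["site"] = (
            proc["gene"].str.upper() + "_" + proc["residue"].str.upper() + proc["position"].astype(str)
        )
        merged = passing.merge(proc.loc[:, ["site", "process"]], on="site", how="left")
    else:
        merged = passing.copy()
        merged["process"] = pd.NA
    merged["process"] = merged["process"].fillna("unannotated")
    out = merged.loc[:, ["process", "site", "sign"]].drop_duplicates()
    return out.sort_values(["process", "site", "sign"]).reset_index(drop=True)
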