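"""Corpus I/O, preprocessing and identifier harmonization.

All tables are plain TSV. ``read_corpus`` parses and validates the three
corpus files and derives differential calls; it does not mutate rows.
``preprocess`` applies the Class-I localization filter and collapses
duplicate (site, dataset) rows; ``harmonize`` re-keys gene symbols and
accessions against mapping tables and drops unmapped records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .model import (
    CALL_NONE,
    DATASET_COLUMNS,
    DIFFERENTIAL_COLUMNS,
    PROFILING_COLUMNS,
    ConfigError,
    Corpus,
    FilterConfig,
    SchemaError,
    is_class1,
)

logger = logging.getLogger(__name__)

DATASETS_FILE = "datasets.tsv"
PROFILING_FILE = "profiling.tsv"
DIFFERENTIAL_FILE = "differential.tsv"

# record files additionally carry pmid/condition_code for human readability;
# they are checked for consistency against datasets.tsv on read
PROFILING_FILE_COLUMNS = ["dataset_id", "pmid", "condition_code"] + PROFILING_COLUMNS[1:]
DIFFERENTIAL_FILE_COLUMNS = ["dataset_id", "pmid", "condition_code"] + DIFFERENTIAL_COLUMNS[1:]


def read_table(path: Union[str, Path], required: list[str], name: Optional[str] = None) -> pd.DataFrame:
    """Read a TSV and fail loudly if a required column is missing."""
    path = Path(path)
    name = name or path.name
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in file {name}")
    return df


def write_results(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a result table as TSV with stable column order and no index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # shortest round-trip float representation, so written corpora re-read exactly
    table.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_corpus(directory: Union[str, Path], cfg: Optional[FilterConfig] = None) -> Corpus:
    """Read ``datasets.tsv``, ``profiling.tsv`` and ``differential.tsv`` from a directory.

    Differential calls are derived from fold change / p-value with ``cfg``.
    The redundant pmid/condition_code columns of the record files are checked
    against the metadata table.
    """
    directory = Path(directory)
    cfg = cfg or FilterConfig()
    datasets = read_table(directory / DATASETS_FILE, DATASET_COLUMNS)
    profiling = read_table(directory / PROFILING_FILE, PROFILING_FILE_COLUMNS)
    differential = read_table(directory / DIFFERENTIAL_FILE, DIFFERENTIAL_FILE_COLUMNS)

    meta = datasets.set_index("dataset_id")
    for name, df in ((PROFILING_FILE, profiling), (DIFFERENTIAL_FILE, differential)):
        unknown = ~df["dataset_id"].isin(meta.index)
        if unknown.any():
            bad = df.loc[unknown, "dataset_id"].iloc[0]
            raise SchemaError(f"record in {name} references unknown dataset_id {bad!r}")
        joined_pmid = df["dataset_id"].map(meta["pmid"])
        joined_code = df["dataset_id"].map(meta["condition_code"])
        if not (joined_pmid.values == df["pmid"].values).all() or not (
            joined_code.values == df["condition_code"].values
        ).all():
            raise SchemaError(
                f"pmid/condition_code in {name} disagree with {DATASETS_FILE} for some rows"
            )

    return Corpus.assemble(
        datasets=datasets,
        profiling=profiling.drop(columns=["pmid", "condition_code"]),
        differential=differential.drop(columns=["pmid", "condition_code"]),
        cfg=cfg,
    )


def write_corpus(corpus: Corpus, directory: Union[str, Path]) -> None:
    """Write the three corpus TSVs (schema-conformant; derived columns dropped)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = corpus.dataset_meta_lookup()

    def with_meta(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        out = df.copy()
        out["pmid"] = out["dataset_id"].map(meta["pmid"])
        out["condition_code"] = out["dataset_id"].map(meta["condition_code"])
        return out.loc[:, cols]

    write_results(corpus.datasets.loc[:, DATASET_COLUMNS], directory / DATASETS_FILE)
    write_results(with_meta(corpus.profiling, PROFILING_FILE_COLUMNS), directory / PROFILING_FILE)
    write_results(
        with_meta(corpus.differential, DIFFERENTIAL_FILE_COLUMNS), directory / DIFFERENTIAL_FILE
    )


# ---------------------------------------------------------------------------
# preprocessing: Class-I filter + duplicate collapse
# ---------------------------------------------------------------------------


@dataclass
class PreprocessReport:
    """Row-level accounting for :func:`preprocess`."""

    profiling_not_class1: int = 0
    profiling_duplicates_collapsed: int = 0
    differential_duplicates_collapsed: int = 0
    differential_conflicts_dropped: int = 0


def preprocess(corpus: Corpus, cfg: Optional[FilterConfig] = None) -> tuple[Corpus, PreprocessReport]:
    """Apply the Class-I filter and collapse duplicate (site, dataset) rows.

    * Profiling rows failing the Class-I criterion are excluded.
    * Duplicate profiling rows keep the maximum loc_prob / ascore.
    * Duplicate differential rows: if the duplicates imply both a U and a D
      call (distinct multiply-phosphorylated peptides), the call with the
      smaller p-value wins; an exact p-value tie is a conflict and the
      (site, dataset) group is dropped from co-regulation counting. Otherwise
      the row with the most extreme fold change is kept.
    """
    cfg = cfg or FilterConfig()
    report = PreprocessReport()

    prof = corpus.profiling
    if len(prof):
        keep = prof.apply(lambda r: is_class1(r["loc_prob"], r["ascore"], cfg), axis=1)
        report.profiling_not_class1 = int((~keep).sum())
        prof = prof[keep]
        before = len(prof)
        prof = (
            prof.sort_values(["loc_prob", "ascore"], na_position="first")
            .groupby(["dataset_id", "site"], as_index=False, sort=False)
            .last()
        )
        prof = prof.loc[:, corpus.profiling.columns]
        report.profiling_duplicates_collapsed = before - len(prof)

    diff = corpus.differential
    if len(diff):
        diff = diff.copy()
        kept_rows = []
        n_conflicts = 0
        n_dups = 0
        grouped = diff.groupby(["dataset_id", "site"], sort=False)
        for _, grp in grouped:
            if len(grp) == 1:
                kept_rows.append(grp.index[0])
                continue
            n_dups += len(grp) - 1
            called = grp[grp["call"] != CALL_NONE]
            calls = set(called["call"])
            if len(calls) == 2:
                pmin = called.groupby("call")["p_value"].min()
                if pmin["U"] == pmin["D"]:
                    n_conflicts += 1
                    n_dups -= len(grp) - 1
                    continue
                winner = pmin.idxmin()
                sub = called[called["call"] == winner]
                kept_rows.append(sub["p_value"].idxmin())
            elif len(calls) == 1:
                sub = called
                extreme = (
                    sub["fold_change"].idxmax()
                    if calls == {"U"}
                    else sub["fold_change"].idxmin()
                )
                kept_rows.append(extreme)
            else:
                dev = (np.log(grp["fold_change"])).abs()
                kept_rows.append(dev.idxmax())
        report.differential_duplicates_collapsed = n_dups
        report.differential_conflicts_dropped = n_conflicts
        diff = diff.loc[sorted(kept_rows)]

    out = Corpus(
        datasets=corpus.datasets.copy(),
        profiling=prof.reset_index(drop=True),
        differential=diff.reset_index(drop=True),
    )
    out.validate()
    return out, report


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


@dataclass
class HarmonizationReport:
    """Counts of records dropped or re-keyed during harmonization."""

    genes_remapped: int = 0
    dropped_unmapped_gene: int = 0
    dropped_unmapped_accession: int = 0


def _as_mapping(table: Union[Mapping[str, str], pd.DataFrame], key: str, value: str) -> dict:
    if isinstance(table, pd.DataFrame):
        if key not in table.columns or value not in table.columns:
            raise SchemaError(f"mapping table must have columns {key!r} and {value!r}")
        return dict(zip(table[key].astype(str), table[value].astype(str)))
    return dict(table)


def harmonize(
    corpus: Corpus,
    gene_map: Union[Mapping[str, str], pd.DataFrame],
    accession_map: Union[Mapping[str, str], pd.DataFrame],
) -> tuple[Corpus, HarmonizationReport]:
    """Re-key records to canonical HGNC-style symbols and accessions.

    ``gene_map`` maps aliases to canonical symbols (``alias`` -> ``symbol``
    columns when a DataFrame); a gene already appearing as a canonical symbol
    is kept as-is. ``accession_map`` maps symbols to accessions. Records whose
    gene cannot be mapped to a canonical symbol, or whose symbol has no
    accession, are dropped and counted.
    """
    gmap = _as_mapping(gene_map, "alias", "symbol")
    amap = _as_mapping(accession_map, "symbol", "accession")
    if not gmap:
        raise ConfigError("gene mapping table is empty")
    if not amap:
        raise ConfigError("accession mapping table is empty")
    canonical = set(gmap.values())
    report = HarmonizationReport()

    def map_frame(df: pd.DataFrame) -> pd.DataFrame:
        if not len(df):
            return df.copy()
        out = df.copy()
        mapped = out["gene"].map(gmap)
        already = out["gene"].isin(canonical)
        new_gene = mapped.where(mapped.notna(), out["gene"].where(already))
        report.genes_remapped += int((mapped.notna() & (mapped != out["gene"])).sum())
        lost_gene = new_gene.isna()
        report.dropped_unmapped_gene += int(lost_gene.sum())
        out = out[~lost_gene].copy()
        out["gene"] = new_gene[~lost_gene]
        acc = out["gene"].map(amap)
        lost_acc = acc.isna()
        report.dropped_unmapped_accession += int(lost_acc.sum())
        out = out[~lost_acc].copy()
        out["accession"] = acc[~lost_acc]
        if len(out):
            out["site"] = out["gene"] + "_" + out["residue"] + out["position"].astype(str)
        return out.reset_index(drop=True)

    out = Corpus(
        datasets=corpus.datasets.copy(),
        profiling=map_frame(corpus.profiling),
        differential=map_frame(corpus.differential),
    )
    out.validate()
    if report.dropped_unmapped_gene or report.dropped_unmapped_accession:
        logger.info(
            "harmonize: dropped %d record(s) with unmapped gene, %d with unmapped accession",
            report.dropped_unmapped_gene,
            report.dropped_unmapped_accession,
        )
    return out, report


# ---------------------------------------------------------------------------
# key = value configuration files
# ---------------------------------------------------------------------------


def read_keyvalue_config(path: Union[str, Path]) -> dict[str, list[str]]:
    """Parse a ``key = value`` text file; repeated keys accumulate into lists.

    Lines starting with ``#`` and blank lines are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    out: dict[str, list[str]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        out.setdefault(key.strip(), []).append(value.strip())
    return out


def scalar(cfg: dict[str, list[str]], key: str, default: Optional[str] = None) -> Optional[str]:
    """Single-valued lookup in a parsed key=value config."""
    values = cfg.get(key)
    if not values:
        return default
    if len(values) > 1:
        raise ConfigError(f"config key {key!r} given {len(values)} times, expected once")
    return values[0]


def filter_config_from_mapping(cfg: dict[str, list[str]]) -> FilterConfig:
    """Build a FilterConfig from a parsed key=value config (unknown keys ignored)."""
    kwargs = {}
    for f in dc_fields(FilterConfig):
        raw = scalar(cfg, f.name)
        if raw is None:
            continue
        kwargs[f.name] = int(raw) if f.type == "int" else float(raw)
    return FilterConfig(**kwargs)


def write_filter_config(cfg: FilterConfig, path: Union[str, Path]) -> None:
    lines = [f"{f.name} = {getattr(cfg, f.name)}" for f in dc_fields(FilterConfig)]
    Path(path).write_text("\n".join(lines) + "\n")
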