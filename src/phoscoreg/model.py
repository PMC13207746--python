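"""Core domain model for multi-study phosphoproteomic corpora.

A *corpus* integrates condition-level datasets from many published studies.
Each dataset is one biological/experimental condition and is either

* **profiling** — a qualitative list of phosphosites identified under that
  condition, each with a localization confidence (localization probability
  and/or A-score), or
* **differential** — a quantitative test-vs-control comparison giving a fold
  change and p-value per phosphosite.

Sites are identified by HGNC gene symbol, UniProt-style accession, residue
letter (S/T/Y) and 1-based position, written as tokens like ``CAV1_Y14``.

The bulk representation of a corpus is three pandas DataFrames (dataset
metadata, profiling records, differential records); the record dataclasses
here define the per-row contracts and are used for validation and for typed
construction in tests.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "RESIDUES",
    "CALL_UP",
    "CALL_DOWN",
    "CALL_NONE",
    "SiteTokenError",
    "ValidationError",
    "SchemaError",
    "ConfigError",
    "PhosphositeID",
    "parse_site_token",
    "format_site_token",
    "DatasetMeta",
    "ProfilingRecord",
    "DifferentialRecord",
    "FilterConfig",
    "is_class1",
    "call_regulation",
    "call_regulation_frame",
    "Corpus",
]

RESIDUES = ("S", "T", "Y")

CALL_UP = "U"
CALL_DOWN = "D"
CALL_NONE = "none"

DATASET_COLUMNS = ["dataset_id", "pmid", "condition_code", "dataset_type", "enrichment"]
PROFILING_COLUMNS = ["dataset_id", "gene", "accession", "residue", "position", "loc_prob", "ascore"]
DIFFERENTIAL_COLUMNS = ["dataset_id", "gene", "accession", "residue", "position", "fold_change", "p_value"]

DATASET_TYPES = ("profiling", "differential")
ENRICHMENT_METHODS = ("STY", "ST", "Y")


class SiteTokenError(ValueError):
    """A phosphosite token could not be parsed."""


class ValidationError(ValueError):
    """A domain invariant was violated."""


class SchemaError(ValueError):
    """An input table is missing columns or carries inconsistent values."""


class ConfigError(ValueError):
    """A configuration (mapping table, simulation config, run config) is invalid."""


@dataclass(frozen=True, order=True)
class PhosphositeID:
    """Canonical identity of one phosphosite.

    The accession rides along for provenance but does not take part in
    equality or ordering: two records that agree on gene, residue and
    position denote the same site.
    """

    gene: str
    residue: str
    position: int
    accession: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("phosphosite gene symbol must be nonempty")
        if self.residue not in RESIDUES:
            raise ValidationError(
                f"phosphosite residue must be one of {RESIDUES}, got {self.residue!r}"
            )
        if not isinstance(self.position, (int, np.integer)) or isinstance(self.position, bool):
            raise ValidationError(f"phosphosite position must be an integer, got {self.position!r}")
        if self.position < 1:
            raise ValidationError(f"phosphosite position must be >= 1, got {self.position}")

    @property
    def token(self) -> str:
        return f"{self.gene}_{self.residue}{self.position}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


_TOKEN_RE = re.compile(r"^(?P<gene>.+)_(?P<residue>[A-Za-z])(?P<position>\d+)$")


def parse_site_token(token: str, accession: str = "") -> PhosphositeID:
    """Parse a ``GENE_R<pos>`` token (e.g. ``CAV1_Y14``) into a :class:`PhosphositeID`.

    Gene symbols are uppercased. The residue letter must be S, T or Y and the
    position a positive integer. Raises :class:`SiteTokenError` naming the
    offending token otherwise.
    """
    if not token or not isinstance(token, str):
        raise SiteTokenError(f"empty or non-string phosphosite token: {token!r}")
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise SiteTokenError(
            f"malformed phosphosite token {token!r}: expected '<gene>_<residue><position>'"
        )
    gene = m.group("gene").upper()
    residue = m.group("residue").upper()
    position = int(m.group("position"))
    if residue not in RESIDUES:
        raise SiteTokenError(
            f"invalid residue {residue!r} in token {token!r}: must be one of {RESIDUES}"
        )
    if position < 1:
        raise SiteTokenError(f"invalid position {position} in token {token!r}: must be >= 1")
    return PhosphositeID(gene=gene, residue=residue, position=position, accession=accession)


def format_site_token(site: PhosphositeID) -> str:
    """Canonical token form of a site; inverse of :func:`parse_site_token`."""
    return site.token


def as_site(site: Union[str, PhosphositeID]) -> PhosphositeID:
    """Coerce a token string or PhosphositeID to a PhosphositeID."""
    if isinstance(site, PhosphositeID):
        return site
    return parse_site_token(site)


@dataclass(frozen=True)
class DatasetMeta:
    """One condition-level dataset: a study (PMID) x experimental-condition unit."""

    dataset_id: str
    study_pmid: str
    condition_code: str
    dataset_type: str
    enrichment: str = "STY"

    def __post_init__(self) -> None:
        if self.dataset_type not in DATASET_TYPES:
            raise ValidationError(
                f"dataset_type must be one of {DATASET_TYPES}, got {self.dataset_type!r}"
            )
        if self.enrichment not in ENRICHMENT_METHODS:
            raise ValidationError(
                f"enrichment must be one of {ENRICHMENT_METHODS}, got {self.enrichment!r}"
            )


@dataclass(frozen=True)
class ProfilingRecord:
    """Identification of a site in one profiling dataset, with localization confidence."""

    dataset_id: str
    site: PhosphositeID
    loc_prob: Optional[float] = None
    ascore: Optional[float] = None

    def __post_init__(self) -> None:
        if _absent(self.loc_prob) and _absent(self.ascore):
            raise ValidationError(
                f"profiling record for {self.site.token} in {self.dataset_id}: "
                "at least one of loc_prob / ascore must be present"
            )
        if not _absent(self.loc_prob) and not (0.0 <= self.loc_prob <= 1.0):
            raise ValidationError(f"loc_prob must be in [0, 1], got {self.loc_prob}")
        if not _absent(self.ascore) and self.ascore < 0:
            raise ValidationError(f"ascore must be nonnegative, got {self.ascore}")


@dataclass(frozen=True)
class DifferentialRecord:
    """One site's regulation evidence in one differential dataset."""

    dataset_id: str
    site: PhosphositeID
    fold_change: float
    p_value: float
    call: str = CALL_NONE

    def __post_init__(self) -> None:
        if not (self.fold_change > 0) or math.isnan(self.fold_change):
            raise ValidationError(f"fold_change must be positive, got {self.fold_change}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value must be in [0, 1], got {self.p_value}")

    @classmethod
    def with_call(
        cls, dataset_id: str, site: PhosphositeID, fold_change: float, p_value: float, cfg: "FilterConfig"
    ) -> "DifferentialRecord":
        rec = cls(dataset_id, site, fold_change, p_value)
        return replace(rec, call=call_regulation(fold_change, p_value, cfg))


def _absent(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class FilterConfig:
    """All thresholds of the analysis.

    Attributes
    ----------
    loc_prob_min:
        Minimum localization probability for a Class-I site (inclusive).
    ascore_min:
        A-score cutoff for a Class-I site; strictly exclusive (``ascore > 13``).
    up_threshold, down_threshold:
        Fold-change thresholds defining up-/down-regulation
        (``fc >= 1.3`` up, ``fc <= 0.76`` down), both combined with
        ``p < p_threshold``.
    p_threshold:
        Significance cutoff for a differential call.
    min_pmids, min_codes:
        Reproducibility filters: distinct publications / distinct
        experimental-condition codes that must support a result.
    freq_ratio_min:
        Minimum co-regulation frequency relative to the predominant site's
        total differential frequency.
    fet_alpha:
        Raw one-sided Fisher's-exact significance level for the PsOP screen.
    """

    loc_prob_min: float = 0.75
    ascore_min: float = 13.0
    up_threshold: float = 1.3
    down_threshold: float = 0.76
    p_threshold: float = 0.05
    min_pmids: int = 3
    min_codes: int = 3
    freq_ratio_min: float = 0.10
    fet_alpha: float = 0.05

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ValidationError(f"FilterConfig.{f.name} must be positive, got {v}")
        if not (self.up_threshold > 1.0 > self.down_threshold):
            raise ValidationError(
                "FilterConfig requires up_threshold > 1 > down_threshold, got "
                f"{self.up_threshold} / {self.down_threshold}"
            )


def is_class1(
    loc_prob: Optional[float], ascore: Optional[float], cfg: Optional[FilterConfig] = None
) -> bool:
    """Class-I localization test.

    True iff the localization probability is >= ``loc_prob_min`` (inclusive)
    or the A-score is > ``ascore_min`` (strict). NaN counts as absent; both
    absent is a :class:`ValidationError`.
    """
    cfg = cfg or FilterConfig()
    lp_absent, as_absent = _absent(loc_prob), _absent(ascore)
    if lp_absent and as_absent:
        raise ValidationError("is_class1 requires at least one of loc_prob / ascore")
    if not lp_absent and loc_prob >= cfg.loc_prob_min:
        return True
    if not as_absent and ascore > cfg.ascore_min:
        return True
    return False


def call_regulation(fold_change: float, p_value: float, cfg: Optional[FilterConfig] = None) -> str:
    """Differential-regulation call for one (fold change, p-value) pair.

    Returns ``"U"`` iff ``fc >= up_threshold`` and ``p < p_threshold``,
    ``"D"`` iff ``fc <= down_threshold`` and ``p < p_threshold``,
    ``"none"`` otherwise. Fold change is a treatment/control ratio and must
    be positive.
    """
    cfg = cfg or FilterConfig()
    if _absent(fold_change) or not (fold_change > 0):
        raise ValidationError(f"fold_change must be positive, got {fold_change!r}")
    if _absent(p_value) or not (0.0 <= p_value <= 1.0):
        raise ValidationError(f"p_value must be in [0, 1], got {p_value!r}")
    if p_value < cfg.p_threshold:
        if fold_change >= cfg.up_threshold:
            return CALL_UP
        if fold_change <= cfg.down_threshold:
            return CALL_DOWN
    return CALL_NONE


def call_regulation_frame(
    fold_change: pd.Series, p_value: pd.Series, cfg: Optional[FilterConfig] = None
) -> pd.Series:
    """Vectorized :func:`call_regulation` over aligned Series."""
    cfg = cfg or FilterConfig()
    fc = fold_change.astype(float)
    p = p_value.astype(float)
    if (fc <= 0).any() or fc.isna().any():
        bad = fc[(fc <= 0) | fc.isna()].index[:5].tolist()
        raise ValidationError(f"nonpositive or missing fold_change at rows {bad}")
    if ((p < 0) | (p > 1)).any() or p.isna().any():
        bad = p[(p < 0) | (p > 1) | p.isna()].index[:5].tolist()
        raise ValidationError(f"p_value outside [0, 1] at rows {bad}")
    sig = p < cfg.p_threshold
    out = pd.Series(CALL_NONE, index=fc.index, dtype=object)
    out[sig & (fc >= cfg.up_threshold)] = CALL_UP
    out[sig & (fc <= cfg.down_threshold)] = CALL_DOWN
    return out


def _site_tokens(df: pd.DataFrame) -> pd.Series:
    return df["gene"].astype(str) + "_" + df["residue"].astype(str) + df["position"].astype(int).astype(str)


@dataclass
class Corpus:
    """A harmonized multi-study corpus.

    ``datasets`` has one row per condition-level dataset; ``profiling`` and
    ``differential`` have one row per (site, dataset). Record frames carry a
    derived ``site`` token column and ``differential`` a derived ``call``
    column.
    """

    datasets: pd.DataFrame
    profiling: pd.DataFrame
    differential: pd.DataFrame

    @classmethod
    def assemble(
        cls,
        datasets: pd.DataFrame,
        profiling: pd.DataFrame,
        differential: pd.DataFrame,
        cfg: Optional[FilterConfig] = None,
    ) -> "Corpus":
        """Normalize dtypes, derive ``site`` / ``call`` columns and validate."""
        cfg = cfg or FilterConfig()
        datasets = datasets.loc[:, DATASET_COLUMNS].copy()
        for col in ("dataset_id", "pmid", "condition_code", "dataset_type", "enrichment"):
            datasets[col] = datasets[col].astype(str)

        profiling = profiling.loc[:, PROFILING_COLUMNS].copy()
        differential = differential.loc[:, DIFFERENTIAL_COLUMNS].copy()
        for df in (profiling, differential):
            for col in ("dataset_id", "gene", "accession", "residue"):
                df[col] = df[col].astype(str)
            df["gene"] = df["gene"].str.upper()
            df["residue"] = df["residue"].str.upper()
            df["position"] = df["position"].astype(int)
        # astype(float) is round-trip exact for decimal strings; to_numeric is not
        profiling["loc_prob"] = profiling["loc_prob"].astype(float)
        profiling["ascore"] = profiling["ascore"].astype(float)
        differential["fold_change"] = differential["fold_change"].astype(float)
        differential["p_value"] = differential["p_value"].astype(float)

        if len(profiling):
            profiling["site"] = _site_tokens(profiling)
        else:
            profiling["site"] = pd.Series(dtype=object)
        if len(differential):
            differential["site"] = _site_tokens(differential)
            differential["call"] = call_regulation_frame(
                differential["fold_change"], differential["p_value"], cfg
            )
        else:
            differential["site"] = pd.Series(dtype=object)
            differential["call"] = pd.Series(dtype=object)

        corpus = cls(datasets=datasets.reset_index(drop=True),
                     profiling=profiling.reset_index(drop=True),
                     differential=differential.reset_index(drop=True))
        corpus.validate()
        return corpus

    def validate(self) -> None:
        """Check referential integrity and per-record invariants."""
        ds = self.datasets
        if ds["dataset_id"].duplicated().any():
            dup = ds.loc[ds["dataset_id"].duplicated(), "dataset_id"].iloc[0]
            raise ValidationError(f"duplicate dataset_id {dup!r} in datasets table")
        bad_type = ~ds["dataset_type"].isin(DATASET_TYPES)
        if bad_type.any():
            raise ValidationError(
                f"invalid dataset_type values: {sorted(ds.loc[bad_type, 'dataset_type'].unique())}"
            )
        bad_enr = ~ds["enrichment"].isin(ENRICHMENT_METHODS)
        if bad_enr.any():
            raise ValidationError(
                f"invalid enrichment values: {sorted(ds.loc[bad_enr, 'enrichment'].unique())}"
            )
        prof_ids = set(ds.loc[ds["dataset_type"] == "profiling", "dataset_id"])
        diff_ids = set(ds.loc[ds["dataset_type"] == "differential", "dataset_id"])
        for name, df, allowed in (
            ("profiling", self.profiling, prof_ids),
            ("differential", self.differential, diff_ids),
        ):
            if not len(df):
                continue
            unknown = ~df["dataset_id"].isin(allowed)
            if unknown.any():
                bad = df.loc[unknown, "dataset_id"].iloc[0]
                raise ValidationError(
                    f"{name} record references dataset_id {bad!r} that is not a "
                    f"{name}-type dataset in the metadata table"
                )
            bad_res = ~df["residue"].isin(RESIDUES)
            if bad_res.any():
                raise ValidationError(
                    f"{name} records with residue outside {RESIDUES}: "
                    f"{sorted(df.loc[bad_res, 'residue'].unique())}"
                )
            if (df["position"] < 1).any():
                raise ValidationError(f"{name} records with position < 1")
        if len(self.profiling):
            both_absent = self.profiling["loc_prob"].isna() & self.profiling["ascore"].isna()
            if both_absent.any():
                n = int(both_absent.sum())
                raise ValidationError(
                    f"{n} profiling record(s) with neither loc_prob nor ascore present"
                )
        if len(self.differential):
            if (self.differential["fold_change"] <= 0).any():
                raise ValidationError("differential records with nonpositive fold_change")
            p = self.differential["p_value"]
            if ((p < 0) | (p > 1)).any():
                raise ValidationError("differential records with p_value outside [0, 1]")

    # -- convenience accessors -------------------------------------------------

    @property
    def differential_dataset_ids(self) -> pd.Index:
        """IDs of all differential-type datasets (including ones with no records)."""
        ds = self.datasets
        return pd.Index(ds.loc[ds["dataset_type"] == "differential", "dataset_id"])

    @property
    def n_differential_datasets(self) -> int:
        return int((self.datasets["dataset_type"] == "differential").sum())

    @property
    def n_profiling_datasets(self) -> int:
        return int((self.datasets["dataset_type"] == "profiling").sum())

    def dataset_meta_lookup(self) -> pd.DataFrame:
        """datasets table indexed by dataset_id."""
        return self.datasets.set_index("dataset_id")

    def copy(self) -> "Corpus":
        return Corpus(self.datasets.copy(), self.profiling.copy(), self.differential.copy())

    def equals(self, other: "Corpus") -> bool:
        """Equality up to row order."""

        def norm(df: pd.DataFrame) -> pd.DataFrame:
            return df.sort_values(list(df.columns)).reset_index(drop=True)

        return (
            norm(self.datasets).equals(norm(other.datasets))
            and norm(self.profiling).equals(norm(other.profiling))
            and norm(self.differential).equals(norm(other.differential))
        )
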