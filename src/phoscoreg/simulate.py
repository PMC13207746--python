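"""Synthetic multi-study phosphoproteomic corpora with planted co-regulation.

The generator emulates the structure of a curated corpus: a set of studies
(PMIDs), each contributing several experimental conditions; every condition
yields one profiling dataset and one differential dataset. Per condition,
each phosphosite is detected independently with its detection probability.
A *planted pair* links a partner site to an anchor site: whenever the anchor
is detected, the partner is co-detected with probability ``co_detect_prob``
and, when co-detected, its regulation sign is drawn concordant with the
anchor's with probability ``rho`` (both up or both down) and discordant
otherwise. The co-detection event is conditional on the anchor so that one
predominant site can anchor many pairs without its own detection saturating.

Fold changes are drawn log-normally around the configured effect sizes and
truncated to stay beyond the call thresholds, so a record's call is decided
by its p-value: sites that are members of planted pairs (or declared
predominant) draw p ~ U(0, p_threshold) and are therefore always called when
detected, while null sites draw p ~ U(0, 1) and are called only when they
land below the significance threshold, mimicking background regulation.

Profiling datasets mirror detection, with localization probabilities drawn
uniformly in [0.75, 1] (all Class I).

Randomness is a single :class:`numpy.random.SeedSequence` seeded once, with
one spawned child stream per condition, so corpora are reproducible and
stable under any per-condition parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import RESIDUES, ConfigError, Corpus, FilterConfig, parse_site_token

__all__ = [
    "PlantedPair",
    "SyntheticConfig",
    "TruthTable",
    "auto_gene",
    "auto_site_token",
    "generate_corpus",
    "planted_truth",
    "default_study_config",
    "calibration_config",
]


@dataclass(frozen=True)
class PlantedPair:
    """A pair of sites with planted joint detection and concordance structure."""

    site_a: str  # anchor site token; co-detection is conditional on this site
    site_b: str
    rho: float  # P(concordant call | co-detected)
    co_detect_prob: float  # P(partner forced detected | anchor detected)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ConfigError(f"planted pair rho must be in [0, 1], got {self.rho}")
        if not (0.0 <= self.co_detect_prob <= 1.0):
            raise ConfigError(
                f"planted pair co_detect_prob must be in [0, 1], got {self.co_detect_prob}"
            )
        if self.site_a == self.site_b:
            raise ConfigError(f"planted pair must link two distinct sites, got {self.site_a}")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic corpus.

    ``predominant_sites`` declares extra sites (token, detection probability)
    on top of the automatic protein roster; planted pairs must reference
    declared or roster sites. ``conditions_per_study`` and
    ``sites_per_protein`` are inclusive integer ranges.
    """

    n_studies: int = 5
    conditions_per_study: tuple[int, int] = (12, 12)
    n_proteins: int = 120
    sites_per_protein: tuple[int, int] = (2, 2)
    base_detect_prob: float = 0.2
    predominant_sites: list[tuple[str, float]] = field(default_factory=list)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    effect_fc_up: float = 1.8
    effect_fc_down: float = 0.55
    fc_sigma: float = 0.2
    seed: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_proteins < 0:
            raise ConfigError("n_studies must be >= 1 and n_proteins >= 0")
        lo, hi = self.conditions_per_study
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid conditions_per_study range {self.conditions_per_study}")
        lo, hi = self.sites_per_protein
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid sites_per_protein range {self.sites_per_protein}")
        if not (0.0 <= self.base_detect_prob <= 1.0):
            raise ConfigError(f"base_detect_prob must be in [0, 1], got {self.base_detect_prob}")
        if self.effect_fc_up < self.filters.up_threshold:
            raise ConfigError(
                f"effect_fc_up {self.effect_fc_up} below up_threshold {self.filters.up_threshold}:"
                " planted calls would not survive call_regulation"
            )
        if self.effect_fc_down > self.filters.down_threshold:
            raise ConfigError(
                f"effect_fc_down {self.effect_fc_down} above down_threshold"
                f" {self.filters.down_threshold}: planted calls would not survive call_regulation"
            )
        for token, p in self.predominant_sites:
            parse_site_token(token)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"detect_prob for {token} must be in [0, 1], got {p}")


def auto_gene(i: int) -> str:
    """Gene symbol of the i-th automatic roster protein (1-based)."""
    return f"P{i:04d}"


def auto_site_token(i: int, k: int) -> str:
    """Token of the k-th site (0-based) of the i-th roster protein (1-based).

    The roster layout is deterministic (no RNG): residues cycle S/T/Y with
    the protein index, positions step by 10.
    """
    residue = RESIDUES[(i + k) % 3]
    return f"{auto_gene(i)}_{residue}{10 * (k + 1)}"


def _site_roster(cfg: SyntheticConfig) -> pd.DataFrame:
    """One row per generated site: gene, accession, residue, position, token, detect_prob."""
    rows = []
    lo, hi = cfg.sites_per_protein
    span = hi - lo + 1
    for i in range(1, cfg.n_proteins + 1):
        n_sites = lo + ((i - 1) % span)
        for k in range(n_sites):
            site = parse_site_token(auto_site_token(i, k))
            rows.append((site.gene, site.residue, site.position, cfg.base_detect_prob))
    for token, p in cfg.predominant_sites:
        site = parse_site_token(token)
        rows.append((site.gene, site.residue, site.position, p))
    roster = pd.DataFrame(rows, columns=["gene", "residue", "position", "detect_prob"])
    dup = roster.duplicated(subset=["gene", "residue", "position"], keep="last")
    roster = roster[~dup].reset_index(drop=True)
    roster["accession"] = "X" + roster["gene"].str.replace(r"\W", "", regex=True)
    roster["site"] = roster["gene"] + "_" + roster["residue"] + roster["position"].astype(str)
    return roster


def _resolve_pairs(cfg: SyntheticConfig, roster: pd.DataFrame) -> list[tuple[int, int, float, float]]:
    index = {tok: i for i, tok in enumerate(roster["site"])}
    resolved = []
    for pair in cfg.planted_pairs:
        for tok in (pair.site_a, pair.site_b):
            if tok not in index:
                raise ConfigError(
                    f"planted pair references unknown site {tok!r}: not in the generated roster"
                )
        resolved.append((index[pair.site_a], index[pair.site_b], pair.rho, pair.co_detect_prob))
    return resolved


@dataclass
class TruthTable:
    """Evaluable restatement of the planted structure (no randomness).

    ``pairs`` carries per planted pair the concordance ``rho``, the
    co-detection probability and the expected co-regulation sign;
    ``sites`` carries per site its configured detection probability and the
    expected marginal detection frequency (per condition) once co-detection
    through planted pairs is accounted for.
    """

    pairs: pd.DataFrame
    sites: pd.DataFrame


def planted_truth(cfg: SyntheticConfig) -> TruthTable:
    roster = _site_roster(cfg)
    pairs = pd.DataFrame(
        [
            {
                "site_a": p.site_a,
                "site_b": p.site_b,
                "rho": p.rho,
                "co_detect_prob": p.co_detect_prob,
                "expected_sign": "positive" if p.rho > 0.5 else ("negative" if p.rho < 0.5 else "none"),
            }
            for p in cfg.planted_pairs
        ],
        columns=["site_a", "site_b", "rho", "co_detect_prob", "expected_sign"],
    )
    _resolve_pairs(cfg, roster)  # validates references
    detect = dict(zip(roster["site"], roster["detect_prob"]))
    marginal = {}
    for tok, p in detect.items():
        miss = 1.0 - p
        for pair in cfg.planted_pairs:
            if pair.site_b == tok:
                miss *= 1.0 - detect[pair.site_a] * pair.co_detect_prob
        marginal[tok] = 1.0 - miss
    sites = roster.loc[:, ["site", "detect_prob"]].copy()
    sites["expected_detect_freq"] = sites["site"].map(marginal)
    return TruthTable(pairs=pairs, sites=sites)


def generate_corpus(cfg: SyntheticConfig) -> tuple[Corpus, TruthTable]:
    """Generate a corpus with the planted structure of ``cfg``; deterministic given seed."""
    roster = _site_roster(cfg)
    pairs = _resolve_pairs(cfg, roster)
    truth = planted_truth(cfg)

    planted_tokens = {p.site_a for p in cfg.planted_pairs} | {p.site_b for p in cfg.planted_pairs}
    planted_tokens |= {tok for tok, _ in cfg.predominant_sites}
    planted_mask = roster["site"].isin(planted_tokens).to_numpy()

    detect_prob = roster["detect_prob"].to_numpy()
    n_sites = len(roster)
    fcfg = cfg.filters

    ss = np.random.SeedSequence(cfg.seed)
    layout_ss, data_ss = ss.spawn(2)
    layout_rng = np.random.default_rng(layout_ss)
    lo, hi = cfg.conditions_per_study
    cond_counts = layout_rng.integers(lo, hi + 1, size=cfg.n_studies)
    total_conditions = int(cond_counts.sum())
    children = data_ss.spawn(total_conditions)

    meta_rows = []
    prof_parts = []
    diff_parts = []
    k = 0
    for s in range(cfg.n_studies):
        pmid = f"PMID{90000000 + s + 1}"
        for j in range(cond_counts[s]):
            code = f"S{s + 1:02d}C{j + 1:02d}"
            prof_id, diff_id = f"{code}P", f"{code}Q"
            meta_rows.append((prof_id, pmid, code, "profiling", "STY"))
            meta_rows.append((diff_id, pmid, code, "differential", "STY"))

            rng = np.random.default_rng(children[k])
            k += 1
            detected = rng.random(n_sites) < detect_prob
            up = rng.random(n_sites) < 0.5  # tentative sign for every site
            for ia, ib, rho, co_p in pairs:
                if detected[ia] and rng.random() < co_p:
                    detected[ib] = True
                    concordant = rng.random() < rho
                    up[ib] = up[ia] if concordant else not up[ia]

            idx = np.flatnonzero(detected)
            if idx.size == 0:
                continue
            loc_prob = rng.uniform(0.75, 1.0, size=idx.size)
            fc = np.where(
                up[idx],
                np.maximum(rng.lognormal(np.log(cfg.effect_fc_up), cfg.fc_sigma, idx.size),
                           fcfg.up_threshold),
                np.minimum(rng.lognormal(np.log(cfg.effect_fc_down), cfg.fc_sigma, idx.size),
                           fcfg.down_threshold),
            )
            p_null = rng.uniform(0.0, 1.0, size=idx.size)
            p_planted = rng.uniform(0.0, fcfg.p_threshold, size=idx.size)
            p = np.where(planted_mask[idx], p_planted, p_null)

            sub = roster.iloc[idx]
            prof_parts.append(
                pd.DataFrame(
                    {
                        "dataset_id": prof_id,
                        "gene": sub["gene"].to_numpy(),
                        "accession": sub["accession"].to_numpy(),
                        "residue": sub["residue"].to_numpy(),
                        "position": sub["position"].to_numpy(),
                        "loc_prob": loc_prob,
                        "ascore": np.nan,
                    }
                )
            )
            diff_parts.append(
                pd.DataFrame(
                    {
                        "dataset_id": diff_id,
                        "gene": sub["gene"].to_numpy(),
                        "accession": sub["accession"].to_numpy(),
                        "residue": sub["residue"].to_numpy(),
                        "position": sub["position"].to_numpy(),
                        "fold_change": fc,
                        "p_value": p,
                    }
                )
            )

    datasets = pd.DataFrame(
        meta_rows, columns=["dataset_id", "pmid", "condition_code", "dataset_type", "enrichment"]
    )
    profiling = (
        pd.concat(prof_parts, ignore_index=True)
        if prof_parts
        else pd.DataFrame(columns=["dataset_id", "gene", "accession", "residue", "position", "loc_prob", "ascore"])
    )
    differential = (
        pd.concat(diff_parts, ignore_index=True)
        if diff_parts
        else pd.DataFrame(columns=["dataset_id", "gene", "accession", "residue", "position", "fold_change", "p_value"])
    )
    corpus = Corpus.assemble(datasets, profiling, differential, cfg.filters)
    return corpus, truth


# ---------------------------------------------------------------------------
# canonical study configurations
# ---------------------------------------------------------------------------

N_PLANTED_PAIRS = 20
N_NULL_PROTEINS = 100  # proteins 21..120, two sites each -> 200 null sites
ANCHOR_SITE = "CAV1_Y14"
SECOND_SITE = "CAV1_S37"
ANCHOR_DETECT_PROB = 0.5
SECOND_DETECT_PROB = 0.6


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """The canonical synthetic study corpus.

    Five studies x twelve conditions (60 differential datasets); a target
    protein (named CAV1 for familiarity) with two predominant sites; twenty
    partner sites on distinct proteins planted at rho = 0.95 with
    co-detection 0.6; two hundred null sites on a further hundred proteins.
    Detection probabilities sit in the range the field reports for
    frequently-observed sites (anchor 0.5, background 0.2).
    """
    pairs = [
        PlantedPair(ANCHOR_SITE, auto_site_token(i, 0), rho=0.95, co_detect_prob=0.6)
        for i in range(1, N_PLANTED_PAIRS + 1)
    ]
    # intra-protein pair: the two predominant sites tend to move together
    pairs.append(PlantedPair(ANCHOR_SITE, SECOND_SITE, rho=0.75, co_detect_prob=0.5))
    return SyntheticConfig(
        n_studies=5,
        conditions_per_study=(12, 12),
        n_proteins=N_PLANTED_PAIRS + N_NULL_PROTEINS,
        sites_per_protein=(2, 2),
        base_detect_prob=0.2,
        predominant_sites=[(ANCHOR_SITE, ANCHOR_DETECT_PROB), (SECOND_SITE, SECOND_DETECT_PROB)],
        planted_pairs=pairs,
        seed=seed,
    )


def null_site_tokens() -> list[str]:
    """The 200 sites of the default study corpus with no planted structure."""
    return [
        auto_site_token(i, k)
        for i in range(N_PLANTED_PAIRS + 1, N_PLANTED_PAIRS + N_NULL_PROTEINS + 1)
        for k in range(2)
    ]


def planted_partner_tokens() -> list[str]:
    """The 20 planted partner sites of the default study corpus."""
    return [auto_site_token(i, 0) for i in range(1, N_PLANTED_PAIRS + 1)]


def calibration_config(rhos: Sequence[float], n_conditions: int = 600, seed: int = 0) -> SyntheticConfig:
    """Corpus for concordance calibration: one pure planted pair per rho.

    Anchors are declared with detection probability 1 and co-detection 1, so
    every condition contributes to the pair's pattern counts and the
    conditional concordance equals rho exactly.
    """
    preds = []
    pairs = []
    for r, rho in enumerate(rhos):
        a = f"ANC{r + 1}_S{10 * (r + 1)}"
        b = f"PRT{r + 1}_T{10 * (r + 1)}"
        preds += [(a, 1.0), (b, 0.0)]
        pairs.append(PlantedPair(a, b, rho=rho, co_detect_prob=1.0))
    per_study = n_conditions // 5
    return SyntheticConfig(
        n_studies=5,
        conditions_per_study=(per_study, per_study),
        n_proteins=0,
        base_detect_prob=0.0,
        predominant_sites=preds,
        planted_pairs=pairs,
        seed=seed,
    )
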