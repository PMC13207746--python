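"""End-to-end orchestration: corpus -> predominance -> co-occurrence -> PsOP -> crossref.

A run is described by a ``key = value`` config file; outputs are TSV tables
plus a JSON run summary whose counts mirror the written tables row for row.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import crossref as xref
from . import io as pio
from . import simulate as sim
from .cooccurrence import cooccurrence_matrix
from .model import ConfigError
from .predominance import predominant_sites, rank_predominant, site_frequencies
from .psop import CATEGORY_NEGATIVE, CATEGORY_POSITIVE, psop_screen

logger = logging.getLogger(__name__)


@dataclass
class RunSummary:
    """Machine-readable account of one pipeline run."""

    input_digests: dict = field(default_factory=dict)
    filter_config: dict = field(default_factory=dict)
    seed: Optional[int] = None
    n_datasets: int = 0
    n_profiling_records: int = 0
    n_differential_records: int = 0
    protein: str = ""
    n_sites: int = 0
    predominant_sites: list = field(default_factory=list)
    cooccurrence_rows: int = 0
    psop_rows: dict = field(default_factory=dict)
    psop_passing: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _range(raw: str) -> tuple[int, int]:
    if "-" in raw:
        lo, _, hi = raw.partition("-")
        return int(lo), int(hi)
    v = int(raw)
    return v, v


def synthetic_config_from_file(path: Union[str, Path], seed: Optional[int] = None) -> sim.SyntheticConfig:
    """Build a SyntheticConfig from a ``key = value`` file.

    ``preset = default_study`` loads the canonical study corpus; explicit
    keys otherwise: n_studies, conditions_per_study (``12`` or ``8-12``),
    n_proteins, sites_per_protein, base_detect_prob, effect_fc_up,
    effect_fc_down, fc_sigma, seed, and repeatable ``predominant_site =
    TOKEN:PROB`` and ``planted_pair = TOKA,TOKB,RHO,CO`` lines.
    """
    raw = pio.read_keyvalue_config(path)
    preset = pio.scalar(raw, "preset")
    cfg_seed = pio.scalar(raw, "seed")
    use_seed = seed if seed is not None else (int(cfg_seed) if cfg_seed is not None else 0)
    if preset == "default_study":
        return sim.default_study_config(seed=use_seed)
    if preset is not None:
        raise ConfigError(f"unknown simulation preset {preset!r}")
    kwargs: dict = {"seed": use_seed}
    for key, cast in (
        ("n_studies", int),
        ("n_proteins", int),
        ("base_detect_prob", float),
        ("effect_fc_up", float),
        ("effect_fc_down", float),
        ("fc_sigma", float),
    ):
        v = pio.scalar(raw, key)
        if v is not None:
            kwargs[key] = cast(v)
    for key in ("conditions_per_study", "sites_per_protein"):
        v = pio.scalar(raw, key)
        if v is not None:
            kwargs[key] = _range(v)
    preds = []
    for spec in raw.get("predominant_site", []):
        token, _, prob = spec.partition(":")
        if not prob:
            raise ConfigError(f"predominant_site must be 'TOKEN:PROB', got {spec!r}")
        preds.append((token.strip(), float(prob)))
    if preds:
        kwargs["predominant_sites"] = preds
    pairs = []
    for spec in raw.get("planted_pair", []):
        parts = [p.strip() for p in spec.split(",")]
        if len(parts) != 4:
            raise ConfigError(f"planted_pair must be 'TOKA,TOKB,RHO,CO', got {spec!r}")
        pairs.append(sim.PlantedPair(parts[0], parts[1], float(parts[2]), float(parts[3])))
    if pairs:
        kwargs["planted_pairs"] = pairs
    return sim.SyntheticConfig(**kwargs)


def run_pipeline(config_path: Union[str, Path], seed: Optional[int] = None) -> RunSummary:
    """Run all stages per a run config file and write outputs + run_summary.json.

    Raises ConfigError / SchemaError / ValidationError on invalid input; the
    CLI maps these to a nonzero exit status.
    """
    config_path = Path(config_path)
    raw = pio.read_keyvalue_config(config_path)
    fcfg = pio.filter_config_from_mapping(raw)

    protein = pio.scalar(raw, "protein")
    if not protein:
        raise ConfigError(f"run config {config_path} must name a target protein (protein = ...)")
    protein = protein.upper()
    out_dir = Path(pio.scalar(raw, "out", "phoscoreg_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    summary = RunSummary(filter_config=asdict(fcfg), protein=protein)

    corpus_dir = pio.scalar(raw, "corpus")
    sim_cfg_path = pio.scalar(raw, "simulate")
    if (corpus_dir is None) == (sim_cfg_path is None):
        raise ConfigError("run config must set exactly one of 'corpus' or 'simulate'")

    base = config_path.parent

    def resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    if sim_cfg_path is not None:
        scfg = synthetic_config_from_file(resolve(sim_cfg_path), seed=seed)
        summary.seed = scfg.seed
        logger.info("simulating corpus (seed=%d)", scfg.seed)
        corpus, truth = sim.generate_corpus(scfg)
        corpus_out = out_dir / "corpus"
        pio.write_corpus(corpus, corpus_out)
        pio.write_results(truth.pairs, corpus_out / "truth.tsv")
        pio.write_results(truth.sites, corpus_out / "site_truth.tsv")
        summary.input_digests["simulate"] = _sha256(resolve(sim_cfg_path))
    else:
        cdir = resolve(corpus_dir)
        corpus = pio.read_corpus(cdir, fcfg)
        for name in (pio.DATASETS_FILE, pio.PROFILING_FILE, pio.DIFFERENTIAL_FILE):
            summary.input_digests[name] = _sha256(cdir / name)

    gene_map = pio.scalar(raw, "gene_map")
    accession_map = pio.scalar(raw, "accession_map")
    if gene_map and accession_map:
        gmap = pio.read_table(resolve(gene_map), ["alias", "symbol"])
        amap = pio.read_table(resolve(accession_map), ["symbol", "accession"])
        corpus, hreport = pio.harmonize(corpus, gmap, amap)
        logger.info("harmonized: %s", hreport)

    corpus, preport = pio.preprocess(corpus, fcfg)
    logger.info(
        "preprocess: %d non-Class-I profiling rows removed, %d conflicts dropped",
        preport.profiling_not_class1,
        preport.differential_conflicts_dropped,
    )
    summary.n_datasets = len(corpus.datasets)
    summary.n_profiling_records = len(corpus.profiling)
    summary.n_differential_records = len(corpus.differential)

    logger.info("thresholds: %s", asdict(fcfg))

    freqs = site_frequencies(corpus, protein, fcfg)
    summary.n_sites = len(freqs)
    if not len(freqs):
        raise ConfigError(f"target protein {protein!r} has no Class-I sites in the corpus")
    ranked = rank_predominant(freqs, fcfg)
    pio.write_results(ranked, out_dir / "predominant.tsv")

    explicit_sites = [s.upper() for s in raw.get("site", [])]
    targets = explicit_sites or predominant_sites(freqs, fcfg)
    summary.predominant_sites = targets

    cooc = cooccurrence_matrix(corpus, protein, fcfg)
    summary.cooccurrence_rows = len(cooc)
    pio.write_results(cooc, out_dir / "cooccurrence.tsv")

    kin_path = pio.scalar(raw, "kinases")
    ppi_path = pio.scalar(raw, "ppi")
    proc_path = pio.scalar(raw, "processes")
    min_db_support = int(pio.scalar(raw, "min_db_support", "2"))

    for token in targets:
        results = psop_screen(token, corpus, fcfg)
        pio.write_results(results, out_dir / f"psop_{token}.tsv")
        summary.psop_rows[token] = len(results)
        passing = results[results["passes"]] if len(results) else results
        summary.psop_passing[token] = {
            CATEGORY_POSITIVE: int((passing["category"] == CATEGORY_POSITIVE).sum()) if len(passing) else 0,
            CATEGORY_NEGATIVE: int((passing["category"] == CATEGORY_NEGATIVE).sum()) if len(passing) else 0,
        }
        if kin_path:
            kin = pio.read_table(resolve(kin_path), xref.KINASE_COLUMNS)
            pio.write_results(
                xref.crossref_kinases(results, kin, token), out_dir / f"kinases_{token}.tsv"
            )
        if ppi_path:
            ppi = pio.read_table(resolve(ppi_path), xref.PPI_COLUMNS)
            pio.write_results(
                xref.crossref_interactors(results, ppi, min_db_support=min_db_support),
                out_dir / f"interactors_{token}.tsv",
            )
        if proc_path:
            proc = pio.read_table(resolve(proc_path), xref.PROCESS_COLUMNS)
            pio.write_results(
                xref.group_by_process(results, proc), out_dir / f"processes_{token}.tsv"
            )

    (out_dir / "run_summary.json").write_text(summary.to_json() + "\n")
    logger.info("pipeline complete: outputs in %s", out_dir)
    return summary
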