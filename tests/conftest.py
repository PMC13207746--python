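import numpy as np
import pandas as pd
import pytest

from phoscoreg.model import Corpus, FilterConfig

# fold change / p-value pairs that realize each call under default thresholds
CALL_VALUES = {
    "U": (2.0, 0.01),
    "D": (0.5, 0.01),
    "none": (1.0, 0.5),
}


def corpus_from_calls(call_map, pmids=None, codes=None, extra_differential=0):
    """Build a differential-only corpus realizing the requested calls.

    ``call_map``: dataset_id -> {site_token: call}. ``pmids``/``codes`` map
    dataset_id to study PMID / condition code (defaults: one per dataset).
    ``extra_differential`` appends empty differential datasets (no records).
    """
    pmids = pmids or {}
    codes = codes or {}
    ds_rows, diff_rows = [], []
    for i, (ds, sites) in enumerate(call_map.items()):
        ds_rows.append(
            {
                "dataset_id": ds,
                "pmid": pmids.get(ds, f"PM{i}"),
                "condition_code": codes.get(ds, f"C{i}"),
                "dataset_type": "differential",
                "enrichment": "STY",
            }
        )
        for token, call in sites.items():
            gene, rp = token.split("_", 1)
            fc, p = CALL_VALUES[call]
            diff_rows.append(
                {
                    "dataset_id": ds,
                    "gene": gene,
                    "accession": f"X{gene}",
                    "residue": rp[0],
                    "position": int(rp[1:]),
                    "fold_change": fc,
                    "p_value": p,
                }
            )
    for j in range(extra_differential):
        ds_rows.append(
            {
                "dataset_id": f"EMPTY{j}",
                "pmid": f"PME{j}",
                "condition_code": f"CE{j}",
                "dataset_type": "differential",
                "enrichment": "STY",
            }
        )
    datasets = pd.DataFrame(ds_rows)
    differential = pd.DataFrame(
        diff_rows,
        columns=["dataset_id", "gene", "accession", "residue", "position", "fold_change", "p_value"],
    )
    profiling = pd.DataFrame(
        columns=["dataset_id", "gene", "accession", "residue", "position", "loc_prob", "ascore"]
    )
    return Corpus.assemble(datasets, profiling, differential)


def add_profiling(corpus, detections, loc_prob=0.9, ascore=np.nan, pmids=None, codes=None):
    """Extend a corpus with profiling datasets.

    ``detections``: dataset_id -> list of site tokens identified.
    """
    pmids = pmids or {}
    codes = codes or {}
    ds_rows, prof_rows = [], []
    for i, (ds, tokens) in enumerate(detections.items()):
        ds_rows.append(
            {
                "dataset_id": ds,
                "pmid": pmids.get(ds, f"PMP{i}"),
                "condition_code": codes.get(ds, f"CP{i}"),
                "dataset_type": "profiling",
                "enrichment": "STY",
            }
        )
        for token in tokens:
            gene, rp = token.split("_", 1)
            prof_rows.append(
                {
                    "dataset_id": ds,
                    "gene": gene,
                    "accession": f"X{gene}",
                    "residue": rp[0],
                    "position": int(rp[1:]),
                    "loc_prob": loc_prob,
                    "ascore": ascore,
                }
            )
    datasets = pd.concat([corpus.datasets, pd.DataFrame(ds_rows)], ignore_index=True)
    profiling = pd.concat(
        [
            corpus.profiling.drop(columns=["site"]),
            pd.DataFrame(
                prof_rows,
                columns=["dataset_id", "gene", "accession", "residue", "position", "loc_prob", "ascore"],
            ),
        ],
        ignore_index=True,
    )
    return Corpus.assemble(datasets, profiling, corpus.differential.drop(columns=["site", "call"]))


@pytest.fixture
def fcfg():
    return FilterConfig()
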