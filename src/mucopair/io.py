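"""Readers and writers: TSV matrices, metadata, truth JSON, BIOM v1 JSON.

Value tables are written features-as-rows with the first column holding the
feature id; metadata is a TSV with columns sample_id, subject_id, arm,
formulation, timepoint, is_tech_replicate.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, METADATA_COLUMNS, TaxonCountTable
from .exceptions import ValidationError


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    out = metadata.reset_index(names="sample_id")
    out.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id",) + METADATA_COLUMNS
               if c not in meta.columns]
    if missing:
        raise ValidationError(
            f"metadata file {path} is missing column(s): {', '.join(missing)}")
    meta["is_tech_replicate"] = meta["is_tech_replicate"].astype(bool)
    return meta.set_index("sample_id")


def write_values_tsv(values: pd.DataFrame, path, feature_col: str) -> None:
    values.rename_axis(feature_col).to_csv(path, sep="\t")


def read_abundance_tsv(values_path, metadata_path) -> AbundanceMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    return AbundanceMatrix(values, read_metadata_tsv(metadata_path))


def write_abundance_tsv(matrix: AbundanceMatrix, values_path,
                        metadata_path) -> None:
    write_values_tsv(matrix.values, values_path, "protein_id")
    write_metadata_tsv(matrix.metadata, metadata_path)


def read_counts_tsv(counts_path, metadata_path) -> TaxonCountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    return TaxonCountTable(counts, read_metadata_tsv(metadata_path))


def write_counts_tsv(table: TaxonCountTable, counts_path,
                     metadata_path) -> None:
    write_values_tsv(table.counts, counts_path, "taxon_id")
    write_metadata_tsv(table.metadata, metadata_path)


def write_truth_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# -- minimal BIOM v1 (JSON) support ----------------------------------------

def write_biom_json(table: TaxonCountTable, path) -> None:
    """Write a sparse BIOM format 1.0 JSON table (counts only, no metadata)."""
    counts = table.counts
    data = []
    arr = counts.to_numpy()
    for i, j in zip(*np.nonzero(arr)):
        data.append([int(i), int(j), float(arr[i, j])])
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "mucopair",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [int(counts.shape[0]), int(counts.shape[1])],
        "rows": [{"id": str(t), "metadata": None} for t in counts.index],
        "columns": [{"id": str(s), "metadata": None} for s in counts.columns],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_biom_json(path, metadata: pd.DataFrame) -> TaxonCountTable:
    """Read a BIOM format 1.0 JSON table; metadata must be supplied separately."""
    with open(path) as fh:
        doc = json.load(fh)
    if "format" not in doc or not str(doc["format"]).startswith(
            "Biological Observation Matrix 1"):
        raise ValidationError(f"{path} is not a BIOM 1.0 JSON table")
    n_rows, n_cols = doc["shape"]
    arr = np.zeros((n_rows, n_cols), dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            arr[int(i), int(j)] = int(v)
    else:
        arr[:] = np.asarray(doc["data"], dtype=np.int64)
    counts = pd.DataFrame(arr,
                          index=[r["id"] for r in doc["rows"]],
                          columns=[c["id"] for c in doc["columns"]])
    return TaxonCountTable(counts, metadata)


def write_run_log(path, config_echo: dict) -> None:
    """Record the thresholds, seeds and versions actually applied."""
    import mucopair
    payload = {"mucopair_version": mucopair.__version__,
               "numpy_version": np.__version__,
               "pandas_version": pd.__version__}
    payload.update(config_echo)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True,
                                     default=str))
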