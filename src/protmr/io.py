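"""Readers and writers for the pipeline's tab-delimited interchange formats.

Summary statistics use one dialect everywhere: tab-separated with header
``variant_id chrom pos ea nea eaf beta se pval n``. Protein matrices are
written as a values TSV (rows = wells, columns = analytes) plus a
``*.samples.tsv`` sidecar carrying well role (sample | calibrator | buffer)
and plate id. Truth manifests round-trip through YAML.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

SUMSTATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ea",
    "nea",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


def write_sumstats(df: pd.DataFrame, path) -> None:
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    df.loc[:, SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def sidecar_path(values_path) -> pathlib.Path:
    p = pathlib.Path(values_path)
    return p.with_suffix("").with_suffix(".samples.tsv")


def write_protein_matrix(matrix, path) -> None:
    """Write a ProteinMatrix as values TSV + sample-metadata sidecar."""
    p = pathlib.Path(path)
    matrix.values.to_csv(p, sep="\t", index_label="well")
    matrix.sample_meta.to_csv(sidecar_path(p), sep="\t", index_label="well")


def read_protein_matrix(path, log_scale: bool = False):
    from .qc import ProteinMatrix

    p = pathlib.Path(path)
    values = pd.read_csv(p, sep="\t", index_col="well")
    sample_meta = pd.read_csv(sidecar_path(p), sep="\t", index_col="well")
    return ProteinMatrix(values=values, sample_meta=sample_meta, log_scale=log_scale)


def write_panel(panel, prefix) -> None:
    """Write a GenotypePanel as <prefix>.dosages.tsv + <prefix>.variants.tsv."""
    p = pathlib.Path(prefix)
    pd.DataFrame(
        panel.dosages, index=panel.sample_ids, columns=panel.variant_ids
    ).to_csv(p.with_suffix(".dosages.tsv"), sep="\t", index_label="sample")
    panel.variant_meta.to_csv(p.with_suffix(".variants.tsv"), sep="\t")


def read_panel(prefix):
    from .simulate import GenotypePanel

    p = pathlib.Path(prefix)
    dos = pd.read_csv(p.with_suffix(".dosages.tsv"), sep="\t", index_col="sample")
    meta = pd.read_csv(
        p.with_suffix(".variants.tsv"), sep="\t", index_col="variant_id", dtype={"chrom": str}
    )
    return GenotypePanel(
        dosages=dos.to_numpy(dtype=np.int8),
        variant_meta=meta.loc[dos.columns],
        sample_ids=list(dos.index),
    )


def write_manifest(manifest, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest.to_dict(), fh, sort_keys=True)


def read_manifest(path):
    from .simulate import TruthManifest

    with open(path) as fh:
        return TruthManifest.from_dict(yaml.safe_load(fh))
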