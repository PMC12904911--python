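"""File formats, SNV quality-control filtering, and run manifests.

All tabular artifacts are tab-separated text with deterministic byte streams:
stable column order and floats at 10 significant digits. Count matrices carry
a header row of cell/sample IDs and a first column of mutation IDs
(chrom:pos:ref:alt recommended, VCF-style 1-based coordinates).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bursting import ExpressionMatrix
from .tree import ClonalTree, ReadCountSet

FLOAT_FORMAT = "%.10g"

COUNT_FILES = {"R_b": "bulk_alt.tsv", "X_b": "bulk_total.tsv",
               "R_s": "cell_alt.tsv", "X_s": "cell_total.tsv"}

#: Required columns of an annotated variant table, in filter order.
SNV_FILTER_COLUMNS = ["filter_status", "normal_genotype", "n_alt_alleles",
                      "normal_total_reads", "tumor_alt_reads_max", "in_1000g",
                      "in_segdup", "ljb_score_available"]

_HOMOZYGOUS_REF = {"0/0", "0|0"}


def _write_matrix(path, matrix, row_ids, col_ids, index_name="mutation_id"):
    df = pd.DataFrame(np.asarray(matrix), index=row_ids, columns=col_ids)
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n")


def _read_matrix(path):
    return pd.read_csv(path, sep="\t", index_col=0)


def write_count_matrices(data: ReadCountSet, outdir) -> dict:
    """Write the four count matrices as TSV; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in COUNT_FILES.items():
        cols = data.sample_ids if attr.endswith("_b") else data.cell_ids
        path = outdir / fname
        _write_matrix(path, getattr(data, attr), data.mutation_ids, cols)
        paths[attr] = path
    return paths


def read_count_matrices(paths: dict) -> ReadCountSet:
    """Parse the four TSV count matrices into a validated ReadCountSet.

    Rows are aligned by mutation ID across matrices; a mismatch in the ID sets
    is an error — rows are never silently dropped or reordered away.
    """
    frames = {attr: _read_matrix(paths[attr]) for attr in COUNT_FILES}
    ref_ids = list(frames["R_b"].index)
    for attr, df in frames.items():
        if set(df.index) != set(ref_ids):
            missing = set(ref_ids) ^ set(df.index)
            raise ValueError(f"mutation IDs of {attr} do not match bulk "
                             f"alternative counts (differing: {sorted(missing)})")
        frames[attr] = df.loc[ref_ids]
    return ReadCountSet(
        R_b=frames["R_b"].to_numpy(), X_b=frames["X_b"].to_numpy(),
        R_s=frames["R_s"].to_numpy(), X_s=frames["X_s"].to_numpy(),
        mutation_ids=ref_ids,
        cell_ids=list(frames["R_s"].columns),
        sample_ids=list(frames["R_b"].columns))


def write_expression(expr: ExpressionMatrix, path) -> None:
    _write_matrix(path, expr.counts, expr.gene_ids,
                  expr.cell_ids or [f"cell{i + 1}" for i in range(expr.N)],
                  index_name="gene_id")


def read_expression(path) -> ExpressionMatrix:
    df = _read_matrix(path)
    return ExpressionMatrix(counts=df.to_numpy(), gene_ids=list(df.index),
                            cell_ids=list(df.columns))


def write_tree(tree: ClonalTree, mutation_ids, newick_path, table_path) -> None:
    """Serialize a clonal tree as Newick plus a mutation -> clone-set table."""
    Path(newick_path).write_text(tree.newick() + "\n")
    Z = tree.Z
    rows = []
    for m, mid in enumerate(mutation_ids):
        clones = ",".join(f"clone{k + 1}" for k in range(tree.K) if Z[m, k])
        rows.append({"mutation_id": mid, "clones": clones})
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False,
                              lineterminator="\n")


def apply_snv_filters(table: pd.DataFrame):
    """Quality-control filter for candidate somatic SNVs.

    Keeps rows that satisfy all of: (i) caller filter status PASS, (ii)
    homozygous-reference genotype in the normal sample, (iii) a single
    alternative allele, (iv) at least 20 total reads in the normal, (v) at
    least five alternative reads in at least one bulk cancer sample, (vi) not
    reported in the 1000 Genomes Project, (vii) outside segmental
    duplications, (viii) a non-missing LJB functional score. Returns the kept
    table and per-criterion removal counts (a row failing several criteria
    counts once under each).
    """
    missing = [c for c in SNV_FILTER_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"annotated variant table missing column(s): {missing}")
    checks = {
        "pass_filter": table["filter_status"].astype(str) == "PASS",
        "normal_homozygous_ref": table["normal_genotype"].astype(str)
            .isin(_HOMOZYGOUS_REF),
        "single_alt_allele": table["n_alt_alleles"].astype(int) == 1,
        "normal_depth_ge_20": table["normal_total_reads"].astype(int) >= 20,
        "tumor_alt_ge_5": table["tumor_alt_reads_max"].astype(int) >= 5,
        "not_in_1000g": ~table["in_1000g"].astype(bool),
        "not_in_segdup": ~table["in_segdup"].astype(bool),
        "ljb_score_present": table["ljb_score_available"].astype(bool),
    }
    removal_counts = {name: int((~mask).sum()) for name, mask in checks.items()}
    keep = np.logical_and.reduce([mask.to_numpy() for mask in checks.values()])
    return table.loc[keep].copy(), removal_counts


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, config: dict, input_paths=None, extra=None) -> None:
    """JSON run manifest: configuration, input checksums, package version."""
    from . import __version__
    manifest = {"version": __version__, "config": config}
    if input_paths:
        manifest["inputs"] = {str(p): file_checksum(p) for p in input_paths}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")
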