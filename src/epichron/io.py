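"""Readers/writers for the plain-text formats the pipeline consumes.

Counts travel as TSV (features x samples) or MatrixMarket (with sidecar row
and column name files); metadata and results as TSV; gene sets as GMT;
intervals as 0-based half-open BED.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty count matrix")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_mtx(path) -> pd.DataFrame:
    """MatrixMarket matrix with ``<stem>.rows`` / ``<stem>.cols`` name files."""
    path = Path(path)
    mat = scipy.io.mmread(path)
    rows = path.with_suffix(".rows").read_text().split()
    cols = path.with_suffix(".cols").read_text().split()
    dense = mat.toarray() if scipy.sparse.issparse(mat) else mat
    return pd.DataFrame(dense, index=rows, columns=cols)


def write_counts_mtx(counts: pd.DataFrame, path) -> None:
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(counts.to_numpy()))
    path.with_suffix(".rows").write_text("\n".join(map(str, counts.index)) + "\n")
    path.with_suffix(".cols").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"age", "sex"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample table lacks columns {sorted(missing)}")
    return df


def read_bed(path, n_fields: int = 3) -> pd.DataFrame:
    """0-based half-open BED; extra columns kept as name/score/strand."""
    names = ["chrom", "start", "end", "name", "score", "strand"][:max(n_fields, 3)]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >= 3 columns")
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    for i, row in df.iterrows():
        if not (int(row["start"]) < int(row["end"])):
            raise ValueError(
                f"{path} line {i + 1}: start >= end; BED intervals are 0-based, "
                "half-open [start, end) — 1-based inclusive coordinates are not accepted")
    return df


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {lineno}: GMT rows need name, "
                                 "description and >= 1 gene")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(map(str, members))]) + "\n")
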