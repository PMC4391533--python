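"""Tab-separated file formats for datasets, truth tables and results.

All files are UTF-8, Unix newlines, tab-separated, with ``#``-prefixed
comment lines (skipped on read; used for provenance headers).  TSV is
used instead of CSV to avoid locale decimal issues.

Expression matrix: header ``gene_id  exon_id  <sample_1> ... <sample_n>``,
one row per exon, exons of a gene contiguous and ordered; values are log2
intensities written with 17 significant digits so a write/read round trip
is exact.  Sample metadata: header ``sample_id  condition``, rows matching
the matrix's sample columns 1:1.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .core_model import (
    ExonExpressionSet,
    MethodResult,
    TruthEntry,
    TruthTable,
    validate,
)

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_truth",
    "write_truth",
    "write_results",
    "read_results",
]

_FLOAT_FMT = "%.17g"


def _provenance_lines(seed: int | None = None, config_text: str | None = None) -> list[str]:
    from . import __version__

    lines = [f"# exonsplice {__version__}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    if config_text is not None:
        digest = hashlib.sha256(config_text.encode()).hexdigest()[:16]
        lines.append(f"# config_sha256 {digest}")
    return lines


def _open_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_dataset(matrix_path: str | Path, metadata_path: str | Path) -> ExonExpressionSet:
    """Read and validate an expression matrix plus its sample metadata.

    Parse errors name the file, line and column; the returned dataset has
    passed :func:`~exonsplice.core_model.validate`.
    """
    meta_rows = list(_open_rows(metadata_path))
    if not meta_rows:
        raise ValueError(f"{metadata_path}: no data rows")
    header = meta_rows[0][1]
    if header[:2] != ["sample_id", "condition"]:
        raise ValueError(f"{metadata_path}: line {meta_rows[0][0]}: expected header 'sample_id\\tcondition'")
    condition_of: dict[str, str] = {}
    for lineno, fields in meta_rows[1:]:
        if len(fields) != 2:
            raise ValueError(f"{metadata_path}: line {lineno}: expected 2 columns, got {len(fields)}")
        condition_of[fields[0]] = fields[1]

    rows = list(_open_rows(matrix_path))
    if not rows:
        raise ValueError(f"{matrix_path}: no data rows")
    lineno0, header = rows[0]
    if header[:2] != ["gene_id", "exon_id"]:
        raise ValueError(f"{matrix_path}: line {lineno0}: expected header starting 'gene_id\\texon_id'")
    sample_ids = header[2:]
    if not sample_ids:
        raise ValueError(f"{matrix_path}: line {lineno0}: no sample columns")
    missing = [s for s in sample_ids if s not in condition_of]
    if missing:
        raise ValueError(f"{matrix_path}: sample {missing[0]!r} absent from metadata {metadata_path}")
    extra = [s for s in condition_of if s not in sample_ids]
    if extra:
        raise ValueError(f"{metadata_path}: sample {extra[0]!r} absent from matrix {matrix_path}")

    gene_ids: list[str] = []
    exon_ids: dict[str, list[str]] = {}
    raw: dict[str, list[list[float]]] = {}
    for lineno, fields in rows[1:]:
        if len(fields) != 2 + len(sample_ids):
            raise ValueError(
                f"{matrix_path}: line {lineno}: expected {2 + len(sample_ids)} columns, got {len(fields)}"
            )
        gene, exon = fields[0], fields[1]
        vals = []
        for col, f in enumerate(fields[2:], start=3):
            try:
                vals.append(float(f))
            except ValueError:
                raise ValueError(
                    f"{matrix_path}: line {lineno}, column {col}: non-numeric value {f!r}"
                ) from None
        if gene not in raw:
            if gene in gene_ids:
                raise ValueError(
                    f"{matrix_path}: line {lineno}: rows of gene {gene!r} are not contiguous"
                )
            gene_ids.append(gene)
            raw[gene] = []
            exon_ids[gene] = []
        elif gene != gene_ids[-1]:
            raise ValueError(
                f"{matrix_path}: line {lineno}: rows of gene {gene!r} are not contiguous"
            )
        raw[gene].append(vals)
        exon_ids[gene].append(exon)

    dataset = ExonExpressionSet(
        gene_ids=gene_ids,
        exon_ids=exon_ids,
        values={g: np.asarray(raw[g], dtype=float) for g in gene_ids},
        sample_ids=sample_ids,
        condition=[condition_of[s] for s in sample_ids],
    )
    problems = validate(dataset)
    if problems:
        raise ValueError(f"{matrix_path}: invalid dataset: " + "; ".join(problems))
    return dataset


def write_dataset(
    dataset: ExonExpressionSet,
    matrix_path: str | Path,
    metadata_path: str | Path,
    seed: int | None = None,
    config_text: str | None = None,
) -> None:
    with open(matrix_path, "w", encoding="utf-8", newline="\n") as fh:
        _write_header(fh, seed, config_text)
        fh.write("\t".join(["gene_id", "exon_id", *dataset.sample_ids]) + "\n")
        for g in dataset.gene_ids:
            for exon, row in zip(dataset.exon_ids[g], dataset.values[g]):
                vals = "\t".join(_FLOAT_FMT % v for v in row)
                fh.write(f"{g}\t{exon}\t{vals}\n")
    with open(metadata_path, "w", encoding="utf-8", newline="\n") as fh:
        _write_header(fh, seed, config_text)
        fh.write("sample_id\tcondition\n")
        for s, c in zip(dataset.sample_ids, dataset.condition):
            fh.write(f"{s}\t{c}\n")


def _write_header(fh: TextIO, seed: int | None, config_text: str | None) -> None:
    for line in _provenance_lines(seed, config_text):
        fh.write(line + "\n")


def write_truth(truth: TruthTable, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_header(fh, seed, None)
        fh.write("gene_id\tis_ds\tds_exons\tds_group\tds_samples\n")
        for g, e in truth.entries.items():
            fh.write(
                "\t".join(
                    [
                        g,
                        "1" if e.is_ds else "0",
                        ",".join(str(i) for i in e.ds_exons),
                        e.ds_group or "",
                        ",".join(str(i) for i in e.ds_samples),
                    ]
                )
                + "\n"
            )


def read_truth(path: str | Path) -> TruthTable:
    rows = list(_open_rows(path))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    entries: dict[str, TruthEntry] = {}
    for lineno, fields in rows[1:]:
        if len(fields) != 5:
            raise ValueError(f"{path}: line {lineno}: expected 5 columns, got {len(fields)}")
        g, is_ds, exons, group, samples = fields
        entries[g] = TruthEntry(
            is_ds=is_ds == "1",
            ds_exons=tuple(int(i) for i in exons.split(",")) if exons else (),
            ds_group=group or None,
            ds_samples=tuple(int(i) for i in samples.split(",")) if samples else (),
        )
    return TruthTable(entries=entries)


def write_results(
    result: MethodResult, path: str | Path, seed: int | None = None, config_text: str | None = None
) -> None:
    """Results TSV: gene_id, method, score, p_value; empty field = absent."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_header(fh, seed, config_text)
        fh.write("gene_id\tmethod\tscore\tp_value\n")
        for i, g in enumerate(result.gene_ids):
            score = "" if result.score is None or np.isnan(result.score[i]) else _FLOAT_FMT % result.score[i]
            p = "" if result.p_value is None or np.isnan(result.p_value[i]) else _FLOAT_FMT % result.p_value[i]
            fh.write(f"{g}\t{result.method}\t{score}\t{p}\n")


def read_results(path: str | Path) -> pd.DataFrame:
    rows = list(_open_rows(path))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    df = pd.DataFrame([f for _, f in rows[1:]], columns=rows[0][1])
    for col in ("score", "p_value"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == "", np.nan))
    return df
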