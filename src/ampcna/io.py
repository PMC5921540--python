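"""Reading and writing coverage matrices, gene annotations and call tables.

The on-disk dialect is strict, unquoted, UTF-8 TSV.  A coverage file has a
header row of sample identifiers and a first column of amplicon
identifiers; every other cell is numeric.  Several coverage files with an
identical amplicon row set can be column-concatenated into one cohort.
"""

from __future__ import annotations

import csv
import math
from typing import Iterable, Sequence

import pandas as pd

from .containers import AmpcnaError, CoverageMatrix, GeneMap

# numeric TSV output uses Python's shortest round-trip float repr (pandas
# default); reads use the round_trip parser so values survive bit-exactly

CALL_LAYOUTS = ("matrix", "gene_list", "sample_list")


def read_coverage_matrix(path, expect_header: bool = True) -> CoverageMatrix:
    """Read a TSV coverage matrix (rows = amplicons, columns = samples).

    The first row must carry sample identifiers and the first column
    amplicon identifiers; row and column order are preserved.  Duplicate
    identifiers, ragged rows and non-numeric cells are reported with their
    location.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise AmpcnaError(f"{path}: empty file")
    if not expect_header:
        raise AmpcnaError("header row with sample identifiers is required")
    header = rows[0]
    # tolerate both conventions for the header's first cell: empty or a label
    sample_ids = header[1:] if len(header) > 1 else []
    n_cols = len(sample_ids)
    if n_cols == 0:
        raise AmpcnaError(f"{path}: header row contains no sample identifiers")
    amplicon_ids: list[str] = []
    data: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols + 1:
            raise AmpcnaError(
                f"{path}: ragged row {i}: expected {n_cols + 1} fields, got {len(row)}"
            )
        amplicon_ids.append(row[0])
        vals = []
        for j, cell in enumerate(row[1:], start=1):
            try:
                v = float(cell)
            except ValueError:
                raise AmpcnaError(
                    f"{path}: non-numeric cell at row {i}, column {j + 1} "
                    f"(amplicon {row[0]!r}, sample {sample_ids[j - 1]!r}): {cell!r}"
                ) from None
            if math.isnan(v):
                raise AmpcnaError(
                    f"{path}: missing value at row {i}, column {j + 1}"
                )
            vals.append(v)
        data.append(vals)
    if not data:
        raise AmpcnaError(f"{path}: no amplicon rows")
    df = pd.DataFrame(data, index=amplicon_ids, columns=sample_ids)
    matrix = CoverageMatrix(values=df, stage="raw")
    _reject_all_zero_rows(matrix)
    return matrix


def _reject_all_zero_rows(matrix: CoverageMatrix) -> None:
    zero = matrix.values.eq(0).all(axis=1)
    if zero.any():
        bad = list(matrix.values.index[zero])
        raise AmpcnaError(
            f"amplicon(s) with zero coverage in every sample: {bad}; "
            "remove them from the panel before analysis (they make median "
            "scaling degenerate)"
        )


def concat_coverage(matrices: Sequence[CoverageMatrix]) -> CoverageMatrix:
    """Column-concatenate cohorts that share an identical amplicon row set."""
    if not matrices:
        raise AmpcnaError("no coverage matrices to concatenate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.amplicon_ids != first.amplicon_ids:
            raise AmpcnaError(
                "coverage files do not share an identical amplicon row set"
            )
        if m.stage != first.stage:
            raise AmpcnaError("cannot concatenate matrices at different stages")
    df = pd.concat([m.values for m in matrices], axis=1)
    return CoverageMatrix(values=df, stage=first.stage)


def parse_gene_map(
    amplicon_ids: Iterable[str],
    mode: str = "prefix_delimiter",
    delimiter_or_path: str = "_",
) -> GeneMap:
    """Build the amplicon -> gene assignment.

    ``prefix_delimiter`` mode splits each amplicon id at the *first*
    occurrence of the delimiter; the prefix is the gene name.
    ``annotation_file`` mode reads a two-column TSV (amplicon_id, gene)
    that must list every amplicon exactly once.
    """
    amplicon_ids = list(amplicon_ids)
    if mode == "prefix_delimiter":
        delim = delimiter_or_path
        missing = [a for a in amplicon_ids if delim not in a]
        if missing:
            raise AmpcnaError(
                f"amplicon id(s) without gene delimiter {delim!r}: {missing}"
            )
        pairs = [(a, a.split(delim, 1)[0]) for a in amplicon_ids]
    elif mode == "annotation_file":
        mapping: dict[str, str] = {}
        with open(delimiter_or_path, encoding="utf-8", newline="") as fh:
            for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) != 2:
                    raise AmpcnaError(
                        f"{delimiter_or_path}: line {i}: expected 2 columns, got {len(row)}"
                    )
                amp, gene = row
                if i == 1 and amp not in amplicon_ids:
                    continue  # optional header line
                if amp in mapping:
                    raise AmpcnaError(
                        f"{delimiter_or_path}: amplicon {amp!r} annotated twice"
                    )
                mapping[amp] = gene
        missing = [a for a in amplicon_ids if a not in mapping]
        if missing:
            raise AmpcnaError(f"amplicon(s) missing from annotation: {missing}")
        pairs = [(a, mapping[a]) for a in amplicon_ids]
    else:
        raise AmpcnaError(f"unknown gene-map mode {mode!r}")

    amplicons_of: dict[str, list[str]] = {}
    for amp, gene in pairs:
        amplicons_of.setdefault(gene, []).append(amp)
    return GeneMap(amplicons_of=amplicons_of)


def write_matrix(df: pd.DataFrame, path, index_label: str = "") -> None:
    """Write any id-indexed matrix as strict TSV with full float precision."""
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


_LIST_COLUMNS = ["gene", "sample", "status", "CN", "p_corrected", "support_count"]


def write_calls(calls, path, layout: str = "matrix") -> None:
    """Write a call set in one of three layouts.

    ``matrix``      genes x samples grid of gain/loss/none.
    ``gene_list``   one row per called alteration, sorted by gene then sample.
    ``sample_list`` one row per called alteration, sorted by sample then gene,
                    with the sample's intra-gene inconsistency (IGI) quality
                    score repeated on each of its rows.
    All layouts round-trip call status, CN, corrected p and support count.
    """
    if layout not in CALL_LAYOUTS:
        raise AmpcnaError(f"unknown call layout {layout!r}")
    if layout == "matrix":
        write_matrix(calls.status, path, index_label="gene")
        return
    records = calls.to_records()
    if layout == "gene_list":
        records = records.sort_values(["gene", "sample"], kind="stable")
        cols = _LIST_COLUMNS
    else:
        if calls.igi is None:
            raise AmpcnaError("sample_list layout requires per-sample IGI on the call set")
        records = records.sort_values(["sample", "gene"], kind="stable")
        records = records.assign(IGI=calls.igi.reindex(records["sample"]).to_numpy())
        cols = _LIST_COLUMNS + ["IGI"]
    records.to_csv(path, sep="\t", index=False, columns=cols)


def read_calls(path, layout: str = "matrix") -> pd.DataFrame:
    """Read back a call table written by :func:`write_calls`."""
    if layout == "matrix":
        return pd.read_csv(path, sep="\t", index_col=0)
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
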