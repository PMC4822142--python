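"""Readers, writers and cohort-preparation rules.

The interchange format is tab-separated text: expression tables are
gene x sample with a header row of sample identifiers, annotation tables
carry ``sample_id, stage, blast_count, is_cd34_reference``.  GEO
series-matrix files are accepted read-only (the expression block between
``!series_matrix_table_begin`` and ``!series_matrix_table_end`` is
parsed; metadata lines are ignored).

Data-preparation rules applied when loading a cohort:

* genes are restricted to an optional gene-list file (the
  low-information-ratio universe) and to complete cases (any gene with a
  missing value is dropped);
* chronic-phase samples with missing blast counts are assigned blast
  count 1; blast-crisis samples with missing blast counts are excluded;
  other stages keep a missing flag.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohortstats import STAGES

__all__ = [
    "read_expression",
    "write_expression",
    "read_gene_list",
    "read_annotations",
    "prepare_cohort",
]

logger = logging.getLogger("cml_chronos")


def read_gene_list(path) -> list[str]:
    """One gene identifier per line; blank lines and '#' comments skipped."""
    lines = Path(path).read_text().splitlines()
    genes = [ln.strip().strip('"') for ln in lines]
    return [g for g in genes if g and not g.startswith("#")]


def _is_series_matrix(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                return True
            if not line.startswith("!") and line.strip():
                return False
    return False


def _read_series_matrix(path: Path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines)
                     if ln.startswith("!series_matrix_table_begin"))
        stop = next(i for i, ln in enumerate(lines)
                    if ln.startswith("!series_matrix_table_end"))
    except StopIteration as exc:
        raise ValueError(f"{path}: malformed series-matrix markers") from exc
    import io as _io

    block = "\n".join(lines[start + 1: stop])
    frame = pd.read_csv(_io.StringIO(block), sep="\t")
    frame.columns = [str(c).strip('"') for c in frame.columns]
    frame.iloc[:, 0] = frame.iloc[:, 0].astype(str).str.strip('"')
    return frame.set_index(frame.columns[0])


def read_expression(
    path,
    gene_list_path=None,
    gene_list: Sequence[str] | None = None,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Load a gene x sample expression matrix (plain TSV or series-matrix).

    Applies the complete-cases rule and the optional gene-list
    restriction; raises on duplicate gene identifiers or an empty
    intersection with the gene list.
    """
    path = Path(path)
    if _is_series_matrix(path):
        frame = _read_series_matrix(path)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique()[:5]
        raise ValueError(f"{path}: duplicate gene identifiers, e.g. {list(dupes)}")
    frame = frame.apply(pd.to_numeric, errors="coerce")
    if gene_list_path is not None:
        gene_list = read_gene_list(gene_list_path)
    if gene_list is not None:
        keep = frame.index.intersection(pd.Index(gene_list))
        if keep.empty:
            raise ValueError(
                f"{path}: no overlap between matrix genes and the gene list"
            )
        frame = frame.loc[keep]
    if drop_incomplete:
        n_before = frame.shape[0]
        frame = frame.dropna(axis=0)
        dropped = n_before - frame.shape[0]
        if dropped:
            logger.info("dropped %d incomplete-case genes", dropped)
    return frame


def write_expression(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="gene_id")


def read_annotations(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "sample_id" in frame.columns:
        frame = frame.set_index("sample_id")
    frame.index = frame.index.astype(str)
    if "is_cd34_reference" in frame.columns:
        frame["is_cd34_reference"] = frame["is_cd34_reference"].astype(bool)
    else:
        frame["is_cd34_reference"] = False
    if "blast_count" not in frame.columns:
        frame["blast_count"] = np.nan
    return frame


def prepare_cohort(annotations: pd.DataFrame) -> pd.DataFrame:
    """Apply the blast-count preparation rules to an annotation table.

    * unknown stage labels raise;
    * CP samples with missing blast count get blast count 1;
    * BC samples with missing blast count are excluded (logged);
    * AP / APcyto samples keep a ``blast_missing`` flag.
    """
    frame = annotations.copy()
    unknown = set(frame["stage"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    frame["blast_count"] = pd.to_numeric(frame["blast_count"], errors="coerce")
    bad_range = frame["blast_count"].dropna()
    if ((bad_range < 0) | (bad_range > 100)).any():
        raise ValueError("blast_count must lie in [0, 100]")
    frame["blast_missing"] = frame["blast_count"].isna()
    cp_missing = (frame["stage"] == "CP") & frame["blast_missing"]
    frame.loc[cp_missing, "blast_count"] = 1.0
    bc_missing = (frame["stage"] == "BC") & frame["blast_missing"]
    if bc_missing.any():
        logger.info(
            "excluding %d BC samples with missing blast counts: %s",
            int(bc_missing.sum()), list(frame.index[bc_missing]),
        )
        frame = frame.loc[~bc_missing]
    return frame
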