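"""Readers and writers for the text formats the pipeline touches.

Expression matrices and label files are tab-separated text; gene sets use the
Broad GMT dialect; fitted models and metric summaries are written as JSON.
All readers validate strictly and report the location (line, gene, sample) of
the first problem they find.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .containers import DataError, ExpressionDataset, GeneSet, GeneSetCollection

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import MetricsReport
    from .optimizer import EnsembleModel

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "write_results",
    "read_results",
]


class FormatError(DataError):
    """Malformed input file."""


# -- expression TSV ------------------------------------------------------


def read_expression(path: str | Path, transpose: bool = False) -> ExpressionDataset:
    """Read a genes x samples TSV (first row sample IDs, first column gene IDs).

    With ``transpose=True`` the file is samples-in-rows and is flipped after
    reading. Returns an unlabelled dataset; attach labels with
    :meth:`ExpressionDataset.with_labels`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if transpose:
        df = df.T
    row_kind, col_kind = "gene", "sample"
    dup_rows = df.index[df.index.duplicated()]
    if len(dup_rows):
        raise FormatError(f"duplicate {row_kind} ID {dup_rows[0]!r} in {path}")
    dup_cols = df.columns[df.columns.duplicated()]
    if len(dup_cols):
        raise FormatError(f"duplicate {col_kind} ID {dup_cols[0]!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if len(bad):
        i, j = bad[0]
        raw = df.iat[i, j]
        raise FormatError(
            f"non-numeric or missing value {raw!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {path}"
        )
    return ExpressionDataset(
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
        values=numeric.to_numpy(dtype=float),
    )


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    df = pd.DataFrame(dataset.values, index=list(dataset.gene_ids), columns=list(dataset.sample_ids))
    df.to_csv(path, sep="\t", index_label="gene_id")


# -- labels TSV ----------------------------------------------------------


def read_labels(path: str | Path, positive_label: str) -> dict[str, str]:
    """Read a two-column (sample_id, label) TSV without header.

    Exactly two distinct labels must occur and ``positive_label`` must be one
    of them.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"label file not found: {path}")
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
            sample, label = (f.strip() for f in fields)
            if sample in labels:
                raise FormatError(f"{path}:{lineno}: duplicate sample ID {sample!r}")
            labels[sample] = label
    distinct = sorted(set(labels.values()))
    if len(distinct) != 2:
        raise FormatError(f"{path}: expected exactly 2 distinct labels, found {distinct}")
    if positive_label not in distinct:
        raise FormatError(f"{path}: positive label {positive_label!r} not among {distinct}")
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


# -- GMT -----------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read Broad-dialect GMT: ``pathway_id TAB description TAB gene TAB ...``.

    Genes repeated within a line are deduplicated (first occurrence kept);
    lines whose gene list is empty are rejected with a logged warning, the way
    pathway collections drop empty pathways before analysis.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GMT file not found: {path}")
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            pathway_id, name = fields[0].strip(), fields[1].strip()
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                logger.warning("%s:%d: pathway %r has no genes; line rejected", path, lineno, pathway_id)
                continue
            sets.append(GeneSet(pathway_id=pathway_id, name=name, genes=tuple(genes)))
    return GeneSetCollection.from_sets(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.pathway_id, gs.name, *gs.genes]) + "\n")


# -- results JSON --------------------------------------------------------


def write_results(model: "EnsembleModel", metrics: "MetricsReport", path: str | Path) -> None:
    """Write the fitted ensemble (members, features, selection trace) and the
    evaluation summary as one JSON document."""
    if metrics is None or metrics.n_runs == 0:
        raise DataError("cannot write results with empty metrics")
    doc = {
        "ensemble": {
            "pathway_ids": [rec.pathway_id for rec in model.learners],
            "feature_genes": {rec.pathway_id: list(rec.feature_genes) for rec in model.learners},
            "positive_label": model.positive_label,
            "kernel": model.kernel,
        },
        "selection_trace": model.trace.to_dict(),
        "metrics": metrics.to_dict(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
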