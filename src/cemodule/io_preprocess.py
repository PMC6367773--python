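"""Reading expression tables and interaction lists, and the standard filters.

Expression tables are tab-delimited with one header row of molecule
identifiers and one leading column of sample identifiers.  The filter
pipeline mirrors the usual low-information screens applied to tumour
expression compendia before factorization: all-zero molecules are
dropped (miRNA layer), low-variance and low-magnitude molecules are
removed by percentile cutoffs (lncRNA/mRNA layers), and the values are
log2(v+1)-transformed, which both compresses dynamic range and keeps
the matrices non-negative as the factorization requires.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    FormatError,
    InteractionData,
    OmicsLayer,
    TriOmicsDataset,
    ValidationError,
)

__all__ = [
    "read_expression_matrix",
    "read_edge_list",
    "filter_low_variance",
    "filter_low_value",
    "drop_all_zero_rows",
    "log2_and_shift",
    "preprocess_dataset",
    "build_interaction_matrices",
]


# ---------------------------------------------------------------- readers

def read_expression_matrix(path, layer_kind: str) -> OmicsLayer:
    """Parse a tab-delimited expression table into an :class:`OmicsLayer`.

    Rows are samples, columns are molecules; no transform is applied.
    """
    # pandas silently renames duplicate header fields, so check them raw
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    molecule_header = header[1:]
    if len(set(molecule_header)) != len(molecule_header):
        dups = sorted({m for m in molecule_header if molecule_header.count(m) > 1})
        raise ValidationError(f"duplicate molecule ids in {path}: {dups[:5]}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed expression table {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"no samples in {path}: file is empty") from exc
    if df.shape[0] == 0:
        raise ValidationError(f"no samples in {path} (header only)")
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValidationError(f"duplicate molecule ids in {path}: {dups[:5]}")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"duplicate sample ids in {path}: {dups[:5]}")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    return OmicsLayer(
        layer_kind=layer_kind,
        molecule_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
        values=values,
    )


def read_edge_list(path, weighted: bool = False) -> List[tuple]:
    """Read a 2-column (or 3-column weighted) tab-delimited edge list.

    A header line is tolerated: a first row whose weight column is not
    numeric (or, unweighted, whose first token looks like a header) is
    skipped only when it cannot be parsed as data.
    """
    edges: List[tuple] = []
    want = 3 if weighted else 2
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < want:
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} columns, expected {want}"
                )
            if weighted:
                try:
                    w = float(parts[2])
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise FormatError(f"{path}: line {lineno}: bad weight {parts[2]!r}")
                if w < 0:
                    raise FormatError(f"{path}: line {lineno}: negative weight {w}")
                edges.append((parts[0], parts[1], w))
            else:
                edges.append((parts[0], parts[1]))
    return edges


# ---------------------------------------------------------------- filters

def _percentile_keep_mask(summary: np.ndarray, percentile: float) -> np.ndarray:
    """Molecules strictly below the linear-interpolation percentile cut are
    removed; ties at the cut survive."""
    cut = np.percentile(summary, percentile * 100.0)
    return summary >= cut


def _check_fraction(percentile: float) -> None:
    if not (0.0 <= percentile < 1.0):
        raise ValidationError(f"percentile must be in [0, 1), got {percentile}")


def filter_low_variance(layer: OmicsLayer, percentile: float) -> OmicsLayer:
    """Remove molecules whose across-sample variance falls below the given
    percentile of the per-molecule variance distribution."""
    _check_fraction(percentile)
    if percentile == 0.0:
        return layer
    variances = layer.values.var(axis=0, ddof=1)
    keep = _percentile_keep_mask(variances, percentile)
    if not keep.any():
        raise ValidationError(f"empty {layer.layer_kind} layer after variance filtering")
    return layer.subset_molecules(keep)


def filter_low_value(layer: OmicsLayer, percentile: float, method: str = "mean") -> OmicsLayer:
    """Remove molecules whose overall magnitude summary (mean or max of
    absolute values, default mean) falls below the given percentile."""
    _check_fraction(percentile)
    if percentile == 0.0:
        return layer
    if method == "mean":
        summary = np.abs(layer.values).mean(axis=0)
    elif method == "max":
        summary = np.abs(layer.values).max(axis=0)
    else:
        raise ValidationError(f"unknown low-value summary {method!r}")
    keep = _percentile_keep_mask(summary, percentile)
    if not keep.any():
        raise ValidationError(f"empty {layer.layer_kind} layer after low-value filtering")
    return layer.subset_molecules(keep)


def drop_all_zero_rows(layer: OmicsLayer) -> OmicsLayer:
    """Remove molecules whose every expression value is exactly zero."""
    keep = ~(layer.values == 0).all(axis=0)
    if not keep.any():
        raise ValidationError(f"empty {layer.layer_kind} layer after filtering")
    if keep.all():
        return layer
    return layer.subset_molecules(keep)


def log2_and_shift(layer: OmicsLayer, shift_negatives: bool = False) -> OmicsLayer:
    """Apply v -> log2(v + 1) elementwise; strictly monotone, maps 0 to 0.

    With ``shift_negatives`` each molecule with a negative minimum is first
    shifted by -min (for pre-normalized inputs); off by default, in which
    case any negative value is an error.
    """
    values = layer.values
    if shift_negatives:
        mins = values.min(axis=0)
        shift = np.where(mins < 0, -mins, 0.0)
        values = values + shift
    if np.any(values < 0):
        raise ValidationError(
            f"negative values in {layer.layer_kind} layer; log2(v+1) requires v >= 0"
        )
    return OmicsLayer(
        layer_kind=layer.layer_kind,
        molecule_ids=list(layer.molecule_ids),
        sample_ids=list(layer.sample_ids),
        values=np.log2(values + 1.0),
    )


def preprocess_dataset(
    lnc: OmicsLayer,
    mir: OmicsLayer,
    mrna: OmicsLayer,
    var_cut: float = 0.30,
    low_cut: float = 0.60,
    low_value_method: str = "mean",
) -> TriOmicsDataset:
    """Full preprocessing chain on raw layers.

    Order: all-zero removal (miRNA) -> variance filter -> low-value filter
    (lncRNA/mRNA, cutoffs applied to raw values) -> log2(v+1) on all layers.
    """
    mir = drop_all_zero_rows(mir)
    out = []
    for layer in (lnc, mrna):
        layer = filter_low_variance(layer, var_cut)
        layer = filter_low_value(layer, low_cut, method=low_value_method)
        out.append(layer)
    lnc, mrna = out
    return TriOmicsDataset(
        lnc=log2_and_shift(lnc),
        mir=log2_and_shift(mir),
        mrna=log2_and_shift(mrna),
    )


# ------------------------------------------------------- interaction nets

def build_interaction_matrices(
    edges_ml: Iterable[Tuple[str, str]],
    edges_mg: Iterable[Tuple[str, str]],
    edges_gg: Iterable[Tuple[str, str, float]],
    dataset: TriOmicsDataset,
) -> Tuple[InteractionData, Dict[str, int]]:
    """Assemble A (miRNA x lncRNA), B (miRNA x mRNA) and C (mRNA x mRNA).

    Edges with an endpoint missing from the corresponding expression layer
    are dropped.  Duplicates collapse by OR for the binary networks and by
    maximum weight for the gene-gene network; C is symmetrized with zero
    diagonal.  Returns the matrices plus retained-edge counts per network.
    """
    lnc_idx = {m: i for i, m in enumerate(dataset.lnc.molecule_ids)}
    mir_idx = {m: i for i, m in enumerate(dataset.mir.molecule_ids)}
    mrna_idx = {m: i for i, m in enumerate(dataset.mrna.molecule_ids)}

    A = np.zeros((len(mir_idx), len(lnc_idx)))
    for edge in edges_ml:
        if len(edge) < 2:
            raise FormatError(f"miRNA-lncRNA edge {edge!r} needs two endpoints")
        m, l = edge[0], edge[1]
        if m in mir_idx and l in lnc_idx:
            A[mir_idx[m], lnc_idx[l]] = 1.0

    B = np.zeros((len(mir_idx), len(mrna_idx)))
    for edge in edges_mg:
        if len(edge) < 2:
            raise FormatError(f"miRNA-mRNA edge {edge!r} needs two endpoints")
        m, g = edge[0], edge[1]
        if m in mir_idx and g in mrna_idx:
            B[mir_idx[m], mrna_idx[g]] = 1.0

    C = np.zeros((len(mrna_idx), len(mrna_idx)))
    for edge in edges_gg:
        if len(edge) < 3:
            raise FormatError(f"gene-gene edge {edge!r} needs two endpoints and a weight")
        g1, g2, w = edge[0], edge[1], float(edge[2])
        if w < 0:
            raise FormatError(f"gene-gene edge ({g1}, {g2}) has negative weight {w}")
        if g1 == g2:
            continue  # self-interactions carry no between-gene information
        if g1 in mrna_idx and g2 in mrna_idx:
            i, j = mrna_idx[g1], mrna_idx[g2]
            if w > C[i, j]:
                C[i, j] = C[j, i] = w

    counts = {
        "miRNA-lncRNA": int(A.sum()),
        "miRNA-mRNA": int(B.sum()),
        "gene-gene": int(np.count_nonzero(np.triu(C, k=1))),
    }
    nets = InteractionData(
        A=A,
        B=B,
        C=C,
        lnc_ids=list(dataset.lnc.molecule_ids),
        mir_ids=list(dataset.mir.molecule_ids),
        mrna_ids=list(dataset.mrna.molecule_ids),
    )
    return nets, counts


# ---------------------------------------------------------------- writers

def write_expression_matrix(layer: OmicsLayer, path) -> None:
    """Write a layer back to the tab-delimited format ``read_expression_matrix`` reads."""
    df = pd.DataFrame(layer.values, index=layer.sample_ids, columns=layer.molecule_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_edge_list(edges: Sequence[tuple], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for edge in edges:
            fh.write("\t".join(str(x) for x in edge) + "\n")
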