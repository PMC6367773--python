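"""Turning coefficient matrices into tri-partite regulatory modules.

Each factorization column defines one module.  Within each coefficient
matrix the entries of column j are standardized to z-scores
z_ij = (h_ij - mu_j) / sigma_j (mu_j, sigma_j over the molecules in
column j, sample standard deviation), and molecule i joins module j
when z_ij strictly exceeds the threshold T.  Molecules may join several
modules; hubs typically do.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    FactorizationResult,
    ModuleSet,
    RegulatoryModule,
    ValidationError,
)

__all__ = [
    "zscore_columns",
    "extract_modules",
    "module_size_report",
    "modules_to_table",
    "table_to_modules",
    "best_match_jaccard",
]


def zscore_columns(H: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Column-wise z-scores of a molecules x K matrix.

    A constant column (sigma = 0) yields all-zero z-scores with a warning.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise ValidationError("zscore_columns expects a 2-D matrix")
    if H.shape[0] == 0:
        return H.copy()
    mu = H.mean(axis=0)
    sigma = H.std(axis=0, ddof=ddof) if H.shape[0] > ddof else np.zeros(H.shape[1])
    constant = sigma == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s); their z-scores are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, sigma)
    Z = (H - mu) / safe
    Z[:, constant] = 0.0
    return Z


def extract_modules(result: FactorizationResult, T: float = 2.0) -> ModuleSet:
    """Threshold column z-scores of H1/H2/H3 at T (strict) into K modules."""
    if result.lnc_ids is None or result.mir_ids is None or result.mrna_ids is None:
        raise ValidationError("factorization result carries no molecule id registries")
    K = result.K
    layers = (
        (result.H1, result.lnc_ids),
        (result.H2, result.mir_ids),
        (result.H3, result.mrna_ids),
    )
    zs = [zscore_columns(H) for H, _ in layers]
    modules: List[RegulatoryModule] = []
    for j in range(K):
        member_sets = []
        zmap: Dict[str, float] = {}
        for (H, ids), Z in zip(layers, zs):
            hit = np.flatnonzero(Z[:, j] > T) if Z.size else np.array([], dtype=int)
            members = frozenset(ids[i] for i in hit)
            member_sets.append(members)
            for i in hit:
                zmap[ids[i]] = float(Z[i, j])
        modules.append(
            RegulatoryModule(
                index=j + 1,
                lnc_members=member_sets[0],
                mir_members=member_sets[1],
                mrna_members=member_sets[2],
                member_zscores=zmap,
            )
        )
    return ModuleSet(modules=modules, threshold_used=T, provenance=result)


def module_size_report(ms: ModuleSet) -> pd.DataFrame:
    """Per-module member counts by layer, plus a trailing mean row
    (means rounded to one decimal)."""
    rows = []
    for mod in ms:
        n_l, n_m, n_g = mod.size()
        rows.append({"module": mod.index, "lncRNAs": n_l, "miRNAs": n_m, "mRNAs": n_g})
    df = pd.DataFrame(rows, columns=["module", "lncRNAs", "miRNAs", "mRNAs"])
    df = df.astype(object)  # keep counts integral next to the float mean row
    means = {
        "module": "mean",
        "lncRNAs": round(float(df["lncRNAs"].mean()), 1) if len(df) else 0.0,
        "miRNAs": round(float(df["miRNAs"].mean()), 1) if len(df) else 0.0,
        "mRNAs": round(float(df["mRNAs"].mean()), 1) if len(df) else 0.0,
    }
    return pd.concat([df, pd.DataFrame([means])], ignore_index=True)


# ------------------------------------------------------------ persistence

def modules_to_table(ms: ModuleSet) -> pd.DataFrame:
    """Flatten a ModuleSet to (module_index, layer, molecule_id, zscore) rows."""
    rows = []
    for mod in ms:
        for layer, members in (
            ("lncRNA", mod.lnc_members),
            ("miRNA", mod.mir_members),
            ("mRNA", mod.mrna_members),
        ):
            for m in sorted(members):
                rows.append(
                    {
                        "module_index": mod.index,
                        "layer": layer,
                        "molecule_id": m,
                        "zscore": mod.member_zscores.get(m, float("nan")),
                    }
                )
    return pd.DataFrame(rows, columns=["module_index", "layer", "molecule_id", "zscore"])


def table_to_modules(df: pd.DataFrame, K: Optional[int] = None,
                     threshold: float = float("nan")) -> ModuleSet:
    """Inverse of :func:`modules_to_table` (K pads trailing empty modules)."""
    if K is None:
        K = int(df["module_index"].max()) if len(df) else 0
    modules = []
    for j in range(1, K + 1):
        sub = df[df["module_index"] == j]
        members = {"lncRNA": set(), "miRNA": set(), "mRNA": set()}
        zmap: Dict[str, float] = {}
        for _, row in sub.iterrows():
            members[row["layer"]].add(row["molecule_id"])
            zmap[row["molecule_id"]] = float(row["zscore"])
        modules.append(
            RegulatoryModule(
                index=j,
                lnc_members=frozenset(members["lncRNA"]),
                mir_members=frozenset(members["miRNA"]),
                mrna_members=frozenset(members["mRNA"]),
                member_zscores=zmap,
            )
        )
    return ModuleSet(modules=modules, threshold_used=threshold)


# --------------------------------------------------------- recovery score

def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def best_match_jaccard(recovered: ModuleSet, planted: ModuleSet) -> Tuple[float, List[Tuple[int, int, float]]]:
    """Mean Jaccard similarity between recovered and planted modules under
    greedy maximum-Jaccard 1-1 matching (without replacement).

    Similarity is computed on the layer-tagged union of the three member
    sets.  Returns (mean over planted modules, list of (planted_index,
    recovered_index, jaccard)).  Ties break toward lower module indices.
    """
    rec = list(recovered)
    pla = list(planted)
    pairs = []
    for p_i, p in enumerate(pla):
        for r_i, r in enumerate(rec):
            pairs.append((_jaccard(p.all_members(), r.all_members()), p_i, r_i))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p, used_r = set(), set()
    matches = []
    for jac, p_i, r_i in pairs:
        if p_i in used_p or r_i in used_r:
            continue
        used_p.add(p_i)
        used_r.add(r_i)
        matches.append((pla[p_i].index, rec[r_i].index, jac))
        if len(used_p) == len(pla):
            break
    mean = float(np.mean([m[2] for m in matches])) if matches else 0.0
    return mean, matches
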