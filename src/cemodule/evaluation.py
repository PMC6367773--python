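"""Module scoring: correlation coherence, permutation nulls, enrichment.

The coherence of a module is the average absolute Pearson correlation
over all cross-layer member pairs,

    S(Cv) = ( sum|corr_lnc,mir| + sum|corr_mir,mrna| + sum|corr_lnc,mrna| ) / N,

with N the number of such pairs.  Significance comes from a permutation
null that redraws module membership uniformly from each layer while
preserving per-module slot sizes.  Gene-level annotation enrichment uses
the one-sided hypergeometric tail with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ModuleSet,
    RegulatoryModule,
    TriOmicsDataset,
    ValidationError,
)

__all__ = [
    "CorrelationScoreResult",
    "EnrichmentRecord",
    "correlation_score",
    "score_modules",
    "permutation_test",
    "hypergeometric_enrichment",
    "benjamini_hochberg",
    "read_gmt",
    "filter_gene_sets",
    "enrich_modules",
    "known_molecule_overlap",
]

#: variance below which an expression vector counts as constant
VARIANCE_GUARD = 1e-15


@dataclass
class CorrelationScoreResult:
    """Observed scores, permutation nulls and p-values for a ModuleSet."""

    per_module_score: Dict[int, float]
    pair_counts: Dict[int, int]
    null_scores: Optional[np.ndarray] = None  # (n_perm, K)
    p_values: Optional[Dict[int, float]] = None
    global_p: Optional[float] = None
    global_statistic: Optional[float] = None


@dataclass
class EnrichmentRecord:
    module_index: int
    term_id: str
    term_size: int
    overlap: int
    p_value: float
    q_value: float = float("nan")


# ------------------------------------------------------- correlation score

def _standardize_block(E: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Center columns; returns (centered, sum-of-squares, good mask).  A
    column with variance below the guard is flagged and its correlations
    count as 0."""
    V = E - E.mean(axis=0, keepdims=True)
    ss = (V * V).sum(axis=0)
    good = ss / max(E.shape[0], 1) >= VARIANCE_GUARD
    if not good.all():
        warnings.warn("near-constant expression vector; its correlations set to 0",
                      RuntimeWarning, stacklevel=3)
    return V, np.where(good, ss, 1.0), good


def _abs_corr_sum(block_a, block_b) -> float:
    """Sum of |Pearson r| over all column pairs of two centered blocks;
    r = cov / sqrt(ss_a * ss_b), matching the explicit covariance formula."""
    Va, ss_a, good_a = block_a
    Vb, ss_b, good_b = block_b
    if Va.shape[1] == 0 or Vb.shape[1] == 0:
        return 0.0
    R = np.abs(Va.T @ Vb) / np.sqrt(np.outer(ss_a, ss_b))
    R[~good_a, :] = 0.0
    R[:, ~good_b] = 0.0
    return float(R.sum())


def _member_matrix(module: RegulatoryModule, dataset: TriOmicsDataset):
    """Stack member expression vectors (S x m per layer), dataset order."""
    blocks = []
    for layer_name, layer in (
        ("lncRNA", dataset.lnc),
        ("miRNA", dataset.mir),
        ("mRNA", dataset.mrna),
    ):
        members = module.members(layer_name)
        idx = [i for i, m in enumerate(layer.molecule_ids) if m in members]
        missing = members - set(layer.molecule_ids)
        if missing:
            raise ValidationError(
                f"module {module.index}: {sorted(missing)[:5]} absent from {layer_name} layer"
            )
        blocks.append(layer.values[:, idx])
    return blocks


def correlation_score(
    module: RegulatoryModule, dataset: TriOmicsDataset
) -> Tuple[float, int]:
    """S(Cv) and the cross-layer pair count N for one module.

    Returns (nan, 0) when the module is empty in two or more layers
    (no cross-layer pair exists).
    """
    E1, E2, E3 = _member_matrix(module, dataset)
    n1, n2, n3 = E1.shape[1], E2.shape[1], E3.shape[1]
    N = n1 * n2 + n2 * n3 + n1 * n3
    if sum(n > 0 for n in (n1, n2, n3)) < 2 or N == 0:
        return float("nan"), 0
    b1 = _standardize_block(E1)
    b2 = _standardize_block(E2)
    b3 = _standardize_block(E3)
    total = _abs_corr_sum(b1, b2) + _abs_corr_sum(b2, b3) + _abs_corr_sum(b1, b3)
    return total / N, N


def score_modules(ms: ModuleSet, dataset: TriOmicsDataset) -> CorrelationScoreResult:
    scores, counts = {}, {}
    for mod in ms:
        s, n = correlation_score(mod, dataset)
        scores[mod.index] = s
        counts[mod.index] = n
    return CorrelationScoreResult(per_module_score=scores, pair_counts=counts)


# --------------------------------------------------------- permutation test

def permutation_test(
    ms: ModuleSet,
    dataset: TriOmicsDataset,
    n_perm: int = 1000,
    seed: int = 0,
) -> CorrelationScoreResult:
    """Permutation null for module coherence.

    Each permutation redraws every module's members uniformly at random
    (without replacement within a module slot, independently across
    modules and layers) from the corresponding layer's full molecule
    registry, preserving slot sizes, then recomputes S(Cv).  The
    per-module empirical p is (#{null >= observed} + 1) / (n_perm + 1);
    a pooled Wilcoxon rank-sum statistic compares all observed scores
    against all null scores.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = score_modules(ms, dataset)
    registries = {
        "lncRNA": list(dataset.lnc.molecule_ids),
        "miRNA": list(dataset.mir.molecule_ids),
        "mRNA": list(dataset.mrna.molecule_ids),
    }
    K = len(ms)
    null = np.full((n_perm, K), np.nan)
    for p in range(n_perm):
        for k, mod in enumerate(ms):
            sizes = mod.size()
            drawn = {}
            for layer, size in zip(("lncRNA", "miRNA", "mRNA"), sizes):
                pool = registries[layer]
                if size > len(pool):
                    raise ValidationError(
                        f"module {mod.index} has more {layer} members than the layer"
                    )
                drawn[layer] = frozenset(
                    pool[i] for i in rng.choice(len(pool), size=size, replace=False)
                )
            fake = RegulatoryModule(
                index=mod.index,
                lnc_members=drawn["lncRNA"],
                mir_members=drawn["miRNA"],
                mrna_members=drawn["mRNA"],
            )
            null[p, k], _ = correlation_score(fake, dataset)

    p_values: Dict[int, float] = {}
    for k, mod in enumerate(ms):
        obs = observed.per_module_score[mod.index]
        if np.isnan(obs):
            p_values[mod.index] = float("nan")
            continue
        col = null[:, k]
        valid = col[~np.isnan(col)]
        p_values[mod.index] = (float(np.sum(valid >= obs)) + 1.0) / (len(valid) + 1.0)

    obs_vec = np.array([v for v in observed.per_module_score.values() if not np.isnan(v)])
    null_vec = null[~np.isnan(null)]
    if len(obs_vec) and len(null_vec):
        stat, gp = stats.ranksums(obs_vec, null_vec)
    else:
        stat, gp = float("nan"), float("nan")
    return CorrelationScoreResult(
        per_module_score=observed.per_module_score,
        pair_counts=observed.pair_counts,
        null_scores=null,
        p_values=p_values,
        global_p=float(gp),
        global_statistic=float(stat),
    )


# ---------------------------------------------------------------- enrichment

def hypergeometric_enrichment(
    module_genes: Set[str], term: Set[str], universe: Set[str]
) -> float:
    """One-sided over-representation p-value P(X >= overlap)."""
    if not universe:
        raise ValidationError("enrichment universe is empty")
    module_genes = set(module_genes)
    term = set(term)
    universe = set(universe)
    if not term <= universe:
        raise ValidationError("term is not a subset of the universe")
    if not module_genes <= universe:
        raise ValidationError("module genes are not a subset of the universe")
    if not module_genes:
        return 1.0
    k = len(module_genes & term)
    # P(X >= k) for X ~ Hypergeom(M=|universe|, n=|term|, N=|module|)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(term), len(module_genes)))


def benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    """BH step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def read_gmt(path) -> Dict[str, Tuple[str, List[Tuple[str, Optional[str]]]]]:
    """Parse a GMT file into {name: (description, [(member, evidence|None), ...])}.

    A member token may carry an evidence code as ``GENE|CODE``.
    """
    sets: Dict[str, Tuple[str, List[Tuple[str, Optional[str]]]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}: line {lineno}: GMT needs name, description, members")
            members = []
            for tok in parts[2:]:
                if not tok:
                    continue
                if "|" in tok:
                    gene, code = tok.split("|", 1)
                    members.append((gene, code))
                else:
                    members.append((tok, None))
            sets[parts[0]] = (parts[1], members)
    return sets


def filter_gene_sets(
    collection: Mapping[str, Tuple[str, List[Tuple[str, Optional[str]]]]],
    min_size: int = 5,
    excluded_evidence: Sequence[str] = ("NAS", "ND", "EA"),
    universe: Optional[Set[str]] = None,
) -> Dict[str, Set[str]]:
    """Drop members with excluded evidence codes, then sets whose remaining
    membership (restricted to the universe, when given) is below min_size."""
    excluded = set(excluded_evidence)
    out: Dict[str, Set[str]] = {}
    for name, (_desc, members) in collection.items():
        genes = {g for g, code in members if code is None or code not in excluded}
        effective = genes & universe if universe is not None else genes
        if len(effective) >= min_size:
            out[name] = genes
    return out


def enrich_modules(
    ms: ModuleSet,
    gene_sets: Mapping[str, Set[str]],
    universe: Set[str],
) -> List[EnrichmentRecord]:
    """Hypergeometric enrichment of each module's mRNA members against each
    gene set; BH correction applied per module across terms."""
    records: List[EnrichmentRecord] = []
    for mod in ms:
        genes = set(mod.mrna_members) & universe
        mod_records = []
        for name, term in sorted(gene_sets.items()):
            term_u = set(term) & universe
            if not term_u:
                continue
            p = hypergeometric_enrichment(genes, term_u, universe)
            mod_records.append(
                EnrichmentRecord(
                    module_index=mod.index,
                    term_id=name,
                    term_size=len(term_u),
                    overlap=len(genes & term_u),
                    p_value=p,
                )
            )
        if mod_records:
            qs = benjamini_hochberg([r.p_value for r in mod_records])
            for r, q in zip(mod_records, qs):
                r.q_value = float(q)
        records.extend(mod_records)
    return records


def known_molecule_overlap(
    ms: ModuleSet,
    known: Set[str],
    layer: str,
    universe: Set[str],
) -> List[EnrichmentRecord]:
    """Per-module overlap of one layer's members with a known molecule list,
    hypergeometric p, BH-corrected across modules."""
    known_u = set(known) & universe
    records = []
    for mod in ms:
        members = set(mod.members(layer)) & universe
        p = hypergeometric_enrichment(members, known_u, universe)
        records.append(
            EnrichmentRecord(
                module_index=mod.index,
                term_id=f"known:{layer}",
                term_size=len(known_u),
                overlap=len(members & known_u),
                p_value=p,
            )
        )
    if records:
        qs = benjamini_hochberg([r.p_value for r in records])
        for r, q in zip(records, qs):
            r.q_value = float(q)
    return records
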