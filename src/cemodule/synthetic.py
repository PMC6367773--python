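"""Synthetic tri-omics data with planted co-modules.

The generator emulates exactly the structure the factorization model
assumes: a shared non-negative sample basis W* and sparse layer
loadings H1*, H2*, H3* whose support encodes K_true disjoint planted
modules, observed as Xi = W* Hi*^T plus truncated Gaussian noise.
Interaction networks are drawn edge-wise with a high probability for
cross-layer pairs sharing a planted module and a low background
probability otherwise, so network attraction and module structure
agree.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .datatypes import (
    InteractionData,
    ModuleSet,
    OmicsLayer,
    RegulatoryModule,
    TriOmicsDataset,
    ValidationError,
)
from .io_preprocess import write_edge_list, write_expression_matrix

__all__ = ["SyntheticSpec", "generate", "write_dataset"]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic instance.

    Defaults: 60 samples, layer sizes 150/60/150, five planted modules of
    10 lncRNAs / 4 miRNAs / 10 mRNAs each.  Planted loadings are drawn
    uniform(signal_strength, 2*signal_strength); layer sizes keep planted
    column support near 7%, which places even the weakest planted loading
    above two column standard deviations, so default-threshold extraction
    is informative about the factorization rather than about T.
    """

    S: int = 60
    N1: int = 150
    N2: int = 60
    N3: int = 150
    K_true: int = 5
    members_lnc: int = 10
    members_mir: int = 4
    members_mrna: int = 10
    signal_strength: float = 1.0
    noise_sd: float = 0.1
    background_edge_prob: float = 0.01
    within_module_edge_prob: float = 0.9
    background_loading: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.S, self.N1, self.N2, self.N3, self.K_true) < 1:
            raise ValidationError("S, N1, N2, N3 and K_true must be positive")
        for name, members, N in (
            ("lncRNA", self.members_lnc, self.N1),
            ("miRNA", self.members_mir, self.N2),
            ("mRNA", self.members_mrna, self.N3),
        ):
            if members < 1:
                raise ValidationError(f"members per module ({name}) must be >= 1")
            if members * self.K_true > N:
                raise ValidationError(
                    f"{name}: {members} members x {self.K_true} modules exceeds layer size {N}"
                )
        for name in ("background_edge_prob", "within_module_edge_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0 or self.signal_strength <= 0:
            raise ValidationError("noise_sd must be >= 0 and signal_strength > 0")


def _planted_loadings(
    rng: np.random.Generator, N: int, spec_members: int, K: int,
    signal: float, background: float,
) -> Tuple[np.ndarray, List[List[int]]]:
    """Sparse loading matrix whose support is K disjoint leading blocks."""
    H = np.zeros((N, K))
    memberships = []
    for k in range(K):
        idx = list(range(k * spec_members, (k + 1) * spec_members))
        H[idx, k] = rng.uniform(signal, 2.0 * signal, size=spec_members)
        memberships.append(idx)
    if background > 0:
        mask = H == 0
        H[mask] = rng.uniform(0.0, background, size=int(mask.sum()))
    return H, memberships


def generate(spec: SyntheticSpec) -> Tuple[TriOmicsDataset, InteractionData, ModuleSet]:
    """Draw (dataset, interaction networks, planted ModuleSet) from the spec."""
    rng = np.random.default_rng(spec.seed)
    K = spec.K_true

    Wstar = rng.uniform(0.0, 1.0, size=(spec.S, K))
    H1, mem1 = _planted_loadings(rng, spec.N1, spec.members_lnc, K,
                                 spec.signal_strength, spec.background_loading)
    H2, mem2 = _planted_loadings(rng, spec.N2, spec.members_mir, K,
                                 spec.signal_strength, spec.background_loading)
    H3, mem3 = _planted_loadings(rng, spec.N3, spec.members_mrna, K,
                                 spec.signal_strength, spec.background_loading)

    def observe(H: np.ndarray) -> np.ndarray:
        X = Wstar @ H.T
        if spec.noise_sd > 0:
            X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
        return np.clip(X, 0.0, None)  # truncate, keeping non-negativity

    lnc_ids = [f"lnc{i:04d}" for i in range(spec.N1)]
    mir_ids = [f"mir{i:04d}" for i in range(spec.N2)]
    mrna_ids = [f"gene{i:04d}" for i in range(spec.N3)]
    sample_ids = [f"sample{i:04d}" for i in range(spec.S)]

    dataset = TriOmicsDataset(
        lnc=OmicsLayer("lncRNA", lnc_ids, sample_ids, observe(H1)),
        mir=OmicsLayer("miRNA", mir_ids, sample_ids, observe(H2)),
        mrna=OmicsLayer("mRNA", mrna_ids, sample_ids, observe(H3)),
    )

    module_of_lnc = np.full(spec.N1, -1)
    module_of_mir = np.full(spec.N2, -1)
    module_of_mrna = np.full(spec.N3, -1)
    for k in range(K):
        module_of_lnc[mem1[k]] = k
        module_of_mir[mem2[k]] = k
        module_of_mrna[mem3[k]] = k

    def draw_bipartite(mod_rows: np.ndarray, mod_cols: np.ndarray) -> np.ndarray:
        shared = (mod_rows[:, None] == mod_cols[None, :]) & (mod_rows[:, None] >= 0)
        prob = np.where(shared, spec.within_module_edge_prob, spec.background_edge_prob)
        return (rng.random(prob.shape) < prob).astype(float)

    A = draw_bipartite(module_of_mir, module_of_lnc)
    B = draw_bipartite(module_of_mir, module_of_mrna)

    shared = (module_of_mrna[:, None] == module_of_mrna[None, :]) & (module_of_mrna[:, None] >= 0)
    prob = np.where(shared, spec.within_module_edge_prob, spec.background_edge_prob)
    upper = np.triu(rng.random(prob.shape) < prob, k=1)
    weights = np.triu(rng.uniform(0.5, 1.0, size=prob.shape), k=1)
    # weights on (0.5, 1]: flip the half-open side of rng.uniform
    weights = 1.5 - weights
    C = np.where(upper, weights, 0.0)
    C = C + C.T

    nets = InteractionData(A=A, B=B, C=C, lnc_ids=lnc_ids, mir_ids=mir_ids, mrna_ids=mrna_ids)

    modules = []
    for k in range(K):
        modules.append(
            RegulatoryModule(
                index=k + 1,
                lnc_members=frozenset(lnc_ids[i] for i in mem1[k]),
                mir_members=frozenset(mir_ids[i] for i in mem2[k]),
                mrna_members=frozenset(mrna_ids[i] for i in mem3[k]),
            )
        )
    truth = ModuleSet(modules=modules, threshold_used=float("nan"))
    return dataset, nets, truth


def write_dataset(dataset: TriOmicsDataset, nets: InteractionData, out_dir) -> None:
    """Write expression tables and edge lists in the formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(dataset.lnc, out / "lncRNA_expression.tsv")
    write_expression_matrix(dataset.mir, out / "miRNA_expression.tsv")
    write_expression_matrix(dataset.mrna, out / "mRNA_expression.tsv")

    ml_edges = [
        (nets.mir_ids[i], nets.lnc_ids[j])
        for i, j in zip(*np.nonzero(nets.A))
    ]
    mg_edges = [
        (nets.mir_ids[i], nets.mrna_ids[j])
        for i, j in zip(*np.nonzero(nets.B))
    ]
    gg_edges = [
        (nets.mrna_ids[i], nets.mrna_ids[j], f"{nets.C[i, j]:.10g}")
        for i, j in zip(*np.nonzero(np.triu(nets.C, k=1)))
    ]
    write_edge_list(ml_edges, out / "mirna_lncrna_edges.tsv")
    write_edge_list(mg_edges, out / "mirna_mrna_edges.tsv")
    write_edge_list(gg_edges, out / "gene_gene_edges.tsv")
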