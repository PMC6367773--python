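"""Core containers shared across the CeModule pipeline.

The pipeline operates on three sample-matched expression matrices
(lncRNA, miRNA, mRNA; samples on rows, molecules on columns), three
interaction networks (miRNA-lncRNA, miRNA-mRNA, weighted gene-gene),
and the factor matrices produced by the joint factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

LAYER_KINDS = ("lncRNA", "miRNA", "mRNA")


class CeModuleError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CeModuleError):
    """Invalid inputs, identifiers or dimensions."""


class FormatError(ValidationError):
    """Malformed input file."""


class NumericalError(CeModuleError):
    """Non-finite values encountered during optimization."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class OmicsLayer:
    """One expression layer: an S x N matrix with identifier registries."""

    layer_kind: str
    molecule_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray  # shape (S, N)

    def __post_init__(self) -> None:
        if self.layer_kind not in LAYER_KINDS:
            raise ValidationError(
                f"layer_kind must be one of {LAYER_KINDS}, got {self.layer_kind!r}"
            )
        self.molecule_ids = list(self.molecule_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.molecule_ids, f"molecule ids in {self.layer_kind} layer")
        _check_unique(self.sample_ids, f"sample ids in {self.layer_kind} layer")
        if self.values.shape != (len(self.sample_ids), len(self.molecule_ids)):
            raise ValidationError(
                f"{self.layer_kind} values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.molecule_ids)} molecules"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"non-finite expression values in {self.layer_kind} layer")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def subset_molecules(self, keep: np.ndarray) -> "OmicsLayer":
        """Return a copy restricted to the boolean/index mask ``keep`` (order kept)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return OmicsLayer(
            layer_kind=self.layer_kind,
            molecule_ids=[self.molecule_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[:, idx].copy(),
        )


@dataclass
class TriOmicsDataset:
    """Three expression layers sharing one ordered sample list."""

    lnc: OmicsLayer
    mir: OmicsLayer
    mrna: OmicsLayer

    def __post_init__(self) -> None:
        if not (self.lnc.sample_ids == self.mir.sample_ids == self.mrna.sample_ids):
            raise ValidationError("the three layers must share an identical ordered sample list")

    @property
    def sample_ids(self) -> List[str]:
        return self.lnc.sample_ids

    @property
    def n_samples(self) -> int:
        return self.lnc.n_samples

    def layer(self, kind: str) -> OmicsLayer:
        return {"lncRNA": self.lnc, "miRNA": self.mir, "mRNA": self.mrna}[kind]


@dataclass
class InteractionData:
    """Interaction networks aligned to a TriOmicsDataset's molecule orderings.

    A is miRNA x lncRNA (binary), B is miRNA x mRNA (binary), C is
    mRNA x mRNA (symmetric, non-negative weights, zero diagonal).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    lnc_ids: List[str]
    mir_ids: List[str]
    mrna_ids: List[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n1, n2, n3 = len(self.lnc_ids), len(self.mir_ids), len(self.mrna_ids)
        if self.A.shape != (n2, n1):
            raise ValidationError(f"A shape {self.A.shape} != ({n2}, {n1})")
        if self.B.shape != (n2, n3):
            raise ValidationError(f"B shape {self.B.shape} != ({n2}, {n3})")
        if self.C.shape != (n3, n3):
            raise ValidationError(f"C shape {self.C.shape} != ({n3}, {n3})")
        for name, M in (("A", self.A), ("B", self.B)):
            if not np.all(np.isin(M, (0.0, 1.0))):
                raise ValidationError(f"{name} must be binary")
        if np.any(self.C < 0):
            raise ValidationError("C must be non-negative")
        if not np.allclose(self.C, self.C.T):
            raise ValidationError("C must be symmetric")
        if np.any(np.diag(self.C) != 0):
            raise ValidationError("C must have zero diagonal")

    def check_alignment(self, dataset: TriOmicsDataset) -> None:
        if (
            self.lnc_ids != dataset.lnc.molecule_ids
            or self.mir_ids != dataset.mir.molecule_ids
            or self.mrna_ids != dataset.mrna.molecule_ids
        ):
            raise ValidationError("interaction matrices are not aligned to the dataset layers")


@dataclass
class Hyperparameters:
    """Weights of the factorization objective and solver controls.

    K is the reduced dimension (number of modules); alpha weighs the
    orthogonality pressure on each coefficient matrix; lambda1/2/3 weigh
    the miRNA-lncRNA, miRNA-mRNA and gene-gene network attraction terms;
    gamma1 penalizes ||W||_F^2 and gamma2 the entrywise L1 norm of the
    coefficient matrices; T is the z-score threshold used downstream.
    """

    K: int = 10
    alpha: float = 1.0
    lambda1: float = 0.01
    lambda2: float = 0.01
    lambda3: float = 0.01
    gamma1: float = 0.1
    gamma2: float = 0.1
    T: float = 2.0
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        for name in ("alpha", "lambda1", "lambda2", "lambda3", "gamma1", "gamma2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")

    def validate_for(self, dataset: TriOmicsDataset) -> None:
        sizes = [dataset.n_samples]
        # zero-width layers are allowed (single-layer reductions) and do not cap K
        for layer in (dataset.lnc, dataset.mir, dataset.mrna):
            if layer.n_molecules > 0:
                sizes.append(layer.n_molecules)
        if self.K > min(sizes):
            raise ValidationError(
                f"K={self.K} exceeds min(S, N1, N2, N3)={min(sizes)}"
            )


@dataclass
class FactorizationResult:
    """Factors W (S x K) and H1/H2/H3 (Ni x K) plus the optimization trace."""

    W: np.ndarray
    H1: np.ndarray
    H2: np.ndarray
    H3: np.ndarray
    objective_trace: List[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False
    seed_used: int = 0
    lnc_ids: Optional[List[str]] = None
    mir_ids: Optional[List[str]] = None
    mrna_ids: Optional[List[str]] = None

    @property
    def K(self) -> int:
        return self.W.shape[1]

    def factors(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return self.W, self.H1, self.H2, self.H3

    def copy(self) -> "FactorizationResult":
        return FactorizationResult(
            W=self.W.copy(),
            H1=self.H1.copy(),
            H2=self.H2.copy(),
            H3=self.H3.copy(),
            objective_trace=list(self.objective_trace),
            iterations_run=self.iterations_run,
            converged=self.converged,
            seed_used=self.seed_used,
            lnc_ids=None if self.lnc_ids is None else list(self.lnc_ids),
            mir_ids=None if self.mir_ids is None else list(self.mir_ids),
            mrna_ids=None if self.mrna_ids is None else list(self.mrna_ids),
        )


@dataclass
class RegulatoryModule:
    """One tri-partite module: member sets per layer with their z-scores."""

    index: int  # 1-based
    lnc_members: FrozenSet[str]
    mir_members: FrozenSet[str]
    mrna_members: FrozenSet[str]
    member_zscores: Dict[str, float] = field(default_factory=dict)

    def members(self, layer: str) -> FrozenSet[str]:
        return {
            "lncRNA": self.lnc_members,
            "miRNA": self.mir_members,
            "mRNA": self.mrna_members,
        }[layer]

    def all_members(self) -> FrozenSet[Tuple[str, str]]:
        """Layer-tagged union of the three member sets."""
        out = set()
        for layer in LAYER_KINDS:
            out.update((layer, m) for m in self.members(layer))
        return frozenset(out)

    def size(self) -> Tuple[int, int, int]:
        return (len(self.lnc_members), len(self.mir_members), len(self.mrna_members))


@dataclass
class ModuleSet:
    """All K modules extracted from one factorization."""

    modules: List[RegulatoryModule]
    threshold_used: float = float("nan")
    provenance: Optional[FactorizationResult] = None

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, i: int) -> RegulatoryModule:
        return self.modules[i]
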