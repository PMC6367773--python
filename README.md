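# cemodule

Discovery of tri-partite **ceRNA regulatory modules** — coherent groups of
lncRNAs, miRNAs and mRNAs — from sample-matched expression profiles, by
joint orthogonality non-negative matrix factorization with network
regularization and sparsity penalties.

Under the competing endogenous RNA (ceRNA) hypothesis, lncRNAs and mRNAs
that share miRNA response elements compete for miRNA binding, so their
expression is coupled across samples. `cemodule` is aimed at computational
biologists who have three expression matrices measured on the *same*
samples — X₁ (lncRNA), X₂ (miRNA), X₃ (mRNA) — plus curated interaction
networks, and want to find modules of molecules that co-vary and interact.

## Model

The three matrices Xᵢ ∈ ℝ^{S×Nᵢ} (samples × molecules, non-negative) are
factorized with one **shared** basis W ∈ ℝ^{S×K} and layer-specific
coefficient matrices Hᵢ ∈ ℝ^{Nᵢ×K}, minimizing

```
min  Σᵢ ( ‖Xᵢ − W Hᵢᵀ‖²_F + (α/2) ‖Hᵢᵀ Hᵢ − I‖²_F )
     − λ₁ Tr(H₂ᵀ A H₁) − λ₂ Tr(H₂ᵀ B H₃) − λ₃ Tr(H₃ᵀ C H₃)
     + γ₁ ‖W‖²_F + γ₂ Σᵢ ‖Hᵢ‖₁          s.t.  W ≥ 0, Hᵢ ≥ 0
```

where A (miRNA×lncRNA) and B (miRNA×mRNA) are binary interaction networks,
C (mRNA×mRNA) is a symmetric weighted gene network, the orthogonality term
pushes factor columns apart, the trace terms pull interacting molecules
into the same column, and the γ terms keep the solution sparse.  The
problem is solved by KKT-derived multiplicative updates that preserve
non-negativity and monotonically decrease the objective.  Each column j
then defines a module: molecule i joins module j when its column z-score
zᵢⱼ = (hᵢⱼ − μⱼ)/σⱼ exceeds a threshold T (default 2).

Modules are evaluated by the correlation score S(Cᵥ) — the mean absolute
Pearson correlation over all cross-layer member pairs — against a
permutation null with size-matched random modules, by hypergeometric
gene-set enrichment with Benjamini–Hochberg correction, and by the
topology (degree, betweenness, closeness) of the merged module network.

## Worked example

No external data are needed: the built-in generator plants modules in
synthetic tri-omics data with consistent interaction networks.

```python
import cemodule as cm

spec = cm.SyntheticSpec(seed=1)          # 60 samples, 150/60/150 molecules, 5 planted modules
dataset, nets, truth = cm.generate(spec)

hp = cm.Hyperparameters(K=5, seed=1, max_iter=3000)
result = cm.fit(dataset, nets, hp)
print(f"converged after {result.iterations_run} iterations, "
      f"objective {result.objective_trace[0]:.1f} -> {result.objective_trace[-1]:.1f}")

modules = cm.extract_modules(result, T=2.0)
print(cm.module_size_report(modules).to_string(index=False))

scores = cm.permutation_test(modules, dataset, n_perm=200, seed=1)
for mod in modules:
    print(f"module {mod.index}: S = {scores.per_module_score[mod.index]:.3f}, "
          f"p = {scores.p_values[mod.index]:.4f}")
print(f"pooled rank-sum p = {scores.global_p:.2e}")

jac, _ = cm.best_match_jaccard(modules, truth)
print(f"mean Jaccard vs planted modules: {jac:.2f}")
```

Output:

```
converged after 1757 iterations, objective 49540.6 -> 193.9
module lncRNAs miRNAs mRNAs
     1      10      4    10
     2      10      4    10
     3      10      4    10
     4      10      4    10
     5      10      4    10
  mean    10.0    4.0  10.0
module 1: S = 0.928, p = 0.0050
module 2: S = 0.956, p = 0.0050
module 3: S = 0.952, p = 0.0050
module 4: S = 0.953, p = 0.0050
module 5: S = 0.943, p = 0.0050
pooled rank-sum p = 1.13e-04
mean Jaccard vs planted modules: 1.00
```

The factorization recovers all five planted modules exactly (Jaccard 1.0);
every module's coherence score is far above its permutation null (the
empirical floor at 200 permutations is p = 1/201 ≈ 0.005).

## Command line

The same pipeline is available as subcommands, each writing a
`manifest_<command>.json` recording input hashes, seed and parameters:

```sh
cemodule simulate --seed 1 --out data/
cemodule preprocess --lnc lnc.tsv --mir mir.tsv --mrna mrna.tsv \
    --var-cut 0.30 --low-cut 0.60 --out data/
cemodule fit --data data/ --k 5 --seed 1 --out result.h5
cemodule extract --result result.h5 --threshold 2.0 --out modules.tsv
cemodule evaluate --modules modules.tsv --data data/ --n-perm 1000 --seed 1 --out eval/
cemodule topology --modules modules.tsv --data data/ --out topo/
```

Exit codes: 0 success, 2 usage, 3 validation error, 4 numerical error.

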