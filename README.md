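# xintnmf

Network-regularized non-negative matrix factorization (NMF) for multi-omics
integration, with an evaluation harness for classification, survival
analysis, and subtype discovery.

## The problem

Molecular layers measured on the same patients — mRNA expression, miRNA
expression, DNA methylation — are not independent: a miRNA represses its
target mRNAs, co-regulated genes covary, methylation silences expression.
Integration methods that factor each layer jointly but ignore these
feature–feature relations, especially the *cross*-omics ones, discard known
regulatory structure.  `xintnmf` is for computational biologists who want a
single low-dimensional patient representation learned from several omics
layers *and* from an interaction network spanning them.

## The model

Given D non-negative feature × sample matrices X⁽ᵈ⁾ ∈ ℝ₊^{m_d×N}, the model
learns omic-specific loadings W⁽ᵈ⁾ ∈ ℝ₊^{m_d×K} and one shared sample
factor matrix H ∈ ℝ₊^{K×N} by minimizing

```
f = ½ Σ_d ‖X⁽ᵈ⁾ − W⁽ᵈ⁾H‖²_F  +  (α/2)·Tr(W̄ᵀLW̄)  +  Σ_d β_d‖W⁽ᵈ⁾‖₁  +  Σ_i γ_i‖H·,ᵢ‖₁
```

where W̄ stacks all W⁽ᵈ⁾ along the feature axis and L = I − Δ^{−1/2}AΔ^{−1/2}
is the normalized Laplacian of a block interaction network A over all
features: block A⁽ᵖ۹⁾ holds the (binary) interactions between layers p and
q, supplied from prior knowledge (e.g. miRNA–mRNA target edge lists) or
computed from |Pearson correlation| thresholded to match the prior blocks'
density.  The Laplacian term pulls factor rows of interacting features
together across layers; α = 0 disables it (the ablation baseline).  The
per-sample sparsity weights γᵢ are selected once by cross-validation during
initialization (NNDSVD for W, non-negative Lasso for H) and frozen;
optimization alternates multiplicative W updates with exact per-sample
non-negative Lasso solves for H, and the objective is guaranteed
non-increasing.

Downstream, H columns feed a logistic classifier (AUC/MCC over repeated
80/20 splits with inner-CV grid search over K, α, β), an elastic-net Cox
model whose prognostic index PI = λᵀH_test median-splits patients into
risk groups compared by Kaplan–Meier/log-rank, and correlation-clustermap
subtyping.  See `docs/methods.md` for the full account.

## Worked example

Everything is driven by one YAML config.  Generate a synthetic two-layer
cohort with a planted informative network, fit, and evaluate:

```sh
cat > sim.yaml <<'EOF'
simulate: {N: 80, m: [60, 30], K_true: 4, n_groups: 3}
out: cohort
seed: 11
EOF
xintnmf simulate --config sim.yaml

cat > run.yaml <<'EOF'
layers:
  - {id: omic1, path: cohort/omic1.tsv}
  - {id: omic2, path: cohort/omic2.tsv}
network:
  prior_edges:
    "omic1,omic1": cohort/edges_omic1_omic1.tsv
    "omic1,omic2": cohort/edges_omic1_omic2.tsv
    "omic2,omic2": cohort/edges_omic2_omic2.tsv
clinical: cohort/clinical.tsv
hyperparameters: {K: 4, alpha: 1.0, beta: 0.01, max_iter: 500}
grid:
  K_values: [4]
  alpha_values: [0, 1, 10]
  beta_values: [0.01]
  n_splits: 10
  cv_folds: 3
  max_iter: 200
out: out
seed: 11
EOF
xintnmf fit      --config run.yaml
xintnmf classify --config run.yaml
xintnmf survival --config run.yaml
xintnmf subtype  --config run.yaml
```

which prints

```
cohort written to cohort
fit done: 119 iterations, objective 7.81126
mean AUC 1.0000, mean MCC 0.9402
log-rank statistic 3.9606, p = 0.04658
subtype assignments written to out/subtype_clusters.tsv
```

Reading the numbers: the fit converged in 119 alternating iterations to
objective value 7.81 (the trace is in `out/objective_trace.csv`; it is
non-increasing by construction).  Over 10 random 80/20 splits with 3-fold
inner CV over α ∈ {0, 1, 10}, the learned sample factors separate the
planted phenotype perfectly by AUC and near-perfectly by MCC — expected
here, since the synthetic groups are strongly separated at this noise
level.  The Cox prognostic index built on H splits patients into risk
groups whose survival curves differ significantly (log-rank p ≈ 0.047;
curves in `out/km_curves.svg`).  `out/` also contains the factor matrices
(`W_omic1.tsv`, `W_omic2.tsv`, `H.tsv`), the subtype clustermap, and a
`manifest.json` with the config hash and output checksums — rerunning the
same config and seed reproduces the checksums exactly.

The same pipeline is available as a library (`xintnmf.generate`,
`xintnmf.fit`, `xintnmf.transform`, `xintnmf.run_classification`, ...);
the CLI is a thin layer over it.

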