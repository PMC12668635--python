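# transmarker

Dynamic network biomarker (DNB) discovery from multi-state single-cell
expression data.

Diseases such as gastric adenocarcinoma progress through ordered pathological
states (normal → metaplasia → carcinoma → metastasis), and the genes that
mark those transitions are often not the most differentially expressed ones
but the ones whose *regulatory neighborhood is rewired* between states.
`transmarker` detects such genes by aligning state-specific gene regulatory
networks in embedding space. It is aimed at computational biologists working
with single-cell cohorts that span several disease states, and ships a
GRN-driven single-cell simulator so the whole pipeline can be exercised and
benchmarked without any external data.

## Method

For states t = 1..T over a shared gene panel 𝒱 (N genes):

1. **State-specific networks.** DEGs (|log₂FC| > 1, rank-sum p < 0.05
   against a reference state) plus optional pathway genes are mapped onto a
   prior regulatory network; the induced background is pruned per state with
   a path-consistency test on Gaussian (conditional) mutual information
   (order 0: MI = −½ log(1 − ρ²); order 1: CMI via covariance determinants;
   threshold 0.03), giving directed graphs E(t).
2. **Structural similarity.** S(t) = α·S_local + (1−α)·S_global with
   S_local,ij = exp(−d_ij) (shortest paths), S_global,ij = p_i·p_j
   (PageRank), both row-normalized; α = 0.3.
3. **Embeddings.** A two-layer graph attention network per state (64 hidden
   units, 2 heads, 62-d output) trained unsupervised to reconstruct the
   adjacency via Â_ij = σ(eᵢᵀeⱼ) with summed binary cross-entropy; S(t)
   weights the attention coefficients.
4. **Alignment.** Entropic Gromov–Wasserstein transport (ε = 10⁻²) couples
   consecutive states through their embedding distance matrices:
   min_Γ Σ (D_ij − D′_kl)² Γ_ik Γ_jl − εH(Γ). Per gene,
   R_i = Σ_t std(Γ_i,:^(t,t+1)) is the cumulative alignment score.
5. **Selection.** Genes above the knee of the descending R curve (top-15%
   fallback) form a union network across states; connected components C are
   ranked by the Dynamic Network Instability
   DNI_C = std_t exp((1 − ρ_C(t))·Ψ_C), with ρ the component's edge density
   and Ψ its summed alignment scores. The argmax component C* is the DNB
   module.
6. **Validation.** An MLP (128-64-32) classifies cells into states from the
   DNB genes' expression; accuracy, macro AUROC/AUPRC, F1, precision,
   recall and specificity are averaged over repeated stratified 70/10/20
   splits.

## Worked example

```python
from transmarker import simulate_dataset, PipelineConfig
from transmarker.classification import ClassifierConfig
from transmarker.pipeline import run_from_dataset

ds = simulate_dataset(n_genes=50, seed=11)      # 4 states x 100 cells
cfg = PipelineConfig(states=list(ds.state_names), seed=11,
                     classifier=ClassifierConfig(n_runs=10))
res = run_from_dataset(ds, cfg)
print(len(res.selected), len(res.dnb.genes), round(res.dnb.dni, 4))
print(res.metrics)
```

prints (numbers from this exact invocation):

```
16 15 0.0014
accuracy=0.8750±0.0250, auroc=0.9719±0.0098, auprc=0.9360±0.0219, f1=0.8739±0.0233, precision=0.8814±0.0222, recall=0.8750±0.0250, specificity=0.9583±0.0083
```

Here 16 genes sit above the knee of the alignment-score curve, 15 of them
form the most unstable union-network component (the DNB module), and the
MLP separates the four simulated disease states from those 15 genes'
expression with ~0.88 mean accuracy over 10 splits. Module size varies
strongly between simulated datasets (see `docs/methods.md`), and
classification quality tracks it.

The same pipeline is scriptable from the shell:

```bash
transmarker simulate --genes 50 --states 4 --cells 100 --seed 11 --out sim/
transmarker rewire --expr-dir sim/ --prior prior.tsv \
    --states state1,state2,state3,state4 --out run/
transmarker embed --run run/ --seed 11
transmarker align --run run/
transmarker rank  --run run/
transmarker classify --expr-dir sim/ --dnb run/dnb_genes.txt \
    --states state1,state2,state3,state4 --runs 50 --seed 11
```

or end-to-end with `transmarker run --config config.yaml`.

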