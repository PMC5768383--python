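# consmod

Consensus co-expression gene modules and eigengene-network preservation
across two expression cohorts.

When the same disease process is profiled in two tissues or cohorts —
for example HPV16-positive head-and-neck and cervical carcinomas —
the interesting question is not just which genes change, but whether
the *co-expression structure* is shared: do the same groups of genes
move together in both data sets, and do those groups relate to each
other the same way? `consmod` answers this with a weighted
co-expression workflow for paired cohorts:

1. **Screening** — per cohort, two-sided Mann-Whitney U tests of cancer
   vs normal; the significant sets are intersected into a common-gene
   list, and a consensus-connectivity filter keeps genes that are
   network hubs in *both* cohorts
   (`k_i = Σ_j a_ij`, consensus = min over cohorts).
2. **Consensus network** — per cohort, Pearson correlation →
   soft-threshold adjacency `a_ij = |r_ij|^β` (default β = 6) →
   topological overlap `TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`;
   the consensus similarity is the elementwise minimum of the two TOMs
   and `d = 1 − consensusTOM` is the clustering dissimilarity.
3. **Module detection** — average-linkage (UPGMA) clustering, a static
   height cut at 0.95 with minimum module size 25, grey for unassigned
   genes, colours assigned by decreasing size (turquoise = largest).
4. **Eigengenes** — each module is summarised by its eigengene, the
   first principal component of the standardised member genes
   (`E = C₁g₁ + C₂g₂ + … + C_ng_n`), with loadings and variance
   explained; per cohort, eigengenes are correlated into an eigengene
   network.
5. **Preservation** — for modules i, j with eigengenes in cohorts A, B:

       preserv_ij(A,B) = 1 − |cor(Eᵢ(A),Eⱼ(A)) − cor(Eᵢ(B),Eⱼ(B))| / 2

   per-module index `D_i = mean_{j≠i} preserv_ij`, overall
   `D = mean_i D_i`. D = 1 means the eigengene relationships are
   identical in both cohorts.

A latent-factor simulator (`simulate_pair`) plants known modules shared
across two cohorts — with a tunable cross-cohort degradation knob — so
every stage is validated against ground truth, and an EASE/Fisher
enrichment module scores detected modules against user-supplied GMT
gene sets. See `docs/methods.md` for the model details and design
decisions.

## Worked example

```python
from consmod import ConsensusModuleModel, SimulationConfig

model, truth = ConsensusModuleModel.from_simulation(
    SimulationConfig(seed=7), screen=False, n_hub=None
)
res = model.fit()
print(res.summary())
```

```
Consensus co-expression module analysis
=======================================================
Cohorts: A (27 samples), B (16 samples)
Genes clustered: 400
Network: beta=6.0 (unsigned), TOM similarity, combiner=min
Cut: height=0.95, min module size=25

   module  n_genes  var_expl_A  var_expl_B      D
turquoise       40      0.7734      0.7981 0.9186
     blue       40      0.7879      0.8388 0.8904
    brown       40      0.8237      0.8025 0.8915
   yellow       40      0.8074      0.7657 0.8768
    green       40      0.7967      0.7483 0.9167
      red       40      0.6809      0.7522 0.8305
    black       40      0.7739      0.7328 0.8414
     pink       39      0.7379      0.6615 0.8629
     grey       81      NaN         NaN     NaN

Overall preservation D = 0.878603 (rounded 0.88)
```

The simulated pair plants eight 40-gene modules (within-module
correlation 0.9² = 0.81) among 400 genes at the cohort sizes 27 and 16.
The pipeline recovers all eight as colour-labelled consensus modules
(one pink gene and the 80 background genes end up grey), each eigengene
explains ~70–84 % of its module's variance, and the per-module
preservation indices D lie around 0.83–0.92: the eigengene networks of
the two cohorts agree well, as they should for cohorts drawn from the
same generative structure — estimation noise at 16 samples keeps D
below 1. `truth.module` holds the planted labels if you want to score
the detection (adjusted Rand index 0.99 here).

The same analysis runs from files — `ConsensusModuleModel.from_tsv(...)`
— or from the command line:

```bash
consmod simulate --n-genes 400 --seed 7 --out fixture/
consmod preserve --expr-a fixture/expr_a.tsv --meta-a fixture/meta_a.tsv \
                 --expr-b fixture/expr_b.tsv --meta-b fixture/meta_b.tsv \
                 --no-screen --out results/
```

`results/` then contains `modules.tsv`, `dendrogram.json`, per-cohort
eigengene matrices and networks, `preservation.tsv` and
`preservation_summary.json`.

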