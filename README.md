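# tmephenotype

Immune phenotyping of the tumor microenvironment (TME) from bulk
transcriptomes, for cancer-genomics analysts who want the full chain —
infiltration scoring, subtype discovery, immune-escape genomics, survival —
as tested, scriptable Python rather than a pile of one-off R sessions.

The workflow mirrors how immune phenotypes are discovered in colorectal and
other solid tumors:

1. **Infiltration scoring.** For each sample, single-sample gene-set
   enrichment (ssGSEA) turns log-scale expression into one score per TME
   cell-type signature: with genes ranked per sample, the enrichment score
   is `ES(S) = Σ_i [ P_in(S, i) − P_out(S, i) ]`, the accumulated difference
   between the rank-weighted (`rank^α`, α = 0.25) in-set cumulative
   distribution and the uniform out-of-set one. Only ranks enter, so scores
   are invariant to monotone transforms of expression. Cross-platform
   cohorts are first merged with a parametric empirical-Bayes location/scale
   batch adjustment; raw counts pass through a log2-CPM transform.
2. **Subtype discovery.** Scaled scores (cohort min-max, per-cell-type
   z-scaling, positive/negative row folding) are clustered by consensus
   non-negative matrix factorization: `X ≈ WH` with Kullback–Leibler
   multiplicative updates, 30 seeded runs per rank on random 80%
   subsamples, consensus matrix `C_k[s,t]` = co-assignment frequency, and
   the rank is the highest k before the largest drop of the cophenetic
   correlation coefficient ρ_k. With three clusters the phenotypes are
   named from their aggregate profiles: **immune-active** (highest
   activated-adaptive infiltration), **stroma-rich** (highest stromal),
   **immune-desert** (the remainder).
3. **Immune-escape genomics.** Mutation load `log2(n + 1)`, SCNV load (%
   altered cytobands), cytolytic activity (geometric mean of GZMA and
   PRF1), TCR/BCR diversity (richness, Shannon entropy, evenness), and
   burden-adjusted differential tests: `subtype ~ burden + event` by
   logistic regression, genes below 2.5% prevalence excluded, CNV
   directions tested separately with opposite-direction calls zeroed.
4. **Survival.** Kaplan–Meier curves, log-rank tests, and Cox regression
   (Efron ties) with the two-stage rule that covariates reaching univariate
   p < 0.1 enter the multivariate model.
5. **Synthetic cohorts.** A seeded generator plants three infiltration
   archetypes (with a realistic within-phenotype infiltration continuum),
   burden-confounded mutations, direction-coded CNVs, clonotype tables,
   subtype-dependent survival and single-cell counts — with ground truth,
   so the whole pipeline is testable offline.

## Worked example

```python
import tmephenotype as t

cfg = t.GeneratorConfig(seed=7)          # 300 samples, 2,000 genes
cohort = t.generate_cohort(cfg)

im, result = t.phenotype_pipeline(cohort.expression, cohort.signatures, seed=7)
print("cophenetic:", {k: round(v, 3) for k, v in result.cophenetic.items()})
print("selected rank:", result.selected_rank)
print(result.phenotypes.value_counts().to_dict())

acc = (result.phenotypes == cohort.truth["phenotype"]).mean()
print(f"naming accuracy vs ground truth: {acc:.2f}")

rec = cohort.clinical[["os_time", "os_event"]].rename(
    columns={"os_time": "time", "os_event": "event"}).copy()
rec["stroma_rich"] = (result.phenotypes == "stroma-rich").astype(int)
from tmephenotype.survival import cox_fit
fit = cox_fit(rec, ["stroma_rich"], mode="univariate")
row = fit.table.loc["stroma_rich"]
print(f"stroma-rich HR {row['hr']:.2f} "
      f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), p = {row['p']:.2g}")
```

prints

```
cophenetic: {2: 0.998, 3: 0.998, 4: 0.961, 5: 0.96, 6: 0.948}
selected rank: 3
{'immune-desert': 109, 'immune-active': 99, 'stroma-rich': 92}
naming accuracy vs ground truth: 0.96
stroma-rich HR 2.08 (95% CI 1.53-2.83), p = 2.8e-06
```

Reading it: the cophenetic profile is stable through rank 3 and drops most
between 3 and 4, so three immune phenotypes are selected; 96% of samples
get their planted phenotype name back; and the stroma-rich phenotype
carries roughly doubled mortality hazard (the generator plants HR 2.3 —
the fit recovers it within estimation error at n = 300).

The same chain is available from the shell:

```sh
tmephenotype simulate --out cohort/ --seed 7
tmephenotype score --expr cohort/expression.tsv --gmt cohort/signatures.gmt \
    --meta cohort/sample_metadata.tsv --out infil.tsv
tmephenotype subtype --infil infil.tsv --ranks 2:6 --runs 30 --seed 7 --out subtypes/
tmephenotype genomics --labels subtypes/labels.tsv --mut cohort/mutations.tsv \
    --cnv cohort/cnv.tsv --out diff/
tmephenotype survival --clinical cohort/clinical.tsv \
    --labels subtypes/labels.tsv --endpoint os --out surv/
```

## Layout

| module | contents |
| --- | --- |
| `io_preprocess` | expression/GMT I/O, log2-CPM, empirical-Bayes batch calibration |
| `infiltration` | ssGSEA, normalization, ESTIMATE-style scores and purity, ratios/aggregates |
| `subtyping` | KL-NMF, consensus clustering, cophenetic rank selection, naming, pseudo-bulk |
| `genomics` | genomic scores, repertoire diversity, burden-adjusted differential tests, MAF reader |
| `survival` | Kaplan–Meier, log-rank, Cox with p < 0.1 enrollment |
| `synthetic_data` | seeded cohort generator with ground truth, file writers |
| `cli` | `tmephenotype` console entry point |

The bundled 31-cell-type signature file is a synthetic stand-in with
plausible marker genes — supply a curated GMT for real analyses. See
`docs/methods.md` for the model, parameter and calibration details.
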