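# Functional grouping of the 31 TME cell types used for aggregate scores
# and for naming NMF clusters. "activated_adaptive" is a subset of
# "adaptive"; group precedence for single-membership lookups is
# activated_adaptive > adaptive > innate > stromal.
adaptive:
  - Activated CD4 T cell
  - Activated CD8 T cell
  - Activated B cell
  - Central memory CD4 T cell
  - Central memory CD8 T cell
  - Effector memory CD4 T cell
  - Effector memory CD8 T cell
  - Gamma delta T cell
  - Immature B cell
  - Memory B cell
  - Regulatory T cell
  - T follicular helper cell
  - Type 1 T helper cell
  - Type 2 T helper cell
  - Type 17 T helper cell
activated_adaptive:
  - Activated CD4 T cell
  - Activated CD8 T cell
  - Activated B cell
  - Effector memory CD4 T cell
  - Effector memory CD8 T cell
innate:
  - Activated dendritic cell
  - Plasmacytoid dendritic cell
  - Immature dendritic cell
  - Macrophage M1
  - Macrophage M2
  - Natural killer cell
  - Natural killer T cell
  - CD56bright natural killer cell
  - CD56dim natural killer cell
  - MDSC
  - Mast cell
  - Monocyte
  - Neutrophil
  - Eosinophil
stromal:
  - Fibroblast
  - Endothelial cell
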