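# Default concept dictionaries: 14 cell types, 11 cytokines, 15 pathological
# processes mined against titles+abstracts of each disease corpus.
#
# An entry is either a bare term (canonical term matched as itself) or a
# mapping {canonical, variants}.  Matching is case-insensitive substring
# with two guards:
#   * a variant ending in a digit only matches when the next character is
#     not a digit (so IL-1 never fires inside IL-10/IL-17/IL-18, while
#     IL-1b and IL-1β still count as IL-1);
#   * a variant written with a leading "^" requires a word boundary before
#     it (so T-cell does not fire inside NKT-cell, and Treg does not fire
#     inside an arbitrary longer word).
# Hyphenated variants are listed with their space-separated twin where the
# literature uses both.  Plurals need no variants: substring matching
# covers "fibroblast" inside "fibroblasts".

cell_type:
  - macrophage
  - canonical: dendritic cells
    variants: ["dendritic cell", "dendritic-cell"]
  - monocyte
  - canonical: T-cell
    variants: ["^T-cell", "^T cell", "^T-lymphocyte", "^T lymphocyte"]
  - canonical: T-reg
    variants: ["^T-reg", "^T reg", "^Treg", "regulatory T"]
  - canonical: B-Cell
    variants: ["^B-cell", "^B cell", "^B-lymphocyte", "^B lymphocyte"]
  - fibroblast
  - osteoclast
  - osteoblast
  - endothelial
  - epithelial
  - chondrocyte
  - nerve
  - neuron

cytokine:
  - canonical: GM-CSF
    variants: ["GM-CSF", "GM CSF"]
  - canonical: IL-1
    variants: ["IL-1", "IL 1", "interleukin-1", "interleukin 1"]
  - canonical: IL-2
    variants: ["IL-2", "IL 2", "interleukin-2", "interleukin 2"]
  - canonical: IL-6
    variants: ["IL-6", "IL 6", "interleukin-6", "interleukin 6"]
  - canonical: IL-8
    variants: ["IL-8", "IL 8", "interleukin-8", "interleukin 8"]
  - canonical: IL-18
    variants: ["IL-18", "IL 18", "interleukin-18", "interleukin 18"]
  - canonical: IL-17
    variants: ["IL-17", "IL 17", "interleukin-17", "interleukin 17"]
  - canonical: IL-10
    variants: ["IL-10", "IL 10", "interleukin-10", "interleukin 10"]
  - canonical: TNF
    variants: ["TNF", "tumor necrosis factor"]
  - RANKL
  - interleukin

process:
  - angiogenesis
  - apoptosis
  - autoantibody
  - biomarker
  - degeneration
  - diagnosis
  - fatigue
  - fibrosis
  - inflammation
  - invasion
  - metabolism
  - migration
  - pain
  - proliferation
  - therapy
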