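# Bundled reference dataset for five mammalian epithelial cell lines:
# fluorescence-marked volume statistics (confocal volumetry; pL) and
# whole-cell-lysate protein abundances (quantitative immunoblots;
# molecules per cell).
#
# volumes_pl: mean [and sd] per marker for the total population, the
#   non-dividing (nd) and the dividing (d) sub-populations.  The Vybrant DiI
#   non-dividing mean is the resting whole-cell volume used to convert
#   molecules per cell to molar concentration.
# molecules_per_cell: thousands of molecules per cell.
# population: cell counts behind the non-dividing/dividing split, with the
#   calcein-vs-hoechst linear-fit R^2 for the whole table and the ND subset.
cell_lines:
  HEK293T:
    lineage: kidney epithelial
    population: {total: 83, nd: 76, d: 7, total_r2: 0.78, nd_r2: 0.58}
    volumes_pl:
      calcein: {total: [1.55, 0.51], nd: [1.44, 0.35], d: [2.75, 0.39]}
      hoechst: {total: [0.69, 0.21], nd: [0.65, 0.14], d: [1.13, 0.28]}
      dii:     {total: [1.97, 0.73], nd: [1.82, 0.51], d: [3.66, 0.62]}
    molecules_per_cell_k:
      beta_catenin: 540
      e_cadherin: 30
      axin: 160
      apc: 4
      gsk3: 80
  MDCK:
    lineage: kidney epithelial
    population: {total: 56, nd: 48, d: 8, total_r2: 0.80, nd_r2: 0.58}
    volumes_pl:
      calcein: {total: [1.39, 0.42], nd: [1.27, 0.29], d: [2.15, 0.24]}
      hoechst: {total: [0.40, 0.11], nd: [0.36, 0.08], d: [0.61, 0.07]}
      dii:     {total: [1.65, 0.51], nd: [1.50, 0.36], d: [2.53, 0.37]}
    molecules_per_cell_k:
      beta_catenin: 1400
      e_cadherin: 510
      axin: 99
      apc: 8
      gsk3: 110
  Caco-2:
    lineage: intestinal epithelial
    population: {total: 119, nd: 110, d: 9, total_r2: 0.99, nd_r2: 0.71}
    volumes_pl:
      calcein: {total: [2.23, 0.88], nd: [2.08, 0.68], d: [4.16, 0.83]}
      hoechst: {total: [0.80, 0.33], nd: [0.74, 0.22], d: [1.61, 0.39]}
      dii:     {total: [2.81, 1.11], nd: [2.61, 0.85], d: [5.28, 1.02]}
    molecules_per_cell_k:
      beta_catenin: 610
      e_cadherin: 440
      axin: 50
      apc: 27
      gsk3: 90
    apc_truncated: true
  SW480:
    lineage: intestinal epithelial
    population: {total: 72, nd: 68, d: 4, total_r2: 0.80, nd_r2: 0.68}
    volumes_pl:
      calcein: {total: [1.64, 0.73], nd: [1.52, 0.51], d: [3.62, 1.06]}
      hoechst: {total: [0.53, 0.20], nd: [0.50, 0.15], d: [1.03, 0.27]}
      dii:     {total: [2.11, 0.90], nd: [1.97, 0.65], d: [4.46, 1.40]}
    molecules_per_cell_k:
      beta_catenin: 780
      e_cadherin: 100
      axin: 40
      apc: 40
      gsk3: 25
    apc_truncated: true
  SW480APC:
    lineage: intestinal epithelial
    population: {total: 139, nd: 127, d: 12, total_r2: 0.99, nd_r2: 0.99}
    volumes_pl:
      calcein: {total: [1.33, 0.49], nd: [1.22, 0.32], d: [2.47, 0.50]}
      hoechst: {total: [0.45, 0.17], nd: [0.41, 0.10], d: [0.83, 0.24]}
      dii:     {total: [1.70, 0.68], nd: [1.56, 0.45], d: [3.18, 0.89]}
    molecules_per_cell_k:
      beta_catenin: 640
      e_cadherin: 180
      axin: 20
      apc: 23
      gsk3: 10
    apc_truncated: true
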