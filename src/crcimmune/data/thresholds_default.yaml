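# Default marker positivity thresholds, in the same arbitrary fluorescence
# units as the cell-table intensities.  Real datasets set these per marker
# from manually phenotyped reference cells; the synthetic generator emits
# intensities on a unit scale where 1.0 separates background from signal.
schema_version: 1
panels:
  lymphocyte:
    CD4: 1.0
    CD8: 1.0
    CD20: 1.0
    FoxP3: 1.0
    CD45RO: 1.0
    panCK: 1.0
  nk_macrophage:
    CD56: 1.0
    NKp46: 1.0
    CD3: 1.0
    CD68: 1.0
    CD163: 1.0
    panCK: 1.0
  dendritic:
    CD3: 1.0
    CD1a: 1.0
    CD208: 1.0
    CD123: 1.0
    CD68: 1.0
    CD15: 1.0
    panCK: 1.0
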