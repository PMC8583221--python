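# Default 15-subclass gating scheme.
#
# Rules are evaluated in file order, first match wins; cells matching no rule
# (including every pan-cytokeratin-positive cell) are labeled "other".
# This file is data, not code: override it to change the gating without
# touching the package.  Marker combinations follow standard immune marker
# biology: FoxP3 marks regulatory T cells within the CD4/CD8 lineages,
# CD45RO marks memory T cells, CD56/NKp46 mark NK lineage with CD3 splitting
# NK from NKT, CD68 marks macrophages with CD163 distinguishing M2 from M1
# polarization, and CD1a/CD208/CD123 mark immature, mature and plasmacytoid
# dendritic cells.  Single-positive T-cell classes are defined FoxP3- CD45RO-
# so the lymphocyte classes partition cleanly.
schema_version: 1
rules:
  # lymphocyte panel -------------------------------------------------
  - subclass: CD4_sp
    panel: lymphocyte
    all_of: [CD4]
    none_of: [FoxP3, CD45RO, panCK]
  - subclass: CD8_sp
    panel: lymphocyte
    all_of: [CD8]
    none_of: [FoxP3, CD45RO, panCK]
  - subclass: CD4_Treg
    panel: lymphocyte
    all_of: [CD4, FoxP3]
    none_of: [panCK]
  - subclass: CD8_Treg
    panel: lymphocyte
    all_of: [CD8, FoxP3]
    none_of: [panCK]
  - subclass: CD4_CD45RO
    panel: lymphocyte
    all_of: [CD4, CD45RO]
    none_of: [panCK]
  - subclass: CD8_CD45RO
    panel: lymphocyte
    all_of: [CD8, CD45RO]
    none_of: [panCK]
  - subclass: B_cell
    panel: lymphocyte
    all_of: [CD20]
    none_of: [panCK]
  # NK / macrophage panel --------------------------------------------
  - subclass: NK
    panel: nk_macrophage
    any_of: [CD56, NKp46]
    none_of: [CD3, panCK]
  - subclass: NKT
    panel: nk_macrophage
    all_of: [CD3]
    any_of: [CD56, NKp46]
    none_of: [panCK]
  - subclass: M1
    panel: nk_macrophage
    all_of: [CD68]
    none_of: [CD163, panCK]
  - subclass: M2
    panel: nk_macrophage
    all_of: [CD68, CD163]
    none_of: [panCK]
  # dendritic cell panel ---------------------------------------------
  - subclass: iDC
    panel: dendritic
    all_of: [CD1a]
    none_of: [panCK]
  - subclass: mDC
    panel: dendritic
    all_of: [CD208]
    none_of: [panCK]
  - subclass: pDC
    panel: dendritic
    all_of: [CD123]
    none_of: [panCK]
  - subclass: myeloid
    panel: dendritic
    all_of: [CD15]
    none_of: [CD68, panCK]
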