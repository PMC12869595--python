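# Default white-matter pathway registry: 64 bundles in 6 categories,
# TractSeg nomenclature. ap_rank orders bundles anterior -> posterior
# within a category (plotting convention, not a geometric computation).
pathways:
  # association (9 bilateral pairs = 18)
  - {name: UF_left,       category: association, hemisphere: left,  ap_rank: 1, homologue: UF_right}
  - {name: UF_right,      category: association, hemisphere: right, ap_rank: 1, homologue: UF_left}
  - {name: IFO_left,      category: association, hemisphere: left,  ap_rank: 2, homologue: IFO_right}
  - {name: IFO_right,     category: association, hemisphere: right, ap_rank: 2, homologue: IFO_left}
  - {name: AF_left,       category: association, hemisphere: left,  ap_rank: 3, homologue: AF_right}
  - {name: AF_right,      category: association, hemisphere: right, ap_rank: 3, homologue: AF_left}
  - {name: SLF_III_left,  category: association, hemisphere: left,  ap_rank: 4, homologue: SLF_III_right}
  - {name: SLF_III_right, category: association, hemisphere: right, ap_rank: 4, homologue: SLF_III_left}
  - {name: SLF_II_left,   category: association, hemisphere: left,  ap_rank: 5, homologue: SLF_II_right}
  - {name: SLF_II_right,  category: association, hemisphere: right, ap_rank: 5, homologue: SLF_II_left}
  - {name: SLF_I_left,    category: association, hemisphere: left,  ap_rank: 6, homologue: SLF_I_right}
  - {name: SLF_I_right,   category: association, hemisphere: right, ap_rank: 6, homologue: SLF_I_left}
  - {name: CG_left,       category: association, hemisphere: left,  ap_rank: 7, homologue: CG_right}
  - {name: CG_right,      category: association, hemisphere: right, ap_rank: 7, homologue: CG_left}
  - {name: MLF_left,      category: association, hemisphere: left,  ap_rank: 8, homologue: MLF_right}
  - {name: MLF_right,     category: association, hemisphere: right, ap_rank: 8, homologue: MLF_left}
  - {name: ILF_left,      category: association, hemisphere: left,  ap_rank: 9, homologue: ILF_right}
  - {name: ILF_right,     category: association, hemisphere: right, ap_rank: 9, homologue: ILF_left}
  # commissural (7 midline)
  - {name: CC_1, category: commissural, hemisphere: midline, ap_rank: 1, homologue: null}
  - {name: CC_2, category: commissural, hemisphere: midline, ap_rank: 2, homologue: null}
  - {name: CC_3, category: commissural, hemisphere: midline, ap_rank: 3, homologue: null}
  - {name: CC_4, category: commissural, hemisphere: midline, ap_rank: 4, homologue: null}
  - {name: CC_5, category: commissural, hemisphere: midline, ap_rank: 5, homologue: null}
  - {name: CC_6, category: commissural, hemisphere: midline, ap_rank: 6, homologue: null}
  - {name: CC_7, category: commissural, hemisphere: midline, ap_rank: 7, homologue: null}
  # thalamic (8 bilateral pairs = 16)
  - {name: ATR_left,      category: thalamic, hemisphere: left,  ap_rank: 1, homologue: ATR_right}
  - {name: ATR_right,     category: thalamic, hemisphere: right, ap_rank: 1, homologue: ATR_left}
  - {name: T_PREF_left,   category: thalamic, hemisphere: left,  ap_rank: 2, homologue: T_PREF_right}
  - {name: T_PREF_right,  category: thalamic, hemisphere: right, ap_rank: 2, homologue: T_PREF_left}
  - {name: T_PREC_left,   category: thalamic, hemisphere: left,  ap_rank: 3, homologue: T_PREC_right}
  - {name: T_PREC_right,  category: thalamic, hemisphere: right, ap_rank: 3, homologue: T_PREC_left}
  - {name: STR_left,      category: thalamic, hemisphere: left,  ap_rank: 4, homologue: STR_right}
  - {name: STR_right,     category: thalamic, hemisphere: right, ap_rank: 4, homologue: STR_left}
  - {name: T_POSTC_left,  category: thalamic, hemisphere: left,  ap_rank: 5, homologue: T_POSTC_right}
  - {name: T_POSTC_right, category: thalamic, hemisphere: right, ap_rank: 5, homologue: T_POSTC_left}
  - {name: T_PAR_left,    category: thalamic, hemisphere: left,  ap_rank: 6, homologue: T_PAR_right}
  - {name: T_PAR_right,   category: thalamic, hemisphere: right, ap_rank: 6, homologue: T_PAR_left}
  - {name: OR_left,       category: thalamic, hemisphere: left,  ap_rank: 7, homologue: OR_right}
  - {name: OR_right,      category: thalamic, hemisphere: right, ap_rank: 7, homologue: OR_left}
  - {name: T_OCC_left,    category: thalamic, hemisphere: left,  ap_rank: 8, homologue: T_OCC_right}
  - {name: T_OCC_right,   category: thalamic, hemisphere: right, ap_rank: 8, homologue: T_OCC_left}
  # striatal (6 bilateral pairs = 12)
  - {name: ST_FO_left,     category: striatal, hemisphere: left,  ap_rank: 1, homologue: ST_FO_right}
  - {name: ST_FO_right,    category: striatal, hemisphere: right, ap_rank: 1, homologue: ST_FO_left}
  - {name: ST_PREF_left,   category: striatal, hemisphere: left,  ap_rank: 2, homologue: ST_PREF_right}
  - {name: ST_PREF_right,  category: striatal, hemisphere: right, ap_rank: 2, homologue: ST_PREF_left}
  - {name: ST_PREC_left,   category: striatal, hemisphere: left,  ap_rank: 3, homologue: ST_PREC_right}
  - {name: ST_PREC_right,  category: striatal, hemisphere: right, ap_rank: 3, homologue: ST_PREC_left}
  - {name: ST_POSTC_left,  category: striatal, hemisphere: left,  ap_rank: 4, homologue: ST_POSTC_right}
  - {name: ST_POSTC_right, category: striatal, hemisphere: right, ap_rank: 4, homologue: ST_POSTC_left}
  - {name: ST_PAR_left,    category: striatal, hemisphere: left,  ap_rank: 5, homologue: ST_PAR_right}
  - {name: ST_PAR_right,   category: striatal, hemisphere: right, ap_rank: 5, homologue: ST_PAR_left}
  - {name: ST_OCC_left,    category: striatal, hemisphere: left,  ap_rank: 6, homologue: ST_OCC_right}
  - {name: ST_OCC_right,   category: striatal, hemisphere: right, ap_rank: 6, homologue: ST_OCC_left}
  # projection (3 bilateral pairs = 6)
  - {name: FPT_left,   category: projection, hemisphere: left,  ap_rank: 1, homologue: FPT_right}
  - {name: FPT_right,  category: projection, hemisphere: right, ap_rank: 1, homologue: FPT_left}
  - {name: CST_left,   category: projection, hemisphere: left,  ap_rank: 2, homologue: CST_right}
  - {name: CST_right,  category: projection, hemisphere: right, ap_rank: 2, homologue: CST_left}
  - {name: POPT_left,  category: projection, hemisphere: left,  ap_rank: 3, homologue: POPT_right}
  - {name: POPT_right, category: projection, hemisphere: right, ap_rank: 3, homologue: POPT_left}
  # cerebellar (2 bilateral pairs + 1 midline = 5)
  - {name: SCP_left,  category: cerebellar, hemisphere: left,  ap_rank: 1, homologue: SCP_right}
  - {name: SCP_right, category: cerebellar, hemisphere: right, ap_rank: 1, homologue: SCP_left}
  - {name: MCP,       category: cerebellar, hemisphere: midline, ap_rank: 2, homologue: null}
  - {name: ICP_left,  category: cerebellar, hemisphere: left,  ap_rank: 3, homologue: ICP_right}
  - {name: ICP_right, category: cerebellar, hemisphere: right, ap_rank: 3, homologue: ICP_left}
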