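# Illustrative diabetic-macular-edema-like characterization for demos and
# tests.  Four pathophysiological processes with a partial effector list
# (pathological direction: +1 hyperactivated in disease, -1 hypoactivated);
# drug targets for an aflibercept-like anti-VEGF stimulus.  This fixture is
# synthetic in membership: it names real proteins but is NOT a complete
# disease characterization.
aliases:
  VEGFR1: FLT1
  VEGFR2: KDR
  PlGF: PGF
  Gal-1: LGALS1
processes:
  oxidative_stress:
    HIF1A: 1
    NOS2: 1
    NOS3: 1
    CA9: 1
    PRDX3: 1
    MAPK14: 1
    EPOR: 1
  inflammation:
    IL6: 1
    TNF: 1
    CXCL8: 1
    CCL2: 1
    CCL5: 1
    IL1B: 1
    CXCL10: 1
    ICAM1: 1
    VCAM1: 1
    SELE: 1
    NFKB2: 1
    RELA: 1
    SERPINF1: -1
    NOS2: 1
  brb_alteration:
    TJP1: -1
    MMP9: 1
    MMP1: 1
    FN1: 1
    TGFB1: 1
    SRC: 1
    PLCG1: 1
    ICAM1: 1
    VCAM1: 1
  angiogenesis:
    VEGFA: 1
    ANGPT2: 1
    FGF2: 1
    PDGFB: 1
    BCL2: 1
    CXCR4: 1
    ROBO4: 1
    NOTCH1: 1
    HIF1A: 1
    MMP9: 1
drugs:
  aflibercept:
    VEGFA: -1
    VEGFB: -1
    PlGF: -1
    Gal-1: -1
    VEGFR1: -1
    VEGFR2: -1
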