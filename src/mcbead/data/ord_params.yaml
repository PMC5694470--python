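# Maximal conductances / permeabilities of the O'Hara-Rudy (2011) human
# ventricular myocyte model, with cell-type multipliers and the Dutta et
# al. (2017) rescalings defining the OHRmv variant.  Units follow the
# published model (mS/uF for conductances, cm/s-equivalent permeabilities
# for PCa/PNab/PCab).
version: 1
base:
  GNa: 75.0
  GNaL: 0.0075
  Gto: 0.02
  PCa: 0.0001
  GKr: 0.046
  GKs: 0.0034
  GK1: 0.1908
  Gncx: 0.0008
  Pnak: 30.0
  GKb: 0.003
  PNab: 3.75e-10
  PCab: 2.5e-8
  GpCa: 0.0005
cell_type_multipliers:
  endo: {}
  epi:
    GNaL: 0.6
    Gto: 4.0
    PCa: 1.2
    GKr: 1.3
    GKs: 1.4
    GK1: 1.2
    Gncx: 1.1
    Pnak: 0.9
    GKb: 0.6
  mid:
    Gto: 4.0
    PCa: 2.5
    GKr: 0.8
    GK1: 1.3
    Gncx: 1.4
    Pnak: 0.7
variants:
  OHR: {}
  OHRmv:
    GKr: 1.119
    GKs: 1.648
    GK1: 1.414
    GNaL: 2.661
    PCa: 1.018
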