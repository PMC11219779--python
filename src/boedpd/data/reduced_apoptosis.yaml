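# Reduced PARP1-inhibited apoptosis network (synthetic desk-scale stand-in).
#
# A 10-species, 11-uncertain-parameter mass-action/Hill network capturing the
# two competing fates of a cell with DNA double-strand breaks (DSB): repair
# (PARP1-mediated, suppressed by a potent inhibitor, i.e. at low IC50) versus
# caspase-mediated programmed cell death via p53 -> Bax transcription ->
# displacement of Bad from Bcl-xL -> caspase activation.  The inhibitor
# enters through a Hill-type factor IC50/(IC50 + K_I) multiplying the repair
# flux: a low-IC50 (potent) inhibitor shuts repair down, damage persists and
# the caspase cascade fires.  Calibrated so that at nominal parameters
# apoptosis (Casp_act peak >= 1000 molecules/cell) is triggered for
# IC50 <= 0.001 and not triggered for IC50 >= 100.
#
# Concentrations are molecules per cell; IC50 and time are in consistent
# arbitrary units.
name: reduced_apoptosis
tau: 30.0
species:
  - {name: DSB,        y0: 100.0,   measurable: false}
  - {name: p53_act,    y0: 0.0,     measurable: true}
  - {name: mRNA_Bax,   y0: 0.0,     measurable: true}
  - {name: Bax,        y0: 0.0,     measurable: false}
  - {name: Bcl_xL,     y0: 200.0,   measurable: false}
  - {name: Bad,        y0: 0.0,     measurable: false}
  - {name: Bad_Bcl_xL, y0: 300.0,   measurable: true}
  - {name: Bax_Bcl_xL, y0: 0.0,     measurable: false}
  - {name: Casp_pro,   y0: 10000.0, measurable: true}
  - {name: Casp_act,   y0: 0.0,     measurable: true}
parameters:
  - {name: k_rep,  value: 1.0,     uncertain: true}   # DSB repair rate (PARP1-dependent)
  - {name: K_I,    value: 1.0,     uncertain: false}  # inhibition half-saturation for the IC50 coupling
  - {name: k_p53,  value: 0.1,     uncertain: true}   # p53 activation by damage
  - {name: d_p53,  value: 0.2,     uncertain: true}   # p53 deactivation
  - {name: k_tx,   value: 0.05,    uncertain: true}   # Bax transcription by p53
  - {name: d_mRNA, value: 0.2,     uncertain: true}   # Bax mRNA decay
  - {name: k_tl,   value: 0.5,     uncertain: true}   # Bax translation
  - {name: d_Bax,  value: 0.1,     uncertain: true}   # Bax degradation
  - {name: k_bind, value: 0.01,    uncertain: true}   # Bad + Bcl-xL association
  - {name: k_disp, value: 0.001,   uncertain: true}   # Bax displaces Bad from Bcl-xL
  - {name: k_act,  value: 0.0025,  uncertain: true}   # caspase activation by free Bax
  - {name: d_casp, value: 0.12,    uncertain: true}   # active caspase degradation
reactions:
  - rate: k_rep * IC50 / (IC50 + K_I) * DSB
    stoichiometry: {DSB: -1}
  - rate: k_p53 * DSB
    stoichiometry: {p53_act: 1}
  - rate: d_p53 * p53_act
    stoichiometry: {p53_act: -1}
  - rate: k_tx * p53_act
    stoichiometry: {mRNA_Bax: 1}
  - rate: d_mRNA * mRNA_Bax
    stoichiometry: {mRNA_Bax: -1}
  - rate: k_tl * mRNA_Bax
    stoichiometry: {Bax: 1}
  - rate: d_Bax * Bax
    stoichiometry: {Bax: -1}
  - rate: k_bind * Bad * Bcl_xL
    stoichiometry: {Bad: -1, Bcl_xL: -1, Bad_Bcl_xL: 1}
  - rate: k_disp * Bax * Bad_Bcl_xL
    stoichiometry: {Bax: -1, Bad_Bcl_xL: -1, Bax_Bcl_xL: 1, Bad: 1}
  - rate: k_act * Bax * Casp_pro
    stoichiometry: {Casp_pro: -1, Casp_act: 1}
  - rate: d_casp * Casp_act
    stoichiometry: {Casp_act: -1}
observables:
  apoptosis_species: Casp_act
  apoptosis_threshold: 1000.0
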