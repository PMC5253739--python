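# Extended C16:0 ceramide network: de novo synthesis, salvage pathway and
# the sphingomyelinase branch, with palmitoyl-CoA / DAG / PC as
# piecewise-linear time-dependent drivers (KLA-stimulated RAW264.7 layout,
# knots at 0, 0.5, 1, 2, 4, 8, 12, 24 h).
#
# Concentrations are pmol/ug DNA, time in hours.  Enzyme concentrations are
# folded into the rate constants; enzymes are labels grouping the reactions
# they mediate.  The default rate constants and initial values are an
# illustrative parameterization tuned for approximate flux balance at the
# baseline driver level; they are not fitted values from any published
# dataset.
species:
  - {name: dhSph, role: dynamic, initial_value: 0.3}
  - {name: dhCer, role: dynamic, initial_value: 3.0}
  - {name: dhSM, role: dynamic, initial_value: 5.0}
  - {name: dhGluCer, role: dynamic, initial_value: 0.5}
  - {name: Cer, role: dynamic, initial_value: 30.0}
  - {name: SM, role: dynamic, initial_value: 300.0}
  - {name: GluCer, role: dynamic, initial_value: 10.0}
  - {name: C1P, role: dynamic, initial_value: 0.005}
  - {name: Sph, role: dynamic, initial_value: 1.0}
  - {name: S1P, role: dynamic, initial_value: 0.05}
  - name: palmCoA
    role: driver
    driver_knots:
      [[0.0, 1.0], [0.5, 1.3], [1.0, 1.6], [2.0, 2.1], [4.0, 2.5],
       [8.0, 2.0], [12.0, 1.6], [24.0, 1.2]]
  - name: DAG
    role: driver
    driver_knots:
      [[0.0, 1.0], [0.5, 1.2], [1.0, 1.5], [2.0, 1.9], [4.0, 2.0],
       [8.0, 1.7], [12.0, 1.4], [24.0, 1.1]]
  - name: PC
    role: driver
    driver_knots:
      [[0.0, 1.0], [0.5, 1.05], [1.0, 1.1], [2.0, 1.2], [4.0, 1.3],
       [8.0, 1.25], [12.0, 1.15], [24.0, 1.05]]
reactions:
  # de novo entry: serine + palmitoyl-CoA condensation (serine implicit)
  - {id: R1, reactants: {}, products: {dhSph: 1}, enzyme: SPT,
     driver_modifiers: [palmCoA], rate_constant: 0.5}
  - {id: R2, reactants: {dhSph: 1}, products: {dhCer: 1}, enzyme: CERS,
     driver_modifiers: [palmCoA], rate_constant: 1.5}
  - {id: R3, reactants: {dhCer: 1}, products: {Cer: 1}, enzyme: DEGS,
     driver_modifiers: [], rate_constant: 0.135}
  # dihydro SM interconversion (PC-/DAG-mediated)
  - {id: R4, reactants: {dhCer: 1}, products: {dhSM: 1}, enzyme: SMS,
     driver_modifiers: [PC], rate_constant: 0.04}
  - {id: R5, reactants: {dhSM: 1}, products: {dhCer: 1}, enzyme: SMS,
     driver_modifiers: [DAG], rate_constant: 0.02}
  - {id: R6, reactants: {dhCer: 1}, products: {dhGluCer: 1}, enzyme: UGCG,
     driver_modifiers: [], rate_constant: 0.02}
  - {id: R7, reactants: {dhGluCer: 1}, products: {dhCer: 1}, enzyme: GBA,
     driver_modifiers: [], rate_constant: 0.1}
  # ceramide / sphingomyelin branch
  - {id: R8, reactants: {Cer: 1}, products: {SM: 1}, enzyme: SMS,
     driver_modifiers: [PC], rate_constant: 0.07}
  - {id: R9, reactants: {SM: 1}, products: {Cer: 1}, enzyme: SMS,
     driver_modifiers: [DAG], rate_constant: 0.002}
  - {id: R10, reactants: {SM: 1}, products: {Cer: 1}, enzyme: SMA,
     driver_modifiers: [], rate_constant: 0.004}
  - {id: R11, reactants: {Cer: 1}, products: {GluCer: 1}, enzyme: UGCG,
     driver_modifiers: [], rate_constant: 0.02}
  - {id: R12, reactants: {GluCer: 1}, products: {Cer: 1}, enzyme: GBA,
     driver_modifiers: [], rate_constant: 0.05}
  - {id: R13, reactants: {Cer: 1}, products: {C1P: 1}, enzyme: CERK,
     driver_modifiers: [], rate_constant: 2.0e-05}
  - {id: R14, reactants: {C1P: 1}, products: {Cer: 1}, enzyme: CAPP,
     driver_modifiers: [], rate_constant: 0.1}
  # salvage pathway
  - {id: R15, reactants: {Cer: 1}, products: {Sph: 1}, enzyme: ASAH,
     driver_modifiers: [], rate_constant: 0.02}
  - {id: R16, reactants: {Sph: 1}, products: {Cer: 1}, enzyme: CERS,
     driver_modifiers: [palmCoA], rate_constant: 0.4}
  - {id: R17, reactants: {Sph: 1}, products: {S1P: 1}, enzyme: SPHK,
     driver_modifiers: [], rate_constant: 0.2}
  - {id: R18, reactants: {S1P: 1}, products: {Sph: 1}, enzyme: SGPP1,
     driver_modifiers: [], rate_constant: 1.0}
  - {id: R19, reactants: {S1P: 1}, products: {}, enzyme: SGPL1,
     driver_modifiers: [], rate_constant: 2.8}
  # first-order clearance of each dynamic species
  - {id: R20, reactants: {dhSph: 1}, products: {}, enzyme: null,
     driver_modifiers: [], rate_constant: 0.1}
  - {id: R21, reactants: {dhCer: 1}, products: {}, enzyme: null,
     driver_modifiers: [], rate_constant: 0.005}
  - {id: R22, reactants: {dhSM: 1}, products: {}, enzyme: null,
     driver_modifiers: [], rate_constant: 0.004}
  - {id: R23, reactants: {dhGluCer: 1}, products: {}, enzyme: null,
     driver_modifiers: [], rate_constant: 0.02}
  - {id: R24, reactants: {Cer: 1}, products: {}, enzyme: null,
     driver_modifiers: [], rate_constant: 0.0058}
  - {id: R25, reactants: {SM: 1}, products: {}, enzyme: null,
     driver_modifiers: [], rate_constant: 0.001}
  - {id: R26, reactants: {GluCer: 1}, products: {}, enzyme: null,
     driver_modifiers: [], rate_constant: 0.01}
  - {id: R27, reactants: {C1P: 1}, products: {}, enzyme: null,
     driver_modifiers: [], rate_constant: 0.02}
  - {id: R28, reactants: {Sph: 1}, products: {}, enzyme: null,
     driver_modifiers: [], rate_constant: 0.05}
  - {id: R29, reactants: {S1P: 1}, products: {}, enzyme: null,
     driver_modifiers: [], rate_constant: 0.2}
enzymes:
  SPT: [R1]
  CERS: [R2, R16]
  DEGS: [R3]
  SMS: [R4, R5, R8, R9]
  SMA: [R10]
  UGCG: [R6, R11]
  GBA: [R7, R12]
  CERK: [R13]
  CAPP: [R14]
  ASAH: [R15]
  SPHK: [R17]
  SGPP1: [R18]
  SGPL1: [R19]
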