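# Propylthiouracil (PTU) compound file: model values for the whole-body PBPK
# simulation of a single oral dose. Physicochemistry from public databases
# (DrugBank), lipophilicity as the model-optimised value; clearances are the
# optimised whole-body plasma clearances of the adult model.
name: propylthiouracil
molecular_weight: 170.23     # g/mol
logP: 0.43                   # optimised lipophilicity
fu: 0.18                     # fraction unbound in plasma
pKa_acidic: 8.09
pKa_basic: -2.9
solubility_mg_per_L: 1200.0  # stored only; dosing uses the dissolved pathway
specific_intestinal_permeability_cm_per_min: 3.92e-6
specific_organ_permeability_cm_per_min: 3.18e-3
blood_plasma_ratio: 1.0      # neutral default for a hydrophilic, low-binding drug
clearance:
  CL_pls_total_L_per_h_per_kg: 0.147
  CL_pls_hepatic_L_per_h_per_kg: 0.09
  CL_pls_renal_L_per_h_per_kg: 0.05
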