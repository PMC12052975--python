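"""Electronic binding-energy relation E_el = E_PL - (E_P + E_L).

E_PL is the pocket+ligand interaction energy, E_P and E_L the isolated
pocket and ligand energies (kcal/mol). A negative E_el marks a ligand the
central pocket can bind in a transport-competent way; a positive one
rules the ligand out.
"""

import gatekeeper as gk

examples = [
    ("toy complex", gk.BindingEnergyComponents(E_PL=-100.0, E_P=-60.0, E_L=-20.0)),
    ("exact cancellation", gk.BindingEnergyComponents(E_PL=-10.0, E_P=-5.0, E_L=-5.0)),
]
for name, comp in examples:
    e = gk.electronic_binding_energy(comp)
    print(f"{name:20s} E_el = {e:+7.2f} kcal/mol -> {gk.classify_binding(e)}")

# sign convention on reported pocket-ligand energies
for ligand, e_el in (("IBA", -19.23), ("CLX", -8.11), ("IAA", +34.08)):
    print(f"{ligand:20s} E_el = {e_el:+7.2f} kcal/mol -> {gk.classify_binding(e_el)}")
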