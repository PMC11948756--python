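"""Sequence-level disorder descriptors and labeling stoichiometry.

Generates a mostly disordered synthetic sequence (90% disordered / 10%
ordered residues), places it on the charge-hydropathy plane relative to
the canonical folded/unfolded discriminant, and reports chain mass and
mean residue weight.  The degree-of-labeling calculation converts a
dye/protein absorbance pair to the average number of dye molecules per
protein.
"""

import idpchar as ip
from idpchar import synth

seq = synth.gen_sequence(
    ip.SequencePlan(((200, "disordered"), (30, "ordered"), (222, "disordered"))),
    seed=51)
pt = ip.charge_hydropathy(seq)
stats = ip.chain_stats(seq)
print(f"synthetic chain: {stats.length} residues, {stats.mass_da / 1e3:.1f} kDa, "
      f"MRW = {stats.mrw_da:.2f} Da (dimer {stats.dimer_mass_kda:.1f} kDa)")
print(f"charge-hydropathy: <H> = {pt.mean_hydropathy:.3f}, "
      f"<q> = {pt.mean_net_charge:.3f}, boundary at {pt.boundary_hydropathy:.3f} "
      f"-> {pt.classification}")

folded = synth.gen_sequence(ip.SequencePlan(((452, "ordered"),)), seed=51)
pt_f = ip.charge_hydropathy(folded)
print(f"all-ordered control: <H> = {pt_f.mean_hydropathy:.3f} "
      f"-> {pt_f.classification}")

dol = ip.degree_of_labeling(ip.LabelingMeasurement(
    a_max=0.36, a_280=0.25, eps_protein=24000.0, eps_max=72000.0, cf=0.11))
print(f"degree of labeling = {dol:.2f} dyes per protein molecule")
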