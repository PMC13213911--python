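"""Build the synthetic receptor/binder complex and inspect its geometry.

The receptor is a rigid polyanionic double-strand arc with a concave
groove; the binder is a folded elastic-network core carrying a short,
positively charged disordered tail.  The start frame displaces the
binder to 30 Å from the nearest receptor bead.
"""

import sumdkit as sk

system, start, bound = sk.make_toy_complex()

receptor = sk.build_selection(system, "component receptor")
binder = sk.build_selection(system, "component ligand")
tail = sk.build_selection(system, "chain P and resname TAL")

print(f"beads: {system.n_atoms} "
      f"(receptor {len(receptor)}, binder {len(binder)}, tail {len(tail)})")
print(f"receptor net charge: {system.charges[receptor.atom_ids].sum():+.0f} e")
print(f"binder net charge:   {system.charges[binder.atom_ids].sum():+.0f} e")
import numpy as np
gap = np.linalg.norm(
    start.coordinates[receptor.atom_ids][:, None]
    - start.coordinates[binder.atom_ids][None, :], axis=-1,
).min()
print(f"start clearance (nearest beads): {gap:.2f} Å")
print(f"start COM separation: "
      f"{sk.com_distance(start, system, receptor, binder):.2f} Å")
print(f"bound COM separation: "
      f"{sk.com_distance(bound, system, receptor, binder):.2f} Å")

protocol = sk.default_protocol(system, bound)
p1, p2 = protocol.phases
print(f"\nphase 1 ({p1.name}): supervise {p1.ligand_sel.label} vs "
      f"{p1.receptor_sel.label}; switch below {p1.switch_distance:.1f} Å")
print(f"phase 2 ({p2.name}): supervise {p2.ligand_sel.label} vs "
      f"{p2.receptor_sel.label}; terminate below {p2.target_distance:.1f} Å")
print("\nThe switch/target thresholds are the bound-reference distances "
      "plus fixed 4 Å / 2 Å margins.")
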