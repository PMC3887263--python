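"""Complexation energies of the two inclusion orientations.

ΔE = E_complex − (E_host + E_guest), from B3LYP/6-31+G* total energies.
Orientation 1 (phosphonate groups entering the wide rim) is more stable
than orientation 2 by 13.20 kcal/mol; both ΔE are negative, i.e. inclusion
is thermodynamically favorable in the gas phase.
"""

import hostguest as hg
from hostguest import reference as ref

results = []
for label, ledger in ref.ORIENTATION_LEDGERS.items():
    de = hg.delta_e(ledger)
    hbonds = ref.ORIENTATION_HBONDS[label]
    results.append((label, de, hbonds))
    print(f"{label}: dE = {de:.2f} kcal/mol, {len(hbonds)} intermolecular H bonds")

report = hg.compare_orientations(results)
best = report["ranking"][0]
diff = report["pairwise_differences"][0]
print(f"\nmost stable: {best['label']} ({best['delta_e_kcal']:.2f} kcal/mol)")
print(f"energy difference: {diff['difference_kcal']:.2f} kcal/mol")
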