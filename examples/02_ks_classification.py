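"""NG86 synonymous distances and homology-class calls.

Generates codon pairs at prescribed true synonymous distances, estimates
dS with the pathway-counting NG86 estimator, and shows how block-level Ks
separates orthologous from duplication-derived (paralogous) blocks.
"""

import numpy as np

from synfrac.ks import classify_block, ks_to_time, ng86_pairs
from synfrac.simulate import diverge_codon_pairs

for target in (0.1, 0.3, 0.6):
    a, b = diverge_codon_pairs(n_pairs=200, n_codons=300, target_ds=target, seed=5)
    ds = ng86_pairs(a, b)["dS"]
    print(f"true dS {target:.1f}: NG86 mean {np.nanmean(ds):.4f} "
          f"(sd {np.nanstd(ds):.4f}, n=200)")

print()
for ks in (0.18, 0.62, 0.35):
    print(f"block Ks {ks:.2f} -> {classify_block(ks)}")

rate = 6.5e-9  # substitutions/site/year; must be calibrated per clade
print(f"\nKs 0.6 at clock {rate:.1e}/site/yr -> {ks_to_time(0.6, rate):.1f} My")
print("\ndS is synonymous substitutions per synonymous site (Jukes-Cantor")
print("corrected); blocks under 0.3 are orthologous, the ~0.6 peak marks")
print("pairs born at the shared tetraploidization.")
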