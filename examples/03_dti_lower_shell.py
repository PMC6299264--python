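"""Fit the diffusion tensor on the lower shell and derive FA/MD/AD/RD.

Also demonstrates the coupling the multi-compartment model explains: at
fixed neurite density, increasing orientation dispersion lowers tensor FA.
"""

import numpy as np

from cortimat import NoddiParams, forward_signal, kappa_from_odi, make_scheme
from cortimat.dti import fit_tensor, tensor_scalars

scheme = make_scheme(32, 64, 1, 4, seed=1)
mu = np.array([0.0, 0.0, 1.0])

p = NoddiParams(vin=0.25, kappa=kappa_from_odi(0.5), fiso=0.1, mu=mu)
fit = fit_tensor(forward_signal(p, scheme), scheme, shell=750.0)
sc = tensor_scalars(fit)
print("tensor scalars of a dispersed-stick voxel (b=750 shell only):")
print(f"  FA {sc.fa:.3f}   MD {sc.md * 1e3:.3f} x10-3 mm^2/s   "
      f"AD {sc.ad * 1e3:.3f}   RD {sc.rd * 1e3:.3f}")

print("\nFA as orientation dispersion rises (NDI fixed at 0.25, no free water):")
for odi in (0.1, 0.3, 0.5, 0.7, 0.9):
    p = NoddiParams(vin=0.25, kappa=kappa_from_odi(odi), fiso=0.0, mu=mu)
    fa = tensor_scalars(fit_tensor(forward_signal(p, scheme), scheme, shell=750.0)).fa
    print(f"  ODI {odi:.1f} -> FA {fa:.3f}")
print("Monotonically falling FA with rising ODI: geometrical complexity, not")
print("neurite loss, can drive the FA decline seen in the maturing cortex.")
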