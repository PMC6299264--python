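"""Evaluate the three-compartment forward model on the study acquisition.

Builds the two-shell scheme (32 directions at b=750 s/mm^2 + 1 b0, 64 at
b=2500 + 4 b0s), evaluates the normalised signal of a moderately dispersed
cortical voxel, and shows how the orientation dispersion index maps to the
Watson concentration.
"""

import numpy as np

from cortimat import (
    NoddiParams, forward_signal, kappa_from_odi, make_scheme, odi_from_kappa,
)

scheme = make_scheme(32, 64, 1, 4, seed=1)
params = NoddiParams(
    vin=0.25,                      # intra-neurite (neurite density) fraction
    kappa=kappa_from_odi(0.6),     # ODI 0.6: substantially dispersed neurites
    fiso=0.15,                     # 15% free-water (CSF partial volume)
    mu=np.array([0.0, 0.0, 1.0]),  # mean neurite orientation
)
signal = forward_signal(params, scheme)

print(f"scheme: {scheme.n_volumes} volumes "
      f"({int(scheme.dw_mask(0).sum())} @ b=750, {int(scheme.dw_mask(1).sum())} @ b=2500)")
print(f"ODI 0.6 corresponds to Watson kappa = {kappa_from_odi(0.6):.4f} "
      f"(back: {odi_from_kappa(kappa_from_odi(0.6)):.4f})")
print(f"signal at b0 volumes      : {signal[scheme.is_b0].mean():.4f} (exactly 1 by construction)")
print(f"mean signal, b=750 shell  : {signal[scheme.dw_mask(0)].mean():.4f}")
print(f"mean signal, b=2500 shell : {signal[scheme.dw_mask(1)].mean():.4f}")
print("Stronger diffusion weighting attenuates the normalised signal more; the")
print("anisotropy across directions within a shell carries the orientation information.")
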