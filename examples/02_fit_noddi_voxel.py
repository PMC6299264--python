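"""Simulate noisy cortical voxels and invert the tissue model.

Voxel signals are generated with per-shell b0 baselines (emulating the
echo-time mismatch between the two shells) and Rician noise at SNR 20, then
fitted with the neonatal-adapted pipeline: per-shell b0 normalisation,
restricted grid-search initialisation, bounded nonlinear refinement, and a
dictionary fallback for non-converged voxels.  Single-voxel estimates
scatter; the median over replicates sits close to the truth, which is why
the pipeline reports region-wise medians rather than voxel values.
"""

import numpy as np

from cortimat import VoxelTruth, simulate_voxel, make_scheme
from cortimat.noddi_fit import fit_voxel

scheme = make_scheme(32, 64, 1, 4, seed=1)
truth = VoxelTruth(ndi=0.30, odi=0.60, fiso=0.15, mu=np.array([0.0, 0.0, 1.0]))

rng = np.random.default_rng(7)
fits = []
for _ in range(15):
    raw = simulate_voxel(truth, scheme, sigma=0.05, seed=rng)  # SNR 20 at b0
    r = fit_voxel(raw, scheme)
    fits.append((r.params.vin, r.params.odi, r.params.fiso, r.converged))

ndi, odi, fiso, conv = map(np.array, zip(*fits))
print(f"truth          : NDI {truth.ndi:.3f}  ODI {truth.odi:.3f}  f_iso {truth.fiso:.3f}")
print(f"median of fits : NDI {np.median(ndi):.3f}  ODI {np.median(odi):.3f}  "
      f"f_iso {np.median(fiso):.3f}   ({conv.sum()}/15 converged)")
print(f"scatter (SD)   : NDI {ndi.std():.3f}  ODI {odi.std():.3f}  f_iso {fiso.std():.3f}")
print("The upward shift of NDI and f_iso is the magnitude-noise floor of")
print("Rician data inflating the attenuated high-shell signal; aggregating")
print("medians over many voxels suppresses the scatter (not this floor bias),")
print("so trajectory analyses compare like-for-like biased estimates across age.")
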