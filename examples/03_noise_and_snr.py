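"""Rician noise, SNR measurement, and its effect on MD and FA.

Adds calibrated Rician magnitude noise to the phantom, measures the SNR the
way the QA pipeline defines it (temporal mean/SD of the direction-averaged
b = 100 s/mm^2 images), and shows the hallmark noise effects: MD stays
nearly unbiased at moderate SNR while FA acquires a positive bias that
grows as SNR falls.
"""

import numpy as np

from dtiphantom import (
    NoiseModel,
    add_rician_noise,
    default_layout,
    fit_tensor_lls,
    protocol_scheme,
    select_bvalues,
    simulate_signal,
    snr_map,
    tube_masks,
)
from dtiphantom.qa import snr_roi_mean

layout = default_layout(grid_shape=(48, 48, 1))
stack = simulate_signal(layout, protocol_scheme(0.0, 30))
mask = tube_masks(layout)[1]
truth = layout.tubes[0].true_md

print("target SNR   measured SNR   tube-1 MD bias   tube-1 mean FA")
for target in (40.0, 20.0, 10.0, 5.0):
    noisy = add_rician_noise(stack, NoiseModel("rician", target, seed=0), reference_mask=mask)
    measured = snr_roi_mean(snr_map(noisy), mask)
    field = fit_tensor_lls(select_bvalues(noisy, (100, 450)), roi_mask=mask)
    md = np.nanmean(field.md[mask & field.valid])
    fa = np.nanmean(field.fa[mask & field.valid])
    print(
        f"   {target:5.1f}       {measured:6.1f}        {100 * (md - truth) / truth:+6.2f}%"
        f"          {fa:.3f}"
    )
# The measured SNR tracks the target; MD bias stays well under 1% down to
# SNR ~10, while FA (which should be 0 in an isotropic medium) rises
# steadily -- the classic eigenvalue-repulsion noise artifact.
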