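"""The three Gaussian-noise losses and the SNR of simulated data.

Shows the invariances that distinguish the objectives: MSE depends on
absolute intensities, the CC loss ignores global scale and offset, and
the BioEM loss marginalizes them (staying finite at a zero prediction),
then prints the SNR of a sigma = 3 simulation calibrated to the 0.05
operating regime.
"""

import numpy as np

import cryofield as cf

rng = np.random.default_rng(0)
y = rng.normal(0, 1, (32, 32)) + 3 * np.outer(np.hanning(32), np.hanning(32))
yhat = y + rng.normal(0, 0.3, y.shape)

print("prediction vs observation:")
print(f"  MSE loss            {cf.loss_mse(y, yhat, sigma=3.0):10.3f}")
print(f"  CC loss             {cf.loss_cc(y, yhat, sigma=3.0):10.3f}")
print(f"  BioEM loss          {cf.loss_bioem(y, yhat):10.3f}")
print("after rescaling the prediction by 5x + offset 2:")
print(f"  MSE loss            {cf.loss_mse(y, 5 * yhat + 2, sigma=3.0):10.3f}")
print(f"  CC loss             {cf.loss_cc(y, 5 * yhat + 2, sigma=3.0):10.3f}  (unchanged)")
print(f"  BioEM loss          {cf.loss_bioem(y, 5 * yhat + 2):10.3f}  (close: scale marginalized)")
print(f"BioEM at yhat = 0     {cf.loss_bioem(y, np.zeros_like(y)):10.3f}  (worse than the fit, as it must be)")

sim = cf.SimConfig(n_pixels=32, pixel_size=1.5, n_particles=50, sigma=3.0, seed=1)
phantom = cf.calibrate_amplitude(cf.random_bead_model(24, sim.box_extent, seed=1),
                                 sim, target_snr=0.05)
data = cf.simulate_particles(phantom, sim)
per_image, mean, std = cf.snr(data.clean, sim.sigma)
print(f"\nsimulated stack SNR: {mean:.3f} +/- {std:.3f} over {len(per_image)} images")
print("(clean-signal pixel variance over noise variance, sigma = 3)")
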