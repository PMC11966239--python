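"""Jittering query points acts as a sinc low-pass filter in expectation.

Averaging many uniformly jittered evaluations of a signal equals
convolving the signal with a top-hat of the jitter width; in Fourier
space that is multiplication by a sinc.  The demonstration is in 1D
where the top-hat convolution has a closed form.
"""

import numpy as np
from scipy.stats import norm

J = 1.5  # jitter width, A
sigma = 0.8  # signal width, A
x = np.linspace(-6, 6, 301)
signal = lambda t: np.exp(-t**2 / (2 * sigma**2))

rng = np.random.default_rng(0)
draws = rng.uniform(-J / 2, J / 2, size=(5000, 1))
jittered_mean = signal(x[None, :] + draws).mean(axis=0)

# closed form: Gaussian convolved with a width-J top-hat
tophat_conv = (
    sigma * np.sqrt(2 * np.pi) / J
    * (norm.cdf((x + J / 2) / sigma) - norm.cdf((x - J / 2) / sigma))
)

err = np.max(np.abs(jittered_mean - tophat_conv))
print(f"max |MC mean - top-hat convolution| over 5000 draws: {err:.4f}")
print("the Monte-Carlo average converges to the top-hat-filtered signal;")
print("its spectrum is the signal spectrum multiplied by sinc(pi J f).")
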