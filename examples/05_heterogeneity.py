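"""Two-state heterogeneity by bending space.

Simulates a two-conformation bead model (state B swings a domain by a
hinge rotation), trains the field jointly with the amortized deformation
encoder, and clusters the per-image vector fields into states via their
cosine-similarity matrix.
"""

import numpy as np

import cryofield as cf
from cryofield.train import RunConfig, train

n, pixel_size = 24, 1.5
sim = cf.SimConfig(n_pixels=n, pixel_size=pixel_size, n_particles=200,
                   sigma=0.1, seed=0)
state_a, state_b = cf.two_state_models(16, sim.box_extent, seed=0)
data = cf.simulate_particles((state_a, state_b), sim)

config = RunConfig(
    hash_config=cf.HashGridConfig.for_box(n, log2_hashmap_size=14),
    n_z=12, batch_size=1, epochs=6, seed=0, val_fraction=0.0,
    heterogeneous=True, n_field=6,
)
result = train(data.particles(), n, pixel_size, config)

fields = [result.vf_model.predict_field(img, center=True)
          for img in data.images]
S = cf.cosine_similarity_matrix([f.ravel() for f in fields])
labels = cf.match_labels(data.states, cf.cluster_states(S, k=2, seed=0))

a, b = data.states == 0, data.states == 1
within = (S[np.ix_(a, a)].mean() + S[np.ix_(b, b)].mean()) / 2
between = S[np.ix_(a, b)].mean()
accuracy = float((labels == data.states).mean())
print(f"within-state mean cosine similarity : {within:.2f}")
print(f"between-state mean cosine similarity: {between:.2f}")
print(f"state recovery accuracy             : {100 * accuracy:.1f}%")
print("within > between indicates the deformation encoder separates the")
print("two conformations; clustering the similarity matrix labels them.")
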