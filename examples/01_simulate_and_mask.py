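"""Generate a synthetic layered tissue and apply the masking protocol.

The generator places cells on a hexagonal lattice split into horizontal
bands (cell-type domains), adds a smooth spatial expression field, draws
Poisson counts and applies zero-inflated dropout.  The masking protocol
then hides 10% of the observed nonzero entries for testing and 10% for
validation — the held-out values are the ground truth that imputation is
scored against.
"""

from pathimpute import apply_mask, make_masks
from pathimpute.simulate import SimConfig, expected_density, simulate

data, truth = simulate(SimConfig(n_cells=500, n_genes=200, seed=0))
density = data.values.nnz / (data.n_cells * data.n_genes)
print(f"dataset: {data.n_cells} cells x {data.n_genes} genes")
print(f"observed density: {density:.3f} "
      f"(closed-form expectation {expected_density(truth.rates, 0.45):.3f})")

split = make_masks(data, test_frac=0.10, val_frac=0.10, seed=0)
print(f"nonzero entries Z = {split.n_nonzero}: "
      f"{len(split.test_idx)} test, {len(split.val_idx)} validation, "
      f"{len(split.train_idx)} train")

observed = apply_mask(data, split)
print(f"entries zeroed by masking: {data.values.nnz - observed.values.nnz}")
# The three index sets partition the nonzero entries exactly; the test
# fraction matches the 10% protocol used for benchmarking imputation.
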