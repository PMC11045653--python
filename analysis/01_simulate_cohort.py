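#!/usr/bin/env python
"""Simulate the default registry-like cohort (1/100 of the published
cohort's scale, ~11,545 cases) and write the case listing, the latent
truth side channel, and the generator parameters under
results/synthetic/.

The truth side channel exists only so later steps can validate the
allocation engine by parameter recovery; the analysis pipeline itself
never reads it.
"""
from propmort.cli import cmd_simulate

SEED = 1234

if __name__ == "__main__":
    paths = cmd_simulate("results/synthetic", n_cases=11_545, seed=SEED)
    print(f"case listing -> {paths['cases']}")
    print(f"latent truth -> {paths['truth']} (validation only)")
    print(f"parameters   -> {paths['params']}")
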