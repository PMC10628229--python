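"""One cell of the cubed-separation clustering benchmark.

Three spherical Gaussians at -0.5*lam*1, 0, +0.5*lam*1 with every
coordinate cubed (so no component is Gaussian); EM and SIA are fitted to
each simulated dataset from a K-Means start and scored by ARI against the
generating labels.  Five datasets keep the example quick; the reported
experiments use 50.
"""

from siagmm import run_benchmark

table = run_benchmark(
    "separation", {"p": [3], "lam": [7.0]},
    methods=("em", "sia"), n_datasets=5, seed=0,
)
print(table[["method", "p", "lam", "ari_mean", "ari_sd", "n_datasets"]]
      .to_string(index=False, float_format=lambda v: f"{v:0.3f}"))
print("\nSIA's penalized refinement rescues the runs where maximum likelihood")
print("lands in an asymmetric, poorly clustering solution.")
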