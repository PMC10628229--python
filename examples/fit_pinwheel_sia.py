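"""Two-step penalized fit (SIA) on warped pinwheel data.

Generates a 3-arm pinwheel (a warped Gaussian mixture that a GMM cannot
represent exactly), fits an unpenalized GMM in Step I, then refines it with
the pairwise-KL penalty over a small weight grid and keeps the fit with the
smallest MPKL.  The penalized fit trades a little likelihood for much more
symmetric components and better label recovery.
"""

from siagmm import PinwheelConfig, ari, pinwheel, sia_fit

data = pinwheel(PinwheelConfig(n_per_class=100, r=0.3, t=0.05, s=0.4, seed=1))
result = sia_fit(data, K=3, seed=1)

s1, sel = result.step1, result.selected
print(f"Step I  (EM):        loglik={s1.loglik_total:8.1f}  KLF={s1.klf:6.1f}  "
      f"KLB={s1.klb:6.1f}  MPKL={s1.mpkl:6.1f}  ARI={ari(data.labels, s1.labels):.3f}")
print(f"Selected (w={sel.weights_used.w1}): loglik={sel.loglik_total:8.1f}  "
      f"KLF={sel.klf:6.1f}  KLB={sel.klb:6.1f}  MPKL={sel.mpkl:6.1f}  "
      f"ARI={ari(data.labels, sel.labels):.3f}")
print("\nLower KLF/KLB and MPKL mean more symmetric, less overlapping components;")
print("the likelihood drops slightly — that is the price of avoiding the")
print("asymmetric high-likelihood solution.")
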