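"""Compute P(r), I(q), Rg, and Dmax for a synthetic protein chain.

Builds a compact 64-residue CA trace, histograms its electron-weighted pair
distances into P(r), evaluates the Debye intensity, and shows that going
through P(r) reproduces the Debye curve to within the binning error.
"""

import numpy as np

import saxsfold as sf

chain = sf.make_chain(sf.FixtureSpec(kind="globule", n_residues=64, seed=0))

pr = sf.compute_pr(chain, dr=0.5, normalize=True)
q = np.linspace(0.0, 0.5, 51)
debye = sf.debye_intensity(chain, q)
via_pr = sf.pr_to_intensity(sf.compute_pr(chain, dr=0.1), q)

print(f"n_atoms          : {chain.n_atoms}")
print(f"Dmax             : {pr.dmax:.2f} A        (largest pair distance)")
print(f"Rg (coordinates) : {sf.rg_from_coords(chain):.3f} A")
print(f"Rg (from P(r))   : {sf.rg_from_pr(pr):.3f} A   (second moment of P(r))")
print(f"I(0)             : {debye.i[0]:.0f}        (= (sum Z_i)^2 = {chain.z.sum()**2})")
rel = np.max(np.abs(via_pr.i - debye.i) / debye.i)
print(f"P(r)-route vs Debye, max relative deviation at dr=0.1: {rel:.2e}")
print("The two routes agree because P(r) and I(q) carry the same pair-distance")
print("information; the residual is pure histogram binning error.")
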