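"""Inject a P(r) curve into MSA and pair latents via cross-attention.

Each P(r) bin becomes one token; every (cluster, residue) position of the
MSA representation and every (i, j) position of the pair representation
queries the tokens.  With the default zero-initialized output projections
the modules are exact no-ops, so they can be bolted onto a pretrained trunk
without perturbing it before training.
"""

import numpy as np

import saxsfold as sf

chain = sf.make_chain(sf.FixtureSpec(kind="globule", n_residues=32, seed=0))
pr = sf.compute_pr(chain, dr=0.5, normalize=True)

tokens = sf.embed_pr(pr, sf.PrEmbedder(c_s=256, seed=0))
print(f"P(r) bins -> tokens: {tokens.n_bins} tokens of width {tokens.width}")

rng = np.random.default_rng(1)
msa = rng.standard_normal((8, 32, 48))      # (clusters, residues, c_m)
pair = rng.standard_normal((32, 32, 32))    # (residues, residues, c_z)

msa_params = sf.default_msa_params(d_q=48, seed=2)    # 8 heads x 32
pair_params = sf.default_pair_params(d_q=32, seed=3)  # 4 heads x 32

update = sf.saxs_msa_attention(msa, tokens, msa_params)
print(f"zero-init MSA update max |value| = {np.abs(update).max():.1f}  (exact no-op)")

msa_params.wo = rng.standard_normal(msa_params.wo.shape) * 0.01
update, attn = sf.saxs_msa_attention(msa, tokens, msa_params, return_weights=True)
print(f"after giving the output projection weight: update std = {update.std():.4f}")
print(f"attention rows sum to 1: max deviation = {np.abs(attn.sum(-1) - 1).max():.2e}")

tokens_p = sf.embed_pr(pr, sf.PrEmbedder(c_s=128, seed=0))
pair_update = sf.saxs_pair_attention(pair, tokens_p, pair_params)
print(f"pair update shape {pair_update.shape} matches the pair representation")
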