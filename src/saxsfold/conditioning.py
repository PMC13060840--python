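"""SAXS-conditioned cross-attention.

Injects an experimental pair-distance distribution into the two latent
representations of an Evoformer-style trunk.  The P(r) bins are embedded as
a sequence of tokens (one per bin, value plus a sinusoidal encoding of the
bin's distance), and two multi-head cross-attention modules let every MSA
(cluster, residue) position and every pair (i, j) position query those
tokens.  The attended output passes through an output projection that is
zero-initialized by default, so an untrained module is an exact no-op on the
trunk — the standard safe-adapter convention.

Defaults follow the consuming trunk: 8 heads of width 32 on the MSA side,
4 heads of width 32 on the pair side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolationError, InvalidParameterError
from .profile import PrCurve

N_HEADS_MSA = 8
N_HEADS_PAIR = 4
HEAD_DIM = 32


def sinusoidal_encoding(r: np.ndarray, dim: int, max_wavelength: float = 1000.0) -> np.ndarray:
    """Transformer-style positional encoding of bin distances, shape (len(r), dim)."""
    if dim % 2:
        raise InvalidParameterError("encoding dimension must be even")
    r = np.asarray(r, dtype=np.float64)
    half = dim // 2
    freqs = max_wavelength ** (-np.arange(half) / half)
    phase = r[:, None] * freqs[None, :]
    return np.concatenate([np.sin(phase), np.cos(phase)], axis=1)


@dataclass
class SaxsTokens:
    """Per-bin token embedding of a P(r) curve, shape (n_bins, c_s)."""

    values: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidParameterError("tokens must be a (n_bins, c_s) array")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class PrEmbedder:
    """Linear map from [p_k ; sinusoidal(r_k)] to token vectors.

    Deterministic given the seed; with ``zero_init`` the map (and therefore
    every token) is identically zero.
    """

    c_s: int
    n_freq_dims: int = 16
    seed: int = 0
    zero_init: bool = False
    weight: np.ndarray = field(init=False)
    bias: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        d_in = 1 + self.n_freq_dims
        if self.zero_init:
            self.weight = np.zeros((d_in, self.c_s))
        else:
            rng = np.random.default_rng(self.seed)
            self.weight = rng.standard_normal((d_in, self.c_s)) / np.sqrt(d_in)
        self.bias = np.zeros(self.c_s)

    def __call__(self, pr: PrCurve) -> SaxsTokens:
        return embed_pr(pr, self)


def embed_pr(pr: PrCurve, embedder: PrEmbedder) -> SaxsTokens:
    """One token per P(r) bin: a learned linear map of the bin value and its
    encoded distance."""
    if not pr.normalized:
        raise ContractViolationError("embed a normalized P(r) curve")
    enc = sinusoidal_encoding(pr.r, embedder.n_freq_dims)
    feats = np.concatenate([pr.p[:, None], enc], axis=1)
    return SaxsTokens(values=feats @ embedder.weight + embedder.bias, r=pr.r.copy())


@dataclass
class AttentionParams:
    """Projection weights of one cross-attention module.

    ``wq`` maps the query-side representation (width d_q) to n_heads*c;
    ``wk``/``wv`` map tokens (width c_s) likewise; ``wo`` maps the
    concatenated heads back to d_q.  ``wo`` is zero-initialized by default so
    the module starts as the identity (zero additive update).
    """

    n_heads: int
    c: int
    d_q: int
    c_s: int
    seed: int = 0
    zero_init_output: bool = True
    wq: np.ndarray = field(init=False)
    wk: np.ndarray = field(init=False)
    wv: np.ndarray = field(init=False)
    wo: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_heads < 1 or self.c < 1:
            raise InvalidParameterError("n_heads and c must be positive")
        rng = np.random.default_rng(self.seed)
        hc = self.n_heads * self.c
        self.wq = rng.standard_normal((self.d_q, hc)) / np.sqrt(self.d_q)
        self.wk = rng.standard_normal((self.c_s, hc)) / np.sqrt(self.c_s)
        self.wv = rng.standard_normal((self.c_s, hc)) / np.sqrt(self.c_s)
        if self.zero_init_output:
            self.wo = np.zeros((hc, self.d_q))
        else:
            self.wo = rng.standard_normal((hc, self.d_q)) / np.sqrt(hc)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {"wq": self.wq, "wk": self.wk, "wv": self.wv, "wo": self.wo}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name in ("wq", "wk", "wv", "wo"):
            arr = np.asarray(state[name])
            if arr.shape != getattr(self, name).shape:
                raise InvalidParameterError(f"shape mismatch loading {name}")
            setattr(self, name, arr.copy())


def default_msa_params(d_q: int, c_s: int | None = None, seed: int = 0) -> AttentionParams:
    c_s = c_s if c_s is not None else N_HEADS_MSA * HEAD_DIM
    return AttentionParams(n_heads=N_HEADS_MSA, c=HEAD_DIM, d_q=d_q, c_s=c_s, seed=seed)


def default_pair_params(d_q: int, c_s: int | None = None, seed: int = 0) -> AttentionParams:
    c_s = c_s if c_s is not None else N_HEADS_PAIR * HEAD_DIM
    return AttentionParams(n_heads=N_HEADS_PAIR, c=HEAD_DIM, d_q=d_q, c_s=c_s, seed=seed)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def _cross_attention(
    queries: np.ndarray,  # (n_q, d_q)
    tokens: SaxsTokens,
    params: AttentionParams,
    return_weights: bool,
):
    """Multi-head cross-attention of flat queries over SAXS tokens."""
    if queries.shape[-1] != params.d_q:
        raise ContractViolationError(
            f"query width {queries.shape[-1]} != configured d_q {params.d_q}"
        )
    if tokens.width != params.c_s:
        raise ContractViolationError(
            f"token width {tokens.width} != configured c_s {params.c_s}"
        )
    h, c = params.n_heads, params.c
    n_q = queries.shape[0]
    n_k = tokens.n_bins
    q = (queries @ params.wq).reshape(n_q, h, c)
    k = (tokens.values @ params.wk).reshape(n_k, h, c)
    v = (tokens.values @ params.wv).reshape(n_k, h, c)
    # (h, n_q, n_k) attention logits
    logits = np.einsum("qhc,khc->hqk", q, k) / np.sqrt(c)
    attn = _softmax(logits, axis=-1)
    ctx = np.einsum("hqk,khc->qhc", attn, v).reshape(n_q, h * c)
    update = ctx @ params.wo
    return (update, attn) if return_weights else (update, None)


def saxs_msa_attention(
    msa: np.ndarray,
    tokens: SaxsTokens,
    params: AttentionParams,
    return_weights: bool = False,
):
    """Additive update to the MSA representation from the SAXS tokens.

    Each (cluster, residue) position of the (N_clust, N_res, c_m) MSA tensor
    forms a query; attention runs over the P(r) bins.  The caller adds the
    returned update to the representation.
    """
    msa = np.asarray(msa, dtype=np.float64)
    if msa.ndim != 3:
        raise ContractViolationError("MSA representation must be (N_clust, N_res, c_m)")
    flat = msa.reshape(-1, msa.shape[-1])
    update, attn = _cross_attention(flat, tokens, params, return_weights)
    update = update.reshape(msa.shape)
    return (update, attn) if return_weights else update


def saxs_pair_attention(
    pair: np.ndarray,
    tokens: SaxsTokens,
    params: AttentionParams,
    return_weights: bool = False,
):
    """Additive update to the pair representation from the SAXS tokens.

    One query per residue pair (i, j) of the (N_res, N_res, c_z) tensor; no
    weight sharing between (i, j) and (j, i).
    """
    pair = np.asarray(pair, dtype=np.float64)
    if pair.ndim != 3 or pair.shape[0] != pair.shape[1]:
        raise ContractViolationError("pair representation must be (N_res, N_res, c_z)")
    flat = pair.reshape(-1, pair.shape[-1])
    update, attn = _cross_attention(flat, tokens, params, return_weights)
    update = update.reshape(pair.shape)
    return (update, attn) if return_weights else update


def save_checkpoint(path, msa_params: AttentionParams, pair_params: AttentionParams,
                    embedder: PrEmbedder) -> None:
    """Serialize both modules and the embedder to one npz checkpoint."""
    arrays = {f"msa_{k}": v for k, v in msa_params.state_dict().items()}
    arrays.update({f"pair_{k}": v for k, v in pair_params.state_dict().items()})
    arrays["embed_weight"] = embedder.weight
    arrays["embed_bias"] = embedder.bias
    arrays["config"] = np.array([
        msa_params.n_heads, pair_params.n_heads, msa_params.c,
        msa_params.d_q, pair_params.d_q, msa_params.c_s,
    ])
    np.savez(path, **arrays)


def load_checkpoint(path, msa_params: AttentionParams, pair_params: AttentionParams,
                    embedder: PrEmbedder) -> None:
    with np.load(path) as data:
        msa_params.load_state_dict({k: data[f"msa_{k}"] for k in ("wq", "wk", "wv", "wo")})
        pair_params.load_state_dict({k: data[f"pair_{k}"] for k in ("wq", "wk", "wv", "wo")})
        embedder.weight = data["embed_weight"].copy()
        embedder.bias = data["embed_bias"].copy()
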