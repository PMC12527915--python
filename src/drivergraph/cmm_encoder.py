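"""Cell manifold model: a gene-graph-aware transformer encoder.

One cell is presented as a token sequence [CLS] + its non-zero genes.  Each
gene token embeds its identity (learnable table, width H) concatenated with
a linear embedding of its shifted-log expression (width H), giving token
states of width E = 2H.  Each of the ``n_layers`` GeneGraph attention
layers adds three graph-aware ingredients to plain multi-head attention:

* centrality encoding — learnable in-/out-degree embeddings added to token
  states before attention;
* spatial encoding — a learnable per-head scalar bias b(S) added to the
  attention logits, indexed by the bucketed shortest-path distance between
  the two genes on the cell-specific graph;
* a dedicated CLS token whose graph features use reserved buckets and
  whose final state, linearly projected to ``coordinate_dim``, is the cell
  coordinate.

Layer ordering follows the pre-attention convention: each layer applies
layer norm + MLP (residual), then centrality, then biased multi-head
attention (residual).  Setting ``pre_norm_mlp=False`` moves the MLP
residual branch after the attention branch instead (ablation flag).

All forward/backward passes are hand-written numpy; see ``_nn``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .data_core import CountMatrix, ValidationError, normalize_rows, sample_nonzero_genes
from .gene_graph import DirectedGeneGraph
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "ModelConfig",
    "TokenBatch",
    "CmmParams",
    "CellCoordinate",
    "init_cmm_params",
    "build_token_batch",
    "encode_token_batch",
    "encode_cell",
    "encode_cells",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the encoder.

    ``D`` (per-head width) satisfies D * n_heads = 2H.  Degree values are
    clipped at ``max_degree_bucket`` before embedding lookup; distances are
    clipped at ``d_max`` with one extra UNREACHABLE bucket, and CLS rows/
    columns use dedicated reserved buckets for both features.
    """

    H: int = 256
    n_layers: int = 6
    n_heads: int = 8
    coordinate_dim: int = 2048
    d_max: int = 8
    max_train_genes: int = 2048
    L: float = 1e4
    max_degree_bucket: int = 64
    mlp_hidden: int | None = None
    decoder_hidden: int = 256
    dgp_hidden: int | None = None
    pre_norm_mlp: bool = True
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if (2 * self.H) % self.n_heads:
            raise ValidationError("n_heads must divide 2*H")
        for name in ("H", "n_layers", "n_heads", "coordinate_dim", "d_max"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def E(self) -> int:
        return 2 * self.H

    @property
    def D(self) -> int:
        return self.E // self.n_heads

    @property
    def mlp_dim(self) -> int:
        return self.mlp_hidden if self.mlp_hidden is not None else 2 * self.E

    @property
    def n_dist_buckets(self) -> int:
        # 0..d_max, UNREACHABLE, CLS
        return self.d_max + 3

    @property
    def cls_dist_bucket(self) -> int:
        return self.d_max + 2

    @property
    def unreachable_bucket(self) -> int:
        return self.d_max + 1

    @property
    def n_deg_buckets(self) -> int:
        # 0..max_degree_bucket, CLS
        return self.max_degree_bucket + 2

    @property
    def cls_deg_bucket(self) -> int:
        return self.max_degree_bucket + 1

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class TokenBatch:
    """Padded token arrays for a batch of cells.

    ``tokens[b, 0]`` is always the CLS index (= vocabulary size); padded
    positions have ``mask`` False and are excluded from attention.
    """

    tokens: np.ndarray  # [B, T] int64, CLS = vocab_size
    expr: np.ndarray  # [B, T] normalized expression (0 at CLS / padding)
    mask: np.ndarray  # [B, T] bool
    deg_in: np.ndarray  # [B, T] bucket indices
    deg_out: np.ndarray  # [B, T]
    dist: np.ndarray  # [B, T, T] bucket indices
    cell_ids: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.tokens.shape[0]


@dataclass
class CellCoordinate:
    """A cell's position on the learned manifold."""

    values: np.ndarray
    cell_id: str = ""
    n_genes_used: int = 0


class CmmParams:
    """Learnable tensors of the encoder, as a flat ``{name: array}`` dict."""

    def __init__(self, arrays: dict[str, np.ndarray], vocab_size: int):
        self.arrays = arrays
        self.vocab_size = vocab_size

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def zeros_like(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.arrays.items()}

    def copy(self) -> "CmmParams":
        return CmmParams({k: v.copy() for k, v in self.arrays.items()}, self.vocab_size)


def init_cmm_params(
    vocab_size: int, config: ModelConfig, seed: int | np.random.Generator
) -> CmmParams:
    rng = np.random.default_rng(seed)
    dt = config.np_dtype
    E, H, F = config.E, config.H, config.mlp_dim
    # residual output projections are shrunk by 1/sqrt(2*n_layers) so the
    # residual stream stays input-dominated at init (the cell signal is
    # otherwise drowned by input-independent branch outputs)
    res_scale = 1.0 / np.sqrt(2.0 * config.n_layers)
    a: dict[str, np.ndarray] = {}
    a["name_emb"] = (rng.standard_normal((vocab_size + 1, H)) * 0.3).astype(dt)
    a["expr_w"] = (rng.standard_normal(H) * 0.5).astype(dt)
    a["expr_b"] = np.zeros(H, dtype=dt)
    a["cls_expr"] = (rng.standard_normal(H) * 0.3).astype(dt)
    for l in range(config.n_layers):
        p = f"layer{l}."
        a[p + "ln1_g"] = np.ones(E, dtype=dt)
        a[p + "ln1_b"] = np.zeros(E, dtype=dt)
        a[p + "mlp_W1"] = _nn.init_linear(rng, E, F, dt)
        a[p + "mlp_b1"] = np.zeros(F, dtype=dt)
        a[p + "mlp_W2"] = _nn.init_linear(rng, F, E, dt) * res_scale
        a[p + "mlp_b2"] = np.zeros(E, dtype=dt)
        a[p + "ln2_g"] = np.ones(E, dtype=dt)
        a[p + "ln2_b"] = np.zeros(E, dtype=dt)
        for w in ("Wq", "Wk", "Wv"):
            a[p + w] = _nn.init_linear(rng, E, E, dt)
        a[p + "Wo"] = _nn.init_linear(rng, E, E, dt) * res_scale
        for b in ("bq", "bk", "bv", "bo"):
            a[p + b] = np.zeros(E, dtype=dt)
        a[p + "z_in"] = (rng.standard_normal((config.n_deg_buckets, E)) * 0.02).astype(dt)
        a[p + "z_out"] = (rng.standard_normal((config.n_deg_buckets, E)) * 0.02).astype(dt)
        a[p + "btab"] = np.zeros((config.n_heads, config.n_dist_buckets), dtype=dt)
    a["out_W"] = _nn.init_linear(rng, E, config.coordinate_dim, dt)
    a["out_b"] = np.zeros(config.coordinate_dim, dtype=dt)
    return CmmParams(a, vocab_size)


class GraphFeatureCache:
    """Memoizes per-cell graph features keyed by the non-zero gene set."""

    def __init__(self, max_entries: int = 20000):
        self.max_entries = max_entries
        self._store: dict[bytes, tuple] = {}

    def get(self, key: bytes):
        return self._store.get(key)

    def put(self, key: bytes, value) -> None:
        if len(self._store) >= self.max_entries:
            self._store.clear()
        self._store[key] = value


def _cell_graph_features(
    graph: DirectedGeneGraph,
    nonzero: np.ndarray,
    sampled: np.ndarray,
    config: ModelConfig,
    cache: GraphFeatureCache | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Degrees and distance buckets of the sampled genes on the
    cell-specific graph (induced on all non-zero genes)."""
    key = None
    if cache is not None and sampled.size == nonzero.size:
        key = nonzero.tobytes()
        hit = cache.get(key)
        if hit is not None:
            return hit
    sub = graph.adjacency[nonzero][:, nonzero]
    pos = np.searchsorted(nonzero, sampled)
    deg_out = np.asarray(sub.sum(axis=1)).ravel()[pos]
    deg_in = np.asarray(sub.sum(axis=0)).ravel()[pos]
    if sub.nnz:
        d = dijkstra(sub, directed=True, unweighted=True, indices=pos)[:, pos]
        buckets = np.where(
            np.isinf(d), config.unreachable_bucket, np.minimum(d, config.d_max)
        ).astype(np.int64)
    else:
        buckets = np.full((pos.size, pos.size), config.unreachable_bucket, dtype=np.int64)
    np.fill_diagonal(buckets, 0)
    out = (
        np.minimum(deg_in, config.max_degree_bucket).astype(np.int64),
        np.minimum(deg_out, config.max_degree_bucket).astype(np.int64),
        buckets,
    )
    if key is not None:
        cache.put(key, out)
    return out


def build_token_batch(
    rows: np.ndarray,
    graph: DirectedGeneGraph,
    config: ModelConfig,
    training: bool = False,
    seed: int | np.random.Generator | None = None,
    cell_ids: list[str] | None = None,
    cache: GraphFeatureCache | None = None,
) -> TokenBatch:
    """Tokenize a batch of raw count rows (cells x genes, graph-aligned).

    Expression values are shifted-log normalized per cell (using the totals
    of the rows as given, i.e. of the possibly downsampled profile).
    """
    rows = np.atleast_2d(rows)
    if rows.shape[1] != graph.n_nodes:
        raise ValidationError("rows are not aligned with the graph vocabulary")
    rng = np.random.default_rng(seed)
    B = rows.shape[0]
    vocab = graph.n_nodes
    norm = normalize_rows(rows, L=config.L)

    per_cell = []
    for b in range(B):
        nonzero = np.flatnonzero(rows[b])
        sampled = sample_nonzero_genes(
            rows[b], config.max_train_genes, rng, training=training
        )
        feats = _cell_graph_features(graph, nonzero, sampled, config, cache)
        per_cell.append((sampled, feats))

    T = 1 + max(s.size for s, _ in per_cell)
    dt = config.np_dtype
    tokens = np.zeros((B, T), dtype=np.int64)
    expr = np.zeros((B, T), dtype=dt)
    mask = np.zeros((B, T), dtype=bool)
    deg_in = np.zeros((B, T), dtype=np.int64)
    deg_out = np.zeros((B, T), dtype=np.int64)
    dist = np.full((B, T, T), config.unreachable_bucket, dtype=np.int64)
    for b, (sampled, (din, dout, buckets)) in enumerate(per_cell):
        n = sampled.size
        tokens[b, 0] = vocab
        tokens[b, 1 : n + 1] = sampled
        expr[b, 1 : n + 1] = norm[b, sampled]
        mask[b, : n + 1] = True
        deg_in[b, 0] = config.cls_deg_bucket
        deg_out[b, 0] = config.cls_deg_bucket
        deg_in[b, 1 : n + 1] = din
        deg_out[b, 1 : n + 1] = dout
        dist[b, 0, :] = config.cls_dist_bucket
        dist[b, :, 0] = config.cls_dist_bucket
        dist[b, 1 : n + 1, 1 : n + 1] = buckets
    return TokenBatch(
        tokens, expr, mask, deg_in, deg_out, dist,
        cell_ids=list(cell_ids) if cell_ids else [""] * B,
    )


# ---------------------------------------------------------------------------
# forward / backward


def _embed(params: CmmParams, config: ModelConfig, batch: TokenBatch):
    H = config.H
    a = params.arrays
    name = a["name_emb"][batch.tokens]  # [B,T,H]
    is_cls = batch.tokens == params.vocab_size
    exprp = batch.expr[..., None] * a["expr_w"] + a["expr_b"]
    exprp = np.where(is_cls[..., None], a["cls_expr"], exprp)
    x = np.concatenate([name, exprp], axis=-1)
    x = x * batch.mask[..., None]
    return x.astype(config.np_dtype, copy=False)


def encoder_forward(
    params: CmmParams, config: ModelConfig, batch: TokenBatch, need_cache: bool = False
):
    """Returns (coordinates [B, coordinate_dim], cache or None)."""
    a = params.arrays
    nh, Dh, E = config.n_heads, config.D, config.E
    mask = batch.mask
    maskf = mask[..., None].astype(config.np_dtype)
    x = _embed(params, config, batch)
    B, T, _ = x.shape
    layers_cache = []
    neg = np.array(-1e30, dtype=config.np_dtype)
    for l in range(config.n_layers):
        p = f"layer{l}."
        x_in = x
        ln1_out, ln1c = _nn.layer_norm(x, a[p + "ln1_g"], a[p + "ln1_b"])
        h1 = ln1_out @ a[p + "mlp_W1"] + a[p + "mlp_b1"]
        g = _nn.gelu(h1)
        m = g @ a[p + "mlp_W2"] + a[p + "mlp_b2"]
        if config.pre_norm_mlp:
            u = x_in + m
        else:
            u = x_in  # conventional order: MLP applied after attention
        u = u + a[p + "z_in"][batch.deg_in] + a[p + "z_out"][batch.deg_out]
        u = u * maskf
        v, ln2c = _nn.layer_norm(u, a[p + "ln2_g"], a[p + "ln2_b"])
        q = (v @ a[p + "Wq"] + a[p + "bq"]).reshape(B, T, nh, Dh).transpose(0, 2, 1, 3)
        k = (v @ a[p + "Wk"] + a[p + "bk"]).reshape(B, T, nh, Dh).transpose(0, 2, 1, 3)
        val = (v @ a[p + "Wv"] + a[p + "bv"]).reshape(B, T, nh, Dh).transpose(0, 2, 1, 3)
        bias = a[p + "btab"][:, batch.dist].transpose(1, 0, 2, 3)  # [B,nh,T,T]
        logits = q @ k.transpose(0, 1, 3, 2) / np.sqrt(Dh) + bias
        logits = np.where(mask[:, None, None, :], logits, neg)
        attn = _nn.softmax(logits, axis=-1)
        o = (attn @ val).transpose(0, 2, 1, 3).reshape(B, T, E)
        y = o @ a[p + "Wo"] + a[p + "bo"]
        x_next = u + y
        if not config.pre_norm_mlp:
            x_next = x_next + m
        x = x_next * maskf
        if need_cache:
            layers_cache.append((x_in, ln1c, h1, g, u, ln2c, v, q, k, val, attn, o))
    crd = x[:, 0] @ a["out_W"] + a["out_b"]
    cache = (x, layers_cache) if need_cache else None
    return crd, cache


def encoder_backward(
    params: CmmParams,
    config: ModelConfig,
    batch: TokenBatch,
    cache,
    d_crd: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss wrt all encoder parameters, given the
    gradient wrt the output coordinates."""
    a = params.arrays
    x_final, layers_cache = cache
    nh, Dh, E, H = config.n_heads, config.D, config.E, config.H
    mask = batch.mask
    maskf = mask[..., None].astype(config.np_dtype)
    B, T = mask.shape
    grads: dict[str, np.ndarray] = {}

    grads["out_W"] = x_final[:, 0].T @ d_crd
    grads["out_b"] = d_crd.sum(axis=0)
    dx = np.zeros_like(x_final)
    dx[:, 0] = d_crd @ a["out_W"].T

    for l in reversed(range(config.n_layers)):
        p = f"layer{l}."
        x_in, ln1c, h1, g, u, ln2c, v, q, k, val, attn, o = layers_cache[l]
        dx = dx * maskf
        dy = dx
        # y = o @ Wo + bo
        grads[p + "Wo"] = o.reshape(-1, E).T @ dy.reshape(-1, E)
        grads[p + "bo"] = dy.sum(axis=(0, 1))
        do = (dy @ a[p + "Wo"].T).reshape(B, T, nh, Dh).transpose(0, 2, 1, 3)
        dattn = do @ val.transpose(0, 1, 3, 2)
        dval = attn.transpose(0, 1, 3, 2) @ do
        dlogits = _nn.softmax_grad(dattn, attn)
        dlogits = dlogits * mask[:, None, :, None]  # no flow from padded queries
        gb = np.zeros_like(a[p + "btab"])
        dist_flat = batch.dist.ravel()
        for h in range(nh):
            gb[h] = np.bincount(
                dist_flat,
                weights=dlogits[:, h].ravel(),
                minlength=config.n_dist_buckets,
            ).astype(gb.dtype)
        grads[p + "btab"] = gb
        scale = 1.0 / np.sqrt(Dh)
        dq = dlogits @ k * scale
        dk = dlogits.transpose(0, 1, 3, 2) @ q * scale
        dqf = dq.transpose(0, 2, 1, 3).reshape(B, T, E)
        dkf = dk.transpose(0, 2, 1, 3).reshape(B, T, E)
        dvf = dval.transpose(0, 2, 1, 3).reshape(B, T, E)
        vflat = v.reshape(-1, E)
        grads[p + "Wq"] = vflat.T @ dqf.reshape(-1, E)
        grads[p + "Wk"] = vflat.T @ dkf.reshape(-1, E)
        grads[p + "Wv"] = vflat.T @ dvf.reshape(-1, E)
        grads[p + "bq"] = dqf.sum(axis=(0, 1))
        grads[p + "bk"] = dkf.sum(axis=(0, 1))
        grads[p + "bv"] = dvf.sum(axis=(0, 1))
        dv = dqf @ a[p + "Wq"].T + dkf @ a[p + "Wk"].T + dvf @ a[p + "Wv"].T
        du_ln, grads[p + "ln2_g"], grads[p + "ln2_b"] = _nn.layer_norm_grad(dv, ln2c)
        du = dx + du_ln  # residual x_next = u + y
        du = du * maskf
        # centrality (pad rows of du are zero, so flat scatter is safe)
        du_flat = du.reshape(-1, E)
        grads[p + "z_in"] = _nn.scatter_rows(
            batch.deg_in.ravel(), du_flat, config.n_deg_buckets
        )
        grads[p + "z_out"] = _nn.scatter_rows(
            batch.deg_out.ravel(), du_flat, config.n_deg_buckets
        )
        # MLP branch
        if config.pre_norm_mlp:
            dm = du
            dx_in = du.copy()
        else:
            dm = dx  # m added after attention
            dx_in = du.copy()
        dg = dm @ a[p + "mlp_W2"].T
        grads[p + "mlp_W2"] = g.reshape(-1, g.shape[-1]).T @ dm.reshape(-1, E)
        grads[p + "mlp_b2"] = dm.sum(axis=(0, 1))
        dh1 = dg * _nn.gelu_grad(h1)
        ln1_out = ln1c[0] * ln1c[2] + a[p + "ln1_b"]  # xh * g + b
        grads[p + "mlp_W1"] = ln1_out.reshape(-1, E).T @ dh1.reshape(-1, dh1.shape[-1])
        grads[p + "mlp_b1"] = dh1.sum(axis=(0, 1))
        da = dh1 @ a[p + "mlp_W1"].T
        dln1, grads[p + "ln1_g"], grads[p + "ln1_b"] = _nn.layer_norm_grad(da, ln1c)
        dx = (dx_in + dln1) * maskf

    # embeddings (dx pad rows are zero; pads carry token index 0)
    dname = dx[..., :H]
    dexpr = dx[..., H:]
    grads["name_emb"] = _nn.scatter_rows(
        batch.tokens.ravel(), dname.reshape(-1, H), params.vocab_size + 1
    )
    is_cls = (batch.tokens == params.vocab_size) & mask
    gm = mask & ~is_cls
    grads["expr_w"] = (dexpr[gm] * batch.expr[gm][:, None]).sum(axis=0)
    grads["expr_b"] = dexpr[gm].sum(axis=0)
    grads["cls_expr"] = dexpr[is_cls].sum(axis=0)
    return grads


def encode_token_batch(
    params: CmmParams, config: ModelConfig, batch: TokenBatch
) -> np.ndarray:
    """Coordinates for a prepared token batch (inference, no cache)."""
    crd, _ = encoder_forward(params, config, batch)
    return crd


def encode_cell(
    cell: np.ndarray,
    graph: DirectedGeneGraph,
    params: CmmParams,
    config: ModelConfig,
    cell_id: str = "",
) -> CellCoordinate:
    """Encode one cell's raw counts to its manifold coordinate.

    Inference mode: all non-zero genes are used, deterministically.
    """
    batch = build_token_batch(np.atleast_2d(cell), graph, config, training=False)
    crd = encode_token_batch(params, config, batch)
    n = int(np.count_nonzero(np.atleast_2d(cell)[0]))
    return CellCoordinate(crd[0], cell_id=cell_id, n_genes_used=n)


def encode_cells(
    counts: CountMatrix,
    graph: DirectedGeneGraph,
    params: CmmParams,
    config: ModelConfig,
    batch_size: int = 16,
    cache: GraphFeatureCache | None = None,
) -> np.ndarray:
    """Encode every cell of a count matrix (inference mode). [N, C] array."""
    out = np.empty((counts.n_cells, config.coordinate_dim), dtype=config.np_dtype)
    for start in range(0, counts.n_cells, batch_size):
        rows = counts.counts[start : start + batch_size]
        batch = build_token_batch(rows, graph, config, training=False, cache=cache)
        out[start : start + rows.shape[0]] = encode_token_batch(params, config, batch)
    return out


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(
    path: str | Path,
    config: ModelConfig,
    cmm: CmmParams,
    extra: dict[str, dict[str, np.ndarray]] | None = None,
) -> None:
    """Write named arrays (npz) plus a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"cmm/{k}": v for k, v in cmm.arrays.items()}
    for group, d in (extra or {}).items():
        arrays.update({f"{group}/{k}": v for k, v in d.items()})
    np.savez(path, **arrays)
    meta = {"config": asdict(config), "vocab_size": cmm.vocab_size}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path):
    """Returns (config, CmmParams, extra dict-of-dicts)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**meta["config"])
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    cmm_arrays: dict[str, np.ndarray] = {}
    extra: dict[str, dict[str, np.ndarray]] = {}
    for key in data.files:
        group, name = key.split("/", 1)
        if group == "cmm":
            cmm_arrays[name] = data[key]
        else:
            extra.setdefault(group, {})[name] = data[key]
    return config, CmmParams(cmm_arrays, meta["vocab_size"]), extra
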