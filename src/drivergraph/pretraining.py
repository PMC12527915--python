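"""Downsampling-reconstruction pretraining of the cell manifold model.

Each training step thins a cell's counts with Binomial(x, 1/r) at a rate
r ~ U[1, 20) drawn per cell, encodes the thinned profile to a coordinate,
and asks a small decoder to reconstruct the *original* expression profile.
The decoder receives, per queried gene, the concatenation of the cell
coordinate and that gene's embedding (the decoder's own table, initialized
from the encoder's) and emits one scalar.  The loss is the mean over cells
of the squared 2-norm of the residual over queried genes; both encoder and
decoder are trained.

By default the reconstruction target is the shifted-log-normalized
original profile; ``raw_target=True`` targets raw counts instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .cmm_encoder import (
    CmmParams,
    GraphFeatureCache,
    ModelConfig,
    build_token_batch,
    encoder_backward,
    encoder_forward,
)
from .data_core import CountMatrix, ValidationError, downsample_row, normalize_rows
from .gene_graph import DirectedGeneGraph

__all__ = [
    "DecoderParams",
    "PretrainReport",
    "TrainOptions",
    "init_decoder_params",
    "decode_profile",
    "reconstruction_loss",
    "pretrain",
]


class DecoderParams:
    """Two-layer MLP: (coordinate ⊕ gene embedding) -> scalar.

    ``mu``/``sigma`` center and scale the incoming coordinates at
    inference (the raw CLS projection carries a large cell-independent
    offset that would otherwise drown the per-cell signal); training uses
    batch statistics and the buffers are recalibrated afterwards.
    """

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = arrays

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def copy(self) -> "DecoderParams":
        return DecoderParams({k: v.copy() for k, v in self.arrays.items()})


def init_decoder_params(
    config: ModelConfig,
    seed: int | np.random.Generator,
    vocab_size: int = 0,
    gene_emb_init: np.ndarray | None = None,
) -> DecoderParams:
    """``gene_emb`` is the decoder's own copy of the gene-name embedding
    (initialized from the encoder's table when given); keeping it separate
    stops decoder gradients from reshaping the encoder's input space under
    the encoder's feet during joint optimization."""
    rng = np.random.default_rng(seed)
    dt = config.np_dtype
    F = config.decoder_hidden
    if gene_emb_init is not None:
        gene_emb = gene_emb_init.astype(dt).copy()
    else:
        gene_emb = (rng.standard_normal((vocab_size, config.H)) * 0.3).astype(dt)
    # the input weight is split into a coordinate part and a gene part so
    # that hidden activations for a batch decode as coord@W1c + emb@W1g
    return DecoderParams(
        {
            "W1c": _nn.init_linear(rng, config.coordinate_dim, F, dt),
            "W1g": _nn.init_linear(rng, config.H, F, dt),
            "b1": np.zeros(F, dtype=dt),
            "W2": _nn.init_linear(rng, F, 1, dt)[:, 0],
            "b2": np.zeros((), dtype=dt),
            "mu": np.zeros(config.coordinate_dim, dtype=dt),
            "sigma": np.ones((), dtype=dt),
            "gene_emb": gene_emb,
        }
    )


@dataclass
class TrainOptions:
    epochs: int = 10
    batch_size: int = 16
    lr: float = 1e-3
    seed: int = 0
    holdout_frac: float = 0.1
    warmup_frac: float = 0.05
    raw_target: bool = False
    max_cells: int | None = None
    rate_low: float = 1.0
    rate_high: float = 20.0


@dataclass
class PretrainReport:
    """Per-epoch losses plus a held-out reconstruction summary."""

    train_loss: list[float] = field(default_factory=list)
    holdout_loss: list[float] = field(default_factory=list)
    holdout_pearson: float = float("nan")
    mean_predictor_pearson: float = float("nan")
    initial_train_loss: float = float("nan")
    seed: int = 0
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def decode_forward(
    coord: np.ndarray, gene_emb: np.ndarray, dec: DecoderParams, train: bool = False
):
    """coord [B,C], gene_emb [Gq,H] -> predictions [B,Gq] (+ cache)."""
    coord_c, sigma, bs = _nn.center_features(dec, coord, train)
    hc = coord_c @ dec["W1c"]  # [B,F]
    hg = gene_emb @ dec["W1g"]  # [Gq,F]
    h1 = hc[:, None, :] + hg[None, :, :] + dec["b1"]  # [B,Gq,F]
    g = _nn.gelu(h1)
    pred = g @ dec["W2"] + dec["b2"]  # [B,Gq]
    return pred, (coord_c, h1, g, sigma, bs)


def decode_backward(
    dpred: np.ndarray,
    gene_emb: np.ndarray,
    dec: DecoderParams,
    cache,
):
    """Returns (decoder grads, d_coord, d_gene_emb)."""
    coord_c, h1, g, sigma, bs = cache
    grads: dict[str, np.ndarray] = {}
    grads["W2"] = np.einsum("bgf,bg->f", g, dpred)
    grads["b2"] = np.asarray(dpred.sum(), dtype=dpred.dtype)
    dg = dpred[..., None] * dec["W2"]
    dh1 = dg * _nn.gelu_grad(h1)
    grads["b1"] = dh1.sum(axis=(0, 1))
    dhc = dh1.sum(axis=1)  # [B,F]
    dhg = dh1.sum(axis=0)  # [Gq,F]
    grads["W1c"] = coord_c.T @ dhc
    grads["W1g"] = gene_emb.T @ dhg
    d_coord = _nn.center_features_grad(dhc @ dec["W1c"].T, sigma, bs)
    d_gene_emb = dhg @ dec["W1g"].T
    return grads, d_coord, d_gene_emb


def decode_profile(
    coordinate: np.ndarray,
    gene_indices: np.ndarray | list[int],
    cmm_params: CmmParams,
    decoder_params: DecoderParams,
) -> np.ndarray:
    """Predicted expression for the queried genes of one cell."""
    gene_indices = np.asarray(gene_indices, dtype=np.int64)
    n_genes = decoder_params["gene_emb"].shape[0]
    if gene_indices.size and (
        gene_indices.min() < 0 or gene_indices.max() >= n_genes
    ):
        raise ValidationError("gene index outside vocabulary")
    emb = decoder_params["gene_emb"][gene_indices]
    pred, _ = decode_forward(np.atleast_2d(coordinate), emb, decoder_params)
    return pred[0]


def reconstruction_loss(predicted: np.ndarray, target: np.ndarray) -> float:
    """Mean over cells of the squared 2-norm of (predicted - target)."""
    predicted = np.atleast_2d(predicted)
    target = np.atleast_2d(target)
    if predicted.shape != target.shape:
        raise ValidationError(
            f"shape mismatch {predicted.shape} vs {target.shape}"
        )
    resid = predicted - target
    return float((resid * resid).sum(axis=1).mean())


def _query_genes(
    orig_row: np.ndarray, config: ModelConfig, rng: np.random.Generator
) -> np.ndarray:
    """Genes whose expression the decoder must reconstruct.

    Full vocabulary when it fits in one step; otherwise all genes non-zero
    in the original profile plus an equal-sized sample of zero genes.
    """
    G = orig_row.shape[0]
    if G <= 2048:
        return np.arange(G)
    nz = np.flatnonzero(orig_row)
    zeros = np.flatnonzero(orig_row == 0)
    k = min(zeros.size, nz.size)
    picked = rng.choice(zeros, size=k, replace=False) if k else zeros
    return np.sort(np.concatenate([nz, picked]))


def pretrain(
    counts: CountMatrix,
    graph: DirectedGeneGraph,
    config: ModelConfig,
    opts: TrainOptions,
    cmm_init: CmmParams | None = None,
) -> tuple[CmmParams, DecoderParams, PretrainReport]:
    """Run the downsampling-reconstruction task; returns trained params.

    Fully reproducible for a fixed ``opts.seed``.  Held-out cells (chosen
    by cell, seeded) are never trained on; the report carries their final
    reconstruction loss and per-cell Pearson correlation, next to a
    mean-predictor baseline (the training-set mean profile).
    """
    if counts.n_cells < 2:
        raise ValidationError("need at least 2 cells")
    if not (0 <= opts.holdout_frac <= 0.5):
        raise ValidationError("holdout_frac must be in [0, 0.5]")
    rng = np.random.default_rng(opts.seed)
    n = counts.n_cells
    perm = rng.permutation(n)
    if opts.max_cells is not None and opts.max_cells < n:
        perm = perm[: opts.max_cells]
        n = opts.max_cells
    n_hold = int(round(opts.holdout_frac * n))
    hold_idx = perm[:n_hold]
    train_idx = perm[n_hold:]

    params = cmm_init.copy() if cmm_init is not None else None
    if params is None:
        from .cmm_encoder import init_cmm_params

        params = init_cmm_params(counts.n_genes, config, rng)
    dec = init_decoder_params(
        config, rng, gene_emb_init=params["name_emb"][: counts.n_genes]
    )
    all_params = {f"cmm/{k}": v for k, v in params.arrays.items()}
    all_params.update({f"dec/{k}": v for k, v in dec.arrays.items()})
    steps_per_epoch = max(1, int(np.ceil(train_idx.size / opts.batch_size)))
    opt = _nn.Adam(
        all_params,
        lr=opts.lr,
        warmup_steps=int(opts.warmup_frac * steps_per_epoch * max(opts.epochs, 1)),
    )
    cache = GraphFeatureCache()
    norm_all = normalize_rows(counts.counts, L=config.L)
    nz_counts = (counts.counts > 0).sum(axis=1)

    def batch_loss(idx: np.ndarray, train: bool, rng_: np.random.Generator):
        rows = counts.counts[idx]
        rates = rng_.uniform(opts.rate_low, opts.rate_high, size=idx.size)
        ds = np.stack(
            [downsample_row(rows[i], rates[i], rng_) for i in range(idx.size)]
        )
        tb = build_token_batch(
            ds, graph, config, training=train, seed=rng_, cache=cache
        )
        crd, enc_cache = encoder_forward(params, config, tb, need_cache=train)
        q = _query_genes(rows[0], config, rng_)
        emb = dec["gene_emb"][q]
        pred, dec_cache = decode_forward(crd, emb, dec, train=train)
        if opts.raw_target:
            target = rows[:, q].astype(config.np_dtype)
        else:
            target = norm_all[idx][:, q].astype(config.np_dtype)
        resid = pred - target
        loss = float((resid * resid).sum(axis=1).mean())
        return loss, (tb, crd, enc_cache, q, emb, pred, dec_cache, resid)

    def eval_loss(idx: np.ndarray, seed: int) -> float:
        r = np.random.default_rng(seed)
        idx = idx[np.argsort(nz_counts[idx], kind="stable")]
        total = 0.0
        for s in range(0, idx.size, opts.batch_size):
            chunk = idx[s : s + opts.batch_size]
            l, _ = batch_loss(chunk, train=False, rng_=r)
            total += l * chunk.size
        return total / max(idx.size, 1)

    def calibrate() -> None:
        # inference-time centering statistics from an encoding pass with
        # the current parameters (training itself uses batch statistics)
        stat_rng = np.random.default_rng(opts.seed + 5)
        stat_idx = train_idx[: min(128, train_idx.size)]
        chunks = []
        for s0 in range(0, stat_idx.size, opts.batch_size):
            chunk = stat_idx[s0 : s0 + opts.batch_size]
            rows = counts.counts[chunk]
            rates = stat_rng.uniform(opts.rate_low, opts.rate_high, size=chunk.size)
            ds = np.stack(
                [downsample_row(rows[i], rates[i], stat_rng) for i in range(chunk.size)]
            )
            tb = build_token_batch(ds, graph, config, training=False, cache=cache)
            crd, _ = encoder_forward(params, config, tb)
            chunks.append(crd)
        _nn.set_feature_stats(dec, np.concatenate(chunks, axis=0))

    calibrate()

    report = PretrainReport(seed=opts.seed, config=asdict(config))
    report.initial_train_loss = eval_loss(train_idx, opts.seed + 1)

    for epoch in range(opts.epochs):
        # linear decay to 10% of the base rate over the run
        if opts.epochs > 1:
            opt.lr = opts.lr * (1.0 - 0.9 * epoch / (opts.epochs - 1))
        batches = _nn.bucketed_batches(
            rng.permutation(train_idx), nz_counts, opts.batch_size, rng
        )
        running = 0.0
        for idx in batches:
            loss, ctx = batch_loss(idx, train=True, rng_=rng)
            running += loss * idx.size
            tb, crd, enc_cache, q, emb, pred, dec_cache, resid = ctx
            dpred = (2.0 / idx.size) * resid
            dec_grads, d_coord, d_emb = decode_backward(dpred, emb, dec, dec_cache)
            enc_grads = encoder_backward(params, config, tb, enc_cache, d_coord)
            gemb_grad = np.zeros_like(dec.arrays["gene_emb"])
            gemb_grad[q] = d_emb  # query indices are unique
            dec_grads["gene_emb"] = gemb_grad
            step_grads = {f"cmm/{k}": v for k, v in enc_grads.items()}
            step_grads.update({f"dec/{k}": v for k, v in dec_grads.items()})
            if not all(np.isfinite(g).all() for g in step_grads.values()):
                raise RuntimeError(
                    f"non-finite gradient at epoch {epoch}; try a lower lr"
                )
            opt.step(step_grads)
        report.train_loss.append(running / train_idx.size)
        if hold_idx.size:
            calibrate()
            report.holdout_loss.append(eval_loss(hold_idx, opts.seed + 2))

    calibrate()
    if hold_idx.size:
        report.holdout_pearson, report.mean_predictor_pearson = _holdout_pearson(
            counts, graph, config, params, dec, norm_all, train_idx, hold_idx, opts, cache
        )
    return params, dec, report


def _holdout_pearson(
    counts, graph, config, params, dec, norm_all, train_idx, hold_idx, opts, cache
) -> tuple[float, float]:
    """Mean per-cell Pearson r of decoded vs true normalized profiles on
    held-out cells, and the same for the train-mean predictor."""
    rng = np.random.default_rng(opts.seed + 3)
    mean_profile = norm_all[train_idx].mean(axis=0)
    rs_model, rs_mean = [], []
    for s in range(0, hold_idx.size, opts.batch_size):
        idx = hold_idx[s : s + opts.batch_size]
        rows = counts.counts[idx]
        rates = rng.uniform(opts.rate_low, opts.rate_high, size=idx.size)
        ds = np.stack(
            [downsample_row(rows[i], rates[i], rng) for i in range(idx.size)]
        )
        tb = build_token_batch(ds, graph, config, training=False, cache=cache)
        crd, _ = encoder_forward(params, config, tb)
        q = _query_genes(rows[0], config, rng)
        pred, _ = decode_forward(crd, dec["gene_emb"][q], dec)
        truth = norm_all[idx][:, q]
        for i in range(idx.size):
            rs_model.append(_pearson(pred[i], truth[i]))
            rs_mean.append(_pearson(mean_profile[q], truth[i]))
    return float(np.mean(rs_model)), float(np.mean(rs_mean))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0
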