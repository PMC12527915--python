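"""Driver-gene prediction from paired cell states.

A source cell (e.g. unperturbed control) and a target cell (post
perturbation) are both encoded to manifold coordinates; a two-layer MLP on
the concatenated coordinates emits one logit per candidate driver gene.
Training minimizes cross-entropy against the known driver and fine-tunes
the encoder jointly with the classifier head.

Ablation variants mirror the component analysis:

* ``no_cmm``  — the same MLP head on concatenated shifted-log expression
  vectors instead of coordinates;
* ``no_dgp``  — multinomial logistic regression (one linear layer +
  softmax) on frozen coordinates;
* ``masked_driver`` — standard prediction after zeroing the true driver's
  count in both cells before encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

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
from .data_core import CountMatrix, ValidationError, normalize_rows
from .gene_graph import DirectedGeneGraph

logger = logging.getLogger(__name__)

__all__ = [
    "Pair",
    "PairedDataset",
    "DgpParams",
    "LikelihoodVector",
    "FinetuneOptions",
    "FinetuneReport",
    "init_dgp_params",
    "predict_likelihoods",
    "predict_pairs",
    "driver_loss",
    "finetune",
    "fit_no_dgp",
    "rank_candidates",
    "ablation_predict",
]


@dataclass(frozen=True)
class Pair:
    source_id: str
    target_id: str
    driver: str
    split: str = "train"  # train | test
    second_driver: str | None = None  # dual perturbations, evaluation only


@dataclass
class PairedDataset:
    """(source, target, driver) triples with train/test split tags."""

    pairs: list[Pair]
    candidate_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.candidate_genes:
            self.candidate_genes = sorted(
                {p.driver for p in self.pairs if p.split == "train"}
            )
        cand = set(self.candidate_genes)
        for p in self.pairs:
            if p.driver not in cand:
                raise ValidationError(
                    f"driver {p.driver!r} outside candidate set"
                )
        train = {(p.source_id, p.target_id) for p in self.pairs if p.split == "train"}
        test = {(p.source_id, p.target_id) for p in self.pairs if p.split == "test"}
        if train & test:
            raise ValidationError("pair appears in both train and test splits")

    @property
    def K(self) -> int:
        return len(self.candidate_genes)

    def split_pairs(self, split: str) -> list[Pair]:
        return [p for p in self.pairs if p.split == split]


class DgpParams:
    """Two-layer MLP head: concat(CRD_src, CRD_tgt) -> K logits.

    ``mu``/``sigma`` center and scale incoming features at inference
    (coordinates carry a large cell-independent offset); training uses
    batch statistics and the buffers are recalibrated afterwards.
    """

    def __init__(self, arrays: dict[str, np.ndarray], candidate_genes: list[str]):
        self.arrays = arrays
        self.candidate_genes = list(candidate_genes)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    @property
    def K(self) -> int:
        return len(self.candidate_genes)

    def copy(self) -> "DgpParams":
        return DgpParams(
            {k: v.copy() for k, v in self.arrays.items()}, self.candidate_genes
        )


@dataclass
class LikelihoodVector:
    """Softmax probability per candidate driver; sums to 1."""

    probabilities: np.ndarray
    candidate_genes: list[str]

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (len(self.candidate_genes),):
            raise ValidationError("probability/candidate length mismatch")


def init_dgp_params(
    input_dim: int,
    candidate_genes: list[str],
    config: ModelConfig,
    seed: int | np.random.Generator,
) -> DgpParams:
    if len(candidate_genes) < 2:
        raise ValidationError("need at least 2 candidate genes")
    rng = np.random.default_rng(seed)
    dt = config.np_dtype
    Hd = config.dgp_hidden if config.dgp_hidden is not None else config.coordinate_dim
    K = len(candidate_genes)
    return DgpParams(
        {
            "W1": _nn.init_linear(rng, input_dim, Hd, dt),
            "b1": np.zeros(Hd, dtype=dt),
            "W2": _nn.init_linear(rng, Hd, K, dt),
            "b2": np.zeros(K, dtype=dt),
            "mu": np.zeros(input_dim, dtype=dt),
            "sigma": np.ones((), dtype=dt),
        },
        candidate_genes,
    )


def dgp_forward(feats: np.ndarray, dgp: DgpParams, train: bool = False):
    feats_c, sigma, bs = _nn.center_features(dgp, feats, train)
    h1 = feats_c @ dgp["W1"] + dgp["b1"]
    g = _nn.gelu(h1)
    logits = g @ dgp["W2"] + dgp["b2"]
    return logits, (feats_c, h1, g, sigma, bs)


def dgp_backward(dlogits: np.ndarray, dgp: DgpParams, cache):
    feats_c, h1, g, sigma, bs = cache
    grads = {
        "W2": g.T @ dlogits,
        "b2": dlogits.sum(axis=0),
    }
    dg = dlogits @ dgp["W2"].T
    dh1 = dg * _nn.gelu_grad(h1)
    grads["W1"] = feats_c.T @ dh1
    grads["b1"] = dh1.sum(axis=0)
    dfeats = _nn.center_features_grad(dh1 @ dgp["W1"].T, sigma, bs)
    return grads, dfeats


def driver_loss(logits: np.ndarray, label: int) -> float:
    """Cross-entropy -log softmax(logits)[label]."""
    logits = np.asarray(logits, dtype=float)
    if not 0 <= label < logits.shape[0]:
        raise ValidationError(f"label {label} out of range for K={logits.shape[0]}")
    m = logits.max()
    return float(np.log(np.exp(logits - m).sum()) - (logits[label] - m))


def predict_likelihoods(
    src: np.ndarray,
    tgt: np.ndarray,
    graph: DirectedGeneGraph,
    cmm_params: CmmParams,
    dgp_params: DgpParams,
    config: ModelConfig,
) -> LikelihoodVector:
    """Likelihood score per candidate driver for one source/target pair."""
    tb = build_token_batch(np.stack([src, tgt]), graph, config, training=False)
    crd, _ = encoder_forward(cmm_params, config, tb)
    feats = np.concatenate([crd[0], crd[1]])[None, :]
    if dgp_params["W1"].shape[0] != feats.shape[1]:
        raise ValidationError("DGP input width does not match coordinate dim")
    logits, _ = dgp_forward(feats, dgp_params)
    return LikelihoodVector(_nn.softmax(logits[0]), dgp_params.candidate_genes)


def predict_pairs(
    counts: CountMatrix,
    pairs: list[Pair],
    graph: DirectedGeneGraph,
    cmm_params: CmmParams,
    dgp_params: DgpParams,
    config: ModelConfig,
    batch_size: int = 16,
    mask_driver: bool = False,
    cache: GraphFeatureCache | None = None,
) -> np.ndarray:
    """Probabilities [n_pairs, K] at inference (all non-zero genes).

    ``mask_driver=True`` zeroes the true driver's count in both cells of
    each pair before encoding (expression-shift ablation).
    """
    cell_index = {c: i for i, c in enumerate(counts.cell_ids)}
    gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
    out = np.empty((len(pairs), dgp_params.K))
    nz = (counts.counts > 0).sum(axis=1)
    order = sorted(
        range(len(pairs)),
        key=lambda i: int(
            nz[cell_index[pairs[i].source_id]] + nz[cell_index[pairs[i].target_id]]
        ),
    )
    for s in range(0, len(pairs), batch_size):
        sel = order[s : s + batch_size]
        chunk = [pairs[i] for i in sel]
        src = counts.counts[[cell_index[p.source_id] for p in chunk]].copy()
        tgt = counts.counts[[cell_index[p.target_id] for p in chunk]].copy()
        if mask_driver:
            for i, p in enumerate(chunk):
                gi = gene_index[p.driver]
                src[i, gi] = 0
                tgt[i, gi] = 0
        tb_s = build_token_batch(src, graph, config, training=False, cache=cache)
        tb_t = build_token_batch(tgt, graph, config, training=False, cache=cache)
        crd_s, _ = encoder_forward(cmm_params, config, tb_s)
        crd_t, _ = encoder_forward(cmm_params, config, tb_t)
        logits, _ = dgp_forward(np.concatenate([crd_s, crd_t], axis=1), dgp_params)
        out[sel] = _nn.softmax(logits, axis=-1)
    return out


def rank_candidates(likelihoods: LikelihoodVector) -> np.ndarray:
    """Dense ranks (1 = most likely); ties broken by ascending gene index."""
    p = likelihoods.probabilities
    order = np.lexsort((np.arange(p.size), -p))
    ranks = np.empty(p.size, dtype=np.int64)
    ranks[order] = np.arange(1, p.size + 1)
    return ranks


@dataclass
class FinetuneOptions:
    epochs: int = 8
    batch_size: int = 8
    lr: float = 1e-3
    seed: int = 0
    freeze_cmm: bool = False
    variant: str = "full"  # full | no_cmm
    pairs_per_epoch: int | None = None
    eval_max_pairs: int | None = None
    eval_every: int = 1
    weight_decay: float = 0.0


@dataclass
class FinetuneReport:
    train_loss: list[float] = field(default_factory=list)
    train_top1: list[float] = field(default_factory=list)
    eval_epochs: list[int] = field(default_factory=list)
    test_top1: list[float] = field(default_factory=list)
    test_top5: list[float] = field(default_factory=list)
    candidate_genes: list[str] = field(default_factory=list)
    seed: int = 0
    variant: str = "full"


def _topk_from_probs(probs: np.ndarray, labels: np.ndarray, k: int) -> float:
    order = np.argsort(-probs, axis=1, kind="stable")
    hits = (order[:, :k] == labels[:, None]).any(axis=1)
    return float(hits.mean())


def finetune(
    dataset: PairedDataset,
    counts: CountMatrix,
    graph: DirectedGeneGraph,
    cmm_params_init: CmmParams | None,
    config: ModelConfig,
    opts: FinetuneOptions,
    source_pool: dict[str, list[str]] | None = None,
) -> tuple[CmmParams | None, DgpParams, FinetuneReport]:
    """Train the driver-gene predictor (and, unless frozen, the encoder).

    ``variant="no_cmm"`` trains the same MLP head directly on concatenated
    shifted-log expression vectors; the returned CmmParams is then None.
    ``source_pool`` (target id -> eligible source cell ids) enables
    control-resampling augmentation: each training epoch re-pairs every
    target with a random eligible control (evaluation pairs stay fixed).
    Dual-perturbation pairs are never part of the train split (enforced by
    the dataset builder); seeded and reproducible.
    """
    train_pairs = dataset.split_pairs("train")
    test_pairs = dataset.split_pairs("test")
    if not train_pairs:
        raise ValidationError("empty train split")
    rng = np.random.default_rng(opts.seed)
    cell_index = {c: i for i, c in enumerate(counts.cell_ids)}
    cand_index = {g: i for i, g in enumerate(dataset.candidate_genes)}
    src_idx = np.array([cell_index[p.source_id] for p in train_pairs])
    tgt_idx = np.array([cell_index[p.target_id] for p in train_pairs])
    labels = np.array([cand_index[p.driver] for p in train_pairs])

    use_encoder = opts.variant == "full"
    if use_encoder:
        if cmm_params_init is not None:
            cmm = cmm_params_init.copy()
        else:
            from .cmm_encoder import init_cmm_params

            cmm = init_cmm_params(counts.n_genes, config, rng)
        feat_dim = 2 * config.coordinate_dim
    else:
        cmm = None
        feat_dim = 2 * counts.n_genes
        norm_all = normalize_rows(counts.counts, L=config.L)
    dgp = init_dgp_params(feat_dim, dataset.candidate_genes, config, rng)

    all_params = {f"dgp/{k}": v for k, v in dgp.arrays.items()}
    if use_encoder and not opts.freeze_cmm:
        all_params.update({f"cmm/{k}": v for k, v in cmm.arrays.items()})
    opt = _nn.Adam(all_params, lr=opts.lr, weight_decay=opts.weight_decay)
    cache = GraphFeatureCache()
    n_train = len(train_pairs)
    pool_idx = None
    if source_pool is not None:
        pool_idx = [
            np.array([cell_index[c] for c in source_pool[p.target_id]])
            for p in train_pairs
        ]

    def calibrate() -> None:
        # inference-time centering statistics from an encoding pass with
        # the current parameters (training itself uses batch statistics)
        n_stat = min(96 if use_encoder else 512, n_train)
        if use_encoder:
            chunks = []
            for s0 in range(0, n_stat, opts.batch_size):
                sel = np.arange(s0, min(s0 + opts.batch_size, n_stat))
                tb_s = build_token_batch(
                    counts.counts[src_idx[sel]], graph, config,
                    training=False, cache=cache,
                )
                tb_t = build_token_batch(
                    counts.counts[tgt_idx[sel]], graph, config,
                    training=False, cache=cache,
                )
                cs, _ = encoder_forward(cmm, config, tb_s)
                ct, _ = encoder_forward(cmm, config, tb_t)
                chunks.append(np.concatenate([cs, ct], axis=1))
            _nn.set_feature_stats(dgp, np.concatenate(chunks, axis=0))
        else:
            _nn.set_feature_stats(
                dgp,
                np.concatenate(
                    [norm_all[src_idx[:n_stat]], norm_all[tgt_idx[:n_stat]]], axis=1
                ).astype(config.np_dtype),
            )

    calibrate()

    report = FinetuneReport(
        candidate_genes=dataset.candidate_genes, seed=opts.seed, variant=opts.variant
    )

    def eval_test() -> tuple[float, float]:
        pairs = test_pairs
        if opts.eval_max_pairs is not None and len(pairs) > opts.eval_max_pairs:
            pick = np.random.default_rng(opts.seed + 7).choice(
                len(pairs), size=opts.eval_max_pairs, replace=False
            )
            pairs = [pairs[i] for i in pick]
        lab = np.array([cand_index[p.driver] for p in pairs])
        if use_encoder:
            probs = predict_pairs(
                counts, pairs, graph, cmm, dgp, config, cache=cache
            )
        else:
            si = [cell_index[p.source_id] for p in pairs]
            ti = [cell_index[p.target_id] for p in pairs]
            feats = np.concatenate([norm_all[si], norm_all[ti]], axis=1)
            logits, _ = dgp_forward(feats.astype(config.np_dtype), dgp)
            probs = _nn.softmax(logits, axis=-1)
        return _topk_from_probs(probs, lab, 1), _topk_from_probs(probs, lab, 5)

    nz = (counts.counts > 0).sum(axis=1)
    pair_len = nz[src_idx] + nz[tgt_idx]  # padding proxy for batch bucketing
    for epoch in range(opts.epochs):
        # linear decay to 10% of the base rate over the run
        if opts.epochs > 1:
            opt.lr = opts.lr * (1.0 - 0.9 * epoch / (opts.epochs - 1))
        order = rng.permutation(n_train)
        if opts.pairs_per_epoch is not None:
            order = order[: opts.pairs_per_epoch]
        batches = _nn.bucketed_batches(order, pair_len, opts.batch_size, rng)
        running, correct, seen = 0.0, 0, 0
        for idx in batches:
            B = idx.size
            lab = labels[idx]
            s_sel = src_idx[idx]
            if pool_idx is not None:
                s_sel = np.array(
                    [pool_idx[i][rng.integers(pool_idx[i].size)] for i in idx]
                )
            if use_encoder:
                tb_s = build_token_batch(
                    counts.counts[s_sel], graph, config,
                    training=True, seed=rng, cache=cache,
                )
                tb_t = build_token_batch(
                    counts.counts[tgt_idx[idx]], graph, config,
                    training=True, seed=rng, cache=cache,
                )
                need = not opts.freeze_cmm
                crd_s, cache_s = encoder_forward(cmm, config, tb_s, need_cache=need)
                crd_t, cache_t = encoder_forward(cmm, config, tb_t, need_cache=need)
                feats = np.concatenate([crd_s, crd_t], axis=1)
            else:
                feats = np.concatenate(
                    [norm_all[s_sel], norm_all[tgt_idx[idx]]], axis=1
                ).astype(config.np_dtype)
            logits, head_cache = dgp_forward(feats, dgp, train=True)
            p = _nn.softmax(logits, axis=-1)
            running += float(-np.log(p[np.arange(B), lab] + 1e-30).sum())
            correct += int((logits.argmax(axis=1) == lab).sum())
            seen += B
            dlogits = p.copy()
            dlogits[np.arange(B), lab] -= 1.0
            dlogits /= B
            head_grads, dfeats = dgp_backward(dlogits, dgp, head_cache)
            step_grads = {f"dgp/{k}": v for k, v in head_grads.items()}
            if use_encoder and not opts.freeze_cmm:
                C = config.coordinate_dim
                gs = encoder_backward(cmm, config, tb_s, cache_s, dfeats[:, :C])
                gt = encoder_backward(cmm, config, tb_t, cache_t, dfeats[:, C:])
                step_grads.update(
                    {f"cmm/{k}": gs[k] + gt[k] for k in gs}
                )
            opt.step(step_grads)
        report.train_loss.append(running / max(seen, 1))
        report.train_top1.append(correct / max(seen, 1))
        last = epoch == opts.epochs - 1
        if test_pairs and (epoch % opts.eval_every == 0 or last):
            calibrate()
            t1, t5 = eval_test()
            report.eval_epochs.append(epoch)
            report.test_top1.append(t1)
            report.test_top5.append(t5)
    calibrate()
    return cmm, dgp, report


def fit_no_dgp(
    dataset: PairedDataset,
    counts: CountMatrix,
    graph: DirectedGeneGraph,
    cmm_params: CmmParams,
    config: ModelConfig,
    seed: int = 0,
):
    """Multinomial logistic regression on frozen concatenated coordinates.

    Returns (fitted sklearn model, coordinates array for all cells) so the
    caller can reuse the embedding.
    """
    from sklearn.linear_model import LogisticRegression
    from .cmm_encoder import encode_cells

    coords = encode_cells(counts, graph, cmm_params, config)
    cell_index = {c: i for i, c in enumerate(counts.cell_ids)}
    cand_index = {g: i for i, g in enumerate(dataset.candidate_genes)}
    train = dataset.split_pairs("train")
    X = np.concatenate(
        [
            coords[[cell_index[p.source_id] for p in train]],
            coords[[cell_index[p.target_id] for p in train]],
        ],
        axis=1,
    )
    y = np.array([cand_index[p.driver] for p in train])
    model = LogisticRegression(max_iter=2000, random_state=seed)
    model.fit(X, y)
    return model, coords


def ablation_predict(
    variant: str,
    src: np.ndarray,
    tgt: np.ndarray,
    graph: DirectedGeneGraph,
    config: ModelConfig,
    cmm_params: CmmParams | None = None,
    dgp_params: DgpParams | None = None,
    logreg=None,
    candidate_genes: list[str] | None = None,
    driver: int | None = None,
) -> LikelihoodVector:
    """Predict under one ablation variant for a single pair.

    ``no_cmm`` expects dgp_params trained on expression features;
    ``no_dgp`` expects a fitted logistic-regression model and cmm_params;
    ``masked_driver`` expects the full model plus the true driver's index.
    """
    if variant == "no_cmm":
        if dgp_params is None:
            raise ValidationError("no_cmm needs expression-space dgp_params")
        feats = np.concatenate(
            [normalize_rows(src, config.L)[0], normalize_rows(tgt, config.L)[0]]
        )[None, :].astype(config.np_dtype)
        if dgp_params["W1"].shape[0] != feats.shape[1]:
            raise ValidationError("dgp_params were not trained in no_cmm mode")
        logits, _ = dgp_forward(feats, dgp_params)
        return LikelihoodVector(_nn.softmax(logits[0]), dgp_params.candidate_genes)
    if variant == "no_dgp":
        if logreg is None or cmm_params is None or candidate_genes is None:
            raise ValidationError("no_dgp needs logreg, cmm_params, candidate_genes")
        tb = build_token_batch(np.stack([src, tgt]), graph, config, training=False)
        crd, _ = encoder_forward(cmm_params, config, tb)
        X = np.concatenate([crd[0], crd[1]])[None, :]
        p = np.zeros(len(candidate_genes))
        p[logreg.classes_] = logreg.predict_proba(X)[0]
        return LikelihoodVector(p, candidate_genes)
    if variant == "masked_driver":
        if cmm_params is None or dgp_params is None or driver is None:
            raise ValidationError("masked_driver needs the full model and driver index")
        src = np.asarray(src).copy()
        tgt = np.asarray(tgt).copy()
        src[driver] = 0
        tgt[driver] = 0
        return predict_likelihoods(src, tgt, graph, cmm_params, dgp_params, config)
    raise ValueError(f"unknown ablation variant {variant!r}")
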