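"""Feature fusion and the Cox-loss neural risk model.

The risk head is a feed-forward network of four FC blocks (1024, 512,
256, 128 units; each linear -> dropout 0.2 -> ReLU) ending in a linear
map to one scalar risk score, trained to minimize the negative Cox
partial log-likelihood

    l(theta) = -sum_i d_i [ h(x_i) - log sum_j 1{t_j >= t_i} exp(h(x_j)) ]

with Breslow-style risk sets (tied times enter each other's risk sets).
Inputs are the early fusion ``[embedding | centered expression |
clinical]``; six variants control which blocks are present and whether
training pools cohorts pan-cancer with the tail of the encoder unfrozen.
Hyperparameters (learning rate, decoupled weight decay, gradient-norm
clip) are grid-searched with the validation split used for model
selection and early stopping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._nn import MLP, AdamW, clip_global_norm
from . import preprocess
from .datagen import SurvivalCohort
from .encoder import EncoderConfig, MockEncoder, init_mock_encoder
from .metrics import harrell_cindex

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "PipelineConfig",
    "TrainConfig",
    "SplitAssignment",
    "RiskModel",
    "stratified_split",
    "encode_clinical",
    "fuse_features",
    "cox_partial_likelihood_loss",
    "cox_loss_and_risk_gradient",
    "train",
    "fit_variant",
    "pan_cancer_pool",
    "FitResult",
]

VARIANTS = (
    "Embed",
    "Embed+Clin",
    "Embed-pan+Clin",
    "mRNA+Clin",
    "EGSP-pan",
    "EGSP",
)

HEAD_WIDTHS = (1024, 512, 256, 128)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings for one variant fit.

    ``Ng`` is the number of survival-associated genes kept by the screen
    (default 1024, grid {512, 1024, 2048} in the study design), ``Nu``
    the number of unfrozen trailing encoder layers for the pan variants;
    ``Ne`` follows from the encoder pooling mode and ``Nc`` from the
    clinical columns available, so neither is set directly.
    """

    Ng: int = 1024
    Nu: int = 3
    variant: str = "EGSP"
    target_sum: float = 10_000.0
    encoder: EncoderConfig | None = None
    head_widths: tuple = HEAD_WIDTHS
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid names: {list(VARIANTS)}"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization grid and schedule (AdamW, up to 200 epochs,
    validation-guided early stopping)."""

    lr_grid: tuple = (2e-5, 2e-4, 2e-3, 2e-2)
    weight_decay_grid: tuple = (0.001, 0.01, 0.1, 0.25)
    grad_norm_grid: tuple = (0.1, 1.0, 2.0, 5.0)
    optimizer_name: str = "adamw"
    max_epochs: int = 200
    patience: int = 10
    criterion: str = "harrell"  # or "loss"
    reduction: str = "sum"  # or "mean" (over events), for lr comparability
    seed: int = 0

    def __post_init__(self):
        if not (self.lr_grid and self.weight_decay_grid and self.grad_norm_grid):
            raise ValueError("hyperparameter grids must be non-empty")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.optimizer_name != "adamw":
            raise ValueError("only the adamw optimizer is supported")
        if self.criterion not in ("harrell", "loss"):
            raise ValueError("criterion must be 'harrell' or 'loss'")


@dataclass
class SplitAssignment:
    """Per-sample train/val/test labels with censoring-stratified counts."""

    labels: np.ndarray  # array of {"train","val","test"}
    fractions: tuple = (0.70, 0.15, 0.15)
    seed: int = 0

    def rows(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.labels == part)


class RiskModel:
    """Risk head h_theta: FC blocks 1024/512/256/128 -> scalar score."""

    def __init__(self, in_dim: int, head_widths=HEAD_WIDTHS, dropout: float = 0.2,
                 seed: int = 0):
        self.in_dim = in_dim
        self.head_widths = tuple(head_widths)
        self.dropout = dropout
        self.seed = seed
        self.net = MLP(in_dim, hidden=self.head_widths, dropout=dropout, seed=seed)

    def predict(self, X) -> np.ndarray:
        """Deterministic evaluation-mode risk scores."""
        return self.net.predict(np.asarray(X, float))

    def reinitialize(self) -> None:
        self.net = MLP(self.in_dim, hidden=self.head_widths, dropout=self.dropout,
                       seed=self.seed)


def _largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    quotas = n * fractions
    base = np.floor(quotas).astype(int)
    rem = quotas - base
    leftover = n - base.sum()
    order = np.argsort(-rem, kind="stable")  # remainder ties: earlier split wins
    base[order[:leftover]] += 1
    return base


def stratified_split(event, fractions=(0.70, 0.15, 0.15), seed: int = 0) -> SplitAssignment:
    """Partition samples into train/val/test, events and censored cases
    separately, with largest-remainder rounding; deterministic in seed."""
    fractions = np.asarray(fractions, float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    event = np.asarray(event, int)
    rng = np.random.default_rng(seed)
    labels = np.empty(len(event), dtype=object)
    names = np.array(["train", "val", "test"])
    for value in (1, 0):
        idx = np.flatnonzero(event == value)
        if 0 < len(idx) < len(fractions):
            warnings.warn(
                f"stratum event={value} has {len(idx)} samples, fewer than "
                "the number of splits; best-effort assignment"
            )
        if len(idx) == 0:
            warnings.warn(f"stratum event={value} is empty")
            continue
        rng.shuffle(idx)
        counts = _largest_remainder(len(idx), fractions)
        bounds = np.cumsum(counts)[:-1]
        for part, chunk in zip(names, np.split(idx, bounds)):
            labels[chunk] = part
    return SplitAssignment(labels=labels.astype(str), fractions=tuple(fractions),
                           seed=seed)


def encode_clinical(clinical: pd.DataFrame, train_rows) -> np.ndarray:
    """Numeric clinical design: age standardized by training mean/sd,
    gender {0,1}, ordinal stage 1-4 when available (Nc = 3, else 2)."""
    age = clinical["age"].to_numpy(float)
    mu = age[train_rows].mean()
    sd = age[train_rows].std() or 1.0
    cols = [(age - mu) / sd, clinical["gender"].to_numpy(float)]
    if clinical["stage"].notna().all():
        cols.append(clinical["stage"].to_numpy(float))
    return np.column_stack(cols)


def fuse_features(embeddings=None, expr_selected=None, clinical=None,
                  training_gene_means=None) -> np.ndarray:
    """Early fusion ``[embedding | centered expression | clinical]``.

    The expression block is centered by ``training_gene_means`` (means of
    the training rows only); any absent block contributes width 0.
    """
    blocks = []
    n = None
    if embeddings is not None:
        emb = embeddings.values if hasattr(embeddings, "values") else np.asarray(embeddings)
        emb = np.asarray(emb, float)
        blocks.append(emb)
        n = emb.shape[0]
    if expr_selected is not None:
        expr = np.asarray(expr_selected, float)
        if training_gene_means is None:
            raise ValueError("training_gene_means required with an expression block")
        blocks.append(expr - np.asarray(training_gene_means, float)[None, :])
        n = expr.shape[0] if n is None else n
    if clinical is not None:
        clin = np.asarray(clinical, float)
        blocks.append(clin)
        n = clin.shape[0] if n is None else n
    if not blocks:
        raise ValueError("at least one feature block is required")
    if len({b.shape[0] for b in blocks}) != 1:
        raise ValueError("feature blocks disagree on sample count")
    return np.concatenate(blocks, axis=1)


def _risk_set_logsumexp(risk, time):
    """Per-event-anchor log of the risk-set sum, plus gradient plumbing."""
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    h = risk[order]
    n = len(time)
    last_of_tie = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        last_of_tie[i : j + 1] = j
        i = j + 1
    hmax = h.max() if n else 0.0
    cum = np.cumsum(np.exp(h - hmax))
    return order, last_of_tie, np.log(cum) + hmax, cum, hmax


def cox_partial_likelihood_loss(risk, time, event, reduction: str = "sum") -> float:
    """Negative Cox partial log-likelihood with ``t_j >= t_i`` risk sets.

    ``reduction="sum"`` (default) matches the printed loss; ``"mean"``
    divides by the number of events. Zero events yield 0 with a warning.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk scores must be finite")
    if event.sum() == 0:
        warnings.warn("no events: Cox loss has no informative terms")
        return 0.0
    order, last_of_tie, log_s0, _, _ = _risk_set_logsumexp(risk, time)
    ds = event[order].astype(bool)
    h = risk[order]
    terms = h[ds] - log_s0[last_of_tie[np.flatnonzero(ds)]]
    loss = -terms.sum()
    if reduction == "mean":
        loss /= event.sum()
    return float(loss)


def cox_loss_and_risk_gradient(risk, time, event, reduction: str = "sum"):
    """Loss plus d(loss)/d(risk) for backprop through the risk head."""
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(risk)
    if event.sum() == 0:
        return 0.0, np.zeros(n)
    order, last_of_tie, log_s0, cum, hmax = _risk_set_logsumexp(risk, time)
    ds = event[order].astype(bool)
    h = risk[order]
    anchors = np.flatnonzero(ds)
    anchor_end = last_of_tie[anchors]
    loss = -(h[anchors] - log_s0[anchor_end]).sum()
    # dl/dh_k (sorted) = -d_k + e^{h_k} * sum_{anchors with risk set covering k} 1/S0
    inv_s0 = np.exp(-(log_s0[anchor_end]))
    cover = np.zeros(n)
    np.add.at(cover, anchor_end, inv_s0)
    suffix = np.cumsum(cover[::-1])[::-1]  # sum over anchors with end >= k
    grad_sorted = -ds.astype(float) + np.exp(h) * suffix
    grad = np.empty(n)
    grad[order] = grad_sorted
    if reduction == "mean":
        loss /= event.sum()
        grad /= event.sum()
    return float(loss), grad


@dataclass
class EncoderContext:
    """Joint-training hookup: which fused columns come from the encoder
    and the masked expression each batch re-encodes."""

    encoder: MockEncoder
    masked_expr: np.ndarray  # all samples x vocab
    emb_slice: slice


@dataclass
class FitResult:
    model: RiskModel
    risks: pd.DataFrame  # columns: sample, cohort, split, risk
    selected_hparams: dict
    training_log: list
    selected_genes: dict | None = None
    encoder: MockEncoder | None = None
    config: PipelineConfig | None = None

    def risk_vector(self, part: str) -> pd.DataFrame:
        return self.risks[self.risks["split"] == part]


def _forward_rows(model, fused, rows, encoder_ctx, training, rng):
    X = fused[rows]
    enc_cache = None
    if encoder_ctx is not None:
        emb, enc_cache = encoder_ctx.encoder.forward(
            encoder_ctx.masked_expr[rows], cache=True
        )
        X = X.copy()
        X[:, encoder_ctx.emb_slice] = emb
    out, cache = model.net.forward(X, training=training, rng=rng)
    return out, cache, enc_cache


def _predict_rows(model, fused, rows, encoder_ctx):
    X = fused[rows]
    if encoder_ctx is not None:
        emb = encoder_ctx.encoder.forward(encoder_ctx.masked_expr[rows])
        X = X.copy()
        X[:, encoder_ctx.emb_slice] = emb
    return model.predict(X)


def train(model: RiskModel, fused, time, event, split: SplitAssignment,
          tc: TrainConfig, encoder_ctx: EncoderContext | None = None,
          train_batches=None):
    """Grid-searched AdamW optimization of the Cox loss.

    For each (lr, weight decay, clip norm) grid point the head (and any
    unfrozen encoder layers) is re-initialized, trained on the training
    rows with early stopping on the validation criterion, and the grid
    point and epoch with the best validation Harrell C (or lowest
    validation loss) is returned. Fully seeded: same config and data give
    identical selected weights. Grid points that diverge to a non-finite
    loss are marked failed and skipped.
    """
    fused = np.asarray(fused, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    train_rows = split.rows("train")
    val_rows = split.rows("val")
    if event[train_rows].sum() < 2:
        raise ValueError("training split must contain at least 2 events")
    if train_batches is None:
        train_batches = [train_rows]

    enc_init = (
        [p.copy() for p in encoder_ctx.encoder.trainable_parameters()]
        if encoder_ctx is not None
        else None
    )

    def val_criterion():
        r = _predict_rows(model, fused, val_rows, encoder_ctx)
        if tc.criterion == "harrell":
            c = harrell_cindex(r, time[val_rows], event[val_rows]).estimate
            return c if np.isfinite(c) else -np.inf
        return -cox_partial_likelihood_loss(r, time[val_rows], event[val_rows],
                                            tc.reduction)

    log = []
    best = None  # (crit, -grid_index) maximized
    grid_index = 0
    for lr in tc.lr_grid:
        for wd in tc.weight_decay_grid:
            for clip in tc.grad_norm_grid:
                model.reinitialize()
                if encoder_ctx is not None:
                    enc_params = encoder_ctx.encoder.trainable_parameters()
                    for p, p0 in zip(enc_params, enc_init):
                        p[...] = p0
                params = model.net.parameters() + (
                    encoder_ctx.encoder.trainable_parameters()
                    if encoder_ctx is not None
                    else []
                )
                opt = AdamW(params, lr=lr, weight_decay=wd)
                rng = np.random.default_rng(tc.seed)
                best_crit = -np.inf
                best_epoch = -1
                best_weights = None
                stall = 0
                failed = False
                for epoch in range(tc.max_epochs):
                    epoch_loss = 0.0
                    for rows in train_batches:
                        out, cache, enc_cache = _forward_rows(
                            model, fused, rows, encoder_ctx, True, rng
                        )
                        loss, d_risk = cox_loss_and_risk_gradient(
                            out, time[rows], event[rows], tc.reduction
                        )
                        epoch_loss += loss
                        if not np.isfinite(loss):
                            failed = True
                            break
                        if encoder_ctx is not None:
                            grads, dX = model.net.backward(
                                d_risk, cache, need_input_grad=True
                            )
                            grads = grads + encoder_ctx.encoder.backward(
                                dX[:, encoder_ctx.emb_slice], enc_cache
                            )
                        else:
                            grads = model.net.backward(d_risk, cache)
                        clip_global_norm(grads, clip)
                        opt.step(grads)
                    if failed:
                        break
                    crit = val_criterion()
                    if crit > best_crit:
                        best_crit = crit
                        best_epoch = epoch
                        best_weights = [p.copy() for p in params]
                        stall = 0
                    else:
                        stall += 1
                        if stall >= tc.patience:
                            break
                entry = {
                    "lr": lr,
                    "weight_decay": wd,
                    "grad_norm": clip,
                    "val_criterion": best_crit,
                    "best_epoch": best_epoch,
                    "failed": failed or best_weights is None,
                }
                log.append(entry)
                if not entry["failed"] and (
                    best is None or best_crit > best[0]
                ):
                    best = (best_crit, grid_index, [w.copy() for w in best_weights],
                            entry)
                grid_index += 1
    if best is None:
        raise RuntimeError("every hyperparameter grid point failed")
    _, _, weights, entry = best
    # restore the winning weights into model (+ encoder)
    n_model = len(model.net.parameters())
    model.net.set_parameters(weights[:n_model])
    if encoder_ctx is not None:
        for p, w in zip(encoder_ctx.encoder.trainable_parameters(),
                        weights[n_model:]):
            p[...] = w
    return model, {"selected": entry, "grid": log}


def pan_cancer_pool(cohorts: list, splits: list):
    """Concatenate already-split cohorts, preserving each sample's split
    and cohort label; duplicate sample identifiers are an error."""
    ids = pd.Index(np.concatenate([c.sample_ids for c in cohorts]))
    if ids.has_duplicates:
        raise ValueError("overlapping sample identifiers across cohorts")
    labels = np.concatenate([s.labels for s in splits])
    cohort_of = np.concatenate(
        [np.repeat(c.cohort_label, c.n_samples) for c in cohorts]
    )
    time = np.concatenate([c.time for c in cohorts])
    event = np.concatenate([c.event for c in cohorts])
    pooled_split = SplitAssignment(labels=labels, seed=splits[0].seed)
    return ids, cohort_of, time, event, pooled_split


# -- variant assembly ----------------------------------------------------


def _variant_blocks(variant: str) -> dict:
    v = variant.replace(" ", "")
    table = {
        "Embed": dict(emb=True, pool="all", expr=False, clin=False, pan=False),
        "Embed+Clin": dict(emb=True, pool="all", expr=False, clin=True, pan=False),
        "Embed-pan+Clin": dict(emb=True, pool="all", expr=False, clin=True, pan=True),
        "mRNA+Clin": dict(emb=False, pool=None, expr=True, clin=True, pan=False),
        "EGSP-pan": dict(emb=True, pool="max", expr=True, clin=True, pan=True),
        "EGSP": dict(emb=True, pool="max", expr=True, clin=True, pan=False),
    }
    if v not in table:
        raise ValueError(f"unknown variant {variant!r}; valid names: {list(VARIANTS)}")
    return table[v]


def _prepare_cohort(cohort: SurvivalCohort, pc: PipelineConfig, spec: dict,
                    split: SplitAssignment | None, vocab=None):
    """Per-cohort preprocessing: normalize, align, screen on train rows,
    select top-Ng, mask; returns the pieces variant assembly needs."""
    if split is None:
        split = stratified_split(cohort.event, seed=pc.seed)
    norm = preprocess.normalize_expression(cohort.expression, pc.target_sum)
    if vocab is None:
        vocab = preprocess.GeneVocabulary(tuple(cohort.expression.columns))
    aligned = preprocess.align_to_vocabulary(norm, norm.columns, vocab)
    tr = split.rows("train")
    screen = preprocess.univariate_cox_screen(
        aligned.iloc[tr], cohort.time[tr], cohort.event[tr]
    )
    selected = preprocess.select_top_genes(screen, min(pc.Ng, vocab.size))
    masked = preprocess.mask_nonselected(aligned, selected)
    expr_sel = aligned.to_numpy()[:, selected] if spec["expr"] else None
    gene_means = expr_sel[tr].mean(axis=0) if spec["expr"] else None
    clin = encode_clinical(cohort.clinical, tr) if spec["clin"] else None
    return dict(split=split, vocab=vocab, masked=masked.to_numpy(),
                expr_sel=expr_sel, gene_means=gene_means, clin=clin,
                selected=selected, screen=screen)


def fit_variant(cohorts, variant: str, pc: PipelineConfig | None = None,
                tc: TrainConfig | None = None, splits=None) -> FitResult:
    """Fit one of the six model variants end to end.

    ``cohorts`` is one cohort or a list (pan variants require a list);
    splits may be supplied, otherwise censoring-stratified 70/15/15
    splits are drawn from the pipeline seed. Returns per-sample risk
    scores for all three splits together with the fitted model.
    """
    spec = _variant_blocks(variant)
    if pc is None:
        pc = PipelineConfig(variant=variant)
    pc = replace(pc, variant=variant)
    if tc is None:
        tc = TrainConfig(seed=pc.seed)
    single = isinstance(cohorts, SurvivalCohort)
    cohort_list = [cohorts] if single else list(cohorts)
    if spec["pan"] and len(cohort_list) < 2:
        logger.warning("pan variant fitted on a single cohort")
    if splits is None:
        splits = [None] * len(cohort_list)

    # one shared vocabulary (the encoder's fixed input width); gene
    # screening and selection stay per-cohort
    vocab = preprocess.GeneVocabulary(tuple(cohort_list[0].expression.columns))
    prepped = []
    for cohort, split in zip(cohort_list, splits):
        prep = _prepare_cohort(cohort, pc, spec, split, vocab=vocab)
        prepped.append(prep)

    enc = None
    emb_blocks = None
    if spec["emb"]:
        enc_cfg = pc.encoder
        if enc_cfg is None:
            enc_cfg = EncoderConfig(
                vocab_size=prepped[0]["vocab"].size, pool_type=spec["pool"],
                seed=pc.seed,
            )
        if enc_cfg.pool_type != spec["pool"]:
            enc_cfg = replace(enc_cfg, pool_type=spec["pool"])
        enc = init_mock_encoder(enc_cfg)
        if spec["pan"]:
            enc.set_unfrozen_layers(pc.Nu)

    masked_all = np.concatenate([p["masked"] for p in prepped], axis=0)
    if spec["emb"]:
        emb_blocks = enc.forward(masked_all)

    # row-wise assembly across cohorts (clinical width must agree)
    offsets = np.cumsum([0] + [c.n_samples for c in cohort_list])
    expr_all = (
        np.concatenate(
            [p["expr_sel"] - p["gene_means"][None, :] for p in prepped], axis=0
        )
        if spec["expr"]
        else None
    )
    clin_all = (
        np.concatenate([p["clin"] for p in prepped], axis=0) if spec["clin"] else None
    )
    if spec["clin"] and len({p["clin"].shape[1] for p in prepped}) != 1:
        raise ValueError("cohorts disagree on clinical width (Nc)")

    blocks = []
    emb_slice = None
    col = 0
    if spec["emb"]:
        emb_slice = slice(col, col + emb_blocks.shape[1])
        blocks.append(emb_blocks)
        col += emb_blocks.shape[1]
    if expr_all is not None:
        blocks.append(expr_all)
        col += expr_all.shape[1]
    if clin_all is not None:
        blocks.append(clin_all)
        col += clin_all.shape[1]
    fused = np.concatenate(blocks, axis=1)

    ids, cohort_of, time, event, pooled_split = pan_cancer_pool(
        cohort_list, [p["split"] for p in prepped]
    )

    model = RiskModel(fused.shape[1], head_widths=pc.head_widths,
                      dropout=pc.dropout, seed=pc.seed)
    encoder_ctx = None
    train_batches = None
    if spec["pan"] and spec["emb"] and pc.Nu > 0:
        encoder_ctx = EncoderContext(encoder=enc, masked_expr=masked_all,
                                     emb_slice=emb_slice)
        # batches stay within cohorts so risk sets never straddle cohorts
        train_batches = [
            np.intersect1d(pooled_split.rows("train"),
                           np.arange(offsets[k], offsets[k + 1]))
            for k in range(len(cohort_list))
        ]
        train_batches = [b for b in train_batches if len(b)]
    model, log = train(model, fused, time, event, pooled_split, tc,
                       encoder_ctx=encoder_ctx, train_batches=train_batches)

    if encoder_ctx is not None:
        fused = fused.copy()
        fused[:, emb_slice] = enc.forward(masked_all)
    risks = pd.DataFrame(
        {
            "sample": ids,
            "cohort": cohort_of,
            "split": pooled_split.labels,
            "risk": model.predict(fused),
        }
    )
    return FitResult(
        model=model,
        risks=risks,
        selected_hparams=log["selected"],
        training_log=log["grid"],
        selected_genes={
            c.cohort_label: p["selected"] for c, p in zip(cohort_list, prepped)
        },
        encoder=enc,
        config=pc,
    )
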