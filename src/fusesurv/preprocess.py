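"""Expression normalization, vocabulary alignment, and Cox gene screening.

The screening step ranks genes by the Wald p-value of a univariate Cox
proportional-hazards fit (Breslow partial likelihood, Newton-Raphson),
computed on training samples only; the top-``Ng`` genes by smallest
p-value are retained and every other gene is masked to zero before the
expression profile is handed to the encoder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneVocabulary",
    "CoxScreenResult",
    "normalize_expression",
    "align_to_vocabulary",
    "univariate_cox_screen",
    "select_top_genes",
    "mask_nonselected",
]


@dataclass(frozen=True)
class GeneVocabulary:
    """Fixed ordered gene universe the encoder expects as input."""

    gene_ids: tuple

    def __post_init__(self):
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("vocabulary gene identifiers must be unique")

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class CoxScreenResult:
    """Per-gene univariate Cox screen: coefficient, SE, Wald z, p, flag."""

    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: np.ndarray
    gene_ids: tuple | None = None

    def to_frame(self) -> pd.DataFrame:
        idx = self.gene_ids if self.gene_ids is not None else range(len(self.p))
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "z": self.z,
                "p": self.p,
                "converged": self.converged,
            },
            index=pd.Index(idx, name="gene"),
        )


def normalize_expression(counts, target_sum: float = 10_000.0):
    """Library-size normalize each sample to ``target_sum``, then log1p.

    Raises if any sample has zero total counts (the sample is named in the
    message). Accepts an array or DataFrame; returns the same container
    type.
    """
    values = np.asarray(counts, dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        idx = np.flatnonzero(totals == 0)
        if isinstance(counts, pd.DataFrame):
            names = list(counts.index[idx])
        else:
            names = list(idx)
        raise ValueError(f"samples with zero total counts: {names}")
    out = np.log1p(values * (target_sum / totals[:, None]))
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def align_to_vocabulary(expr, genes, vocab: GeneVocabulary):
    """Reindex ``expr`` columns to the vocabulary order.

    Genes absent from ``expr`` become zero columns; genes absent from the
    vocabulary are dropped (count logged). Duplicate gene labels are an
    error.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene labels in expression matrix")
    df = (
        expr
        if isinstance(expr, pd.DataFrame)
        else pd.DataFrame(np.asarray(expr, float))
    )
    df = pd.DataFrame(df.to_numpy(float), index=df.index, columns=genes)
    dropped = len(set(genes) - set(vocab.gene_ids))
    if dropped:
        logger.info("align_to_vocabulary: dropped %d genes not in vocabulary", dropped)
    out = df.reindex(columns=list(vocab.gene_ids), fill_value=0.0)
    return out


def _risk_set_reduction(time: np.ndarray):
    """Sort order and segment bookkeeping for Breslow risk sets.

    Returns (order, event_rows, risk_index) where samples are sorted by
    descending time; ``risk_index[i]`` is the last sorted position whose
    time still satisfies ``t_j >= t_i`` (ties share the full risk set).
    """
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    # for each position, last index with the same time (ties included)
    n = len(time)
    last_of_tie = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        last_of_tie[i : j + 1] = j
        i = j + 1
    return order, t_sorted, last_of_tie


def univariate_cox_screen(
    expr,
    time,
    event,
    max_iter: int = 50,
    tol: float = 1e-9,
    p_method: str = "wald",
) -> CoxScreenResult:
    """Screen each gene with a single-covariate Cox PH fit.

    Newton-Raphson on the Breslow partial log-likelihood, vectorized over
    genes. Wald p = 2 * Phi(-|beta/se|); ``p_method="lrt"`` replaces it
    with the likelihood-ratio chi-square p. Constant or non-convergent
    genes are flagged and assigned p = 1 so index bookkeeping stays
    stable.
    """
    if p_method not in ("wald", "lrt"):
        raise ValueError("p_method must be 'wald' or 'lrt'")
    gene_ids = tuple(expr.columns) if isinstance(expr, pd.DataFrame) else None
    X = np.asarray(expr, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, g = X.shape
    if event.sum() < 2:
        raise ValueError("univariate Cox screen requires at least 2 events")

    order, _, last_of_tie = _risk_set_reduction(time)
    Xs = X[order]
    ds = event[order].astype(bool)
    # standardize covariates for numerical stability; beta rescaled after
    mean = Xs.mean(axis=0)
    sd = Xs.std(axis=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = (Xs - mean) / sd_safe

    beta = np.zeros(g)
    active = ~degenerate
    event_rows = np.flatnonzero(ds)
    risk_end = last_of_tie[event_rows]  # risk set = sorted rows [0 .. risk_end]

    def loglik_grad_hess(b):
        # e: n x g weights; cumulative sums along descending time give
        # risk-set aggregates S0, S1, S2 at each event anchor
        eta = Z * b[None, :]
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        S0 = np.cumsum(w, axis=0)[risk_end]
        S1 = np.cumsum(w * Z, axis=0)[risk_end]
        S2 = np.cumsum(w * Z * Z, axis=0)[risk_end]
        xe = Z[event_rows]
        ll = np.sum(eta[event_rows] - np.log(S0), axis=0)
        grad = np.sum(xe - S1 / S0, axis=0)
        hess = -np.sum(S2 / S0 - (S1 / S0) ** 2, axis=0)
        return ll, grad, hess

    ll0, _, _ = loglik_grad_hess(np.zeros(g))
    converged = np.zeros(g, dtype=bool)
    ll_cur, grad, hess = loglik_grad_hess(beta)
    for _ in range(max_iter):
        if not active.any():
            break
        step = np.zeros(g)
        ok = active & (hess < -1e-12)
        step[ok] = -grad[ok] / hess[ok]
        step = np.clip(step, -2.0, 2.0)  # damp huge Newton steps
        beta_new = beta + step
        newly = active & (np.abs(step) < tol)
        converged |= newly
        active &= ~newly
        beta = np.where(active, beta_new, beta)
        # genes whose Hessian degenerated (separation) stop iterating
        stuck = active & ~ok
        active &= ~stuck
        if not active.any():
            break
        ll_cur, grad, hess = loglik_grad_hess(beta)

    ll_fit, _, hess = loglik_grad_hess(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_z = np.sqrt(-1.0 / hess)
    bad = degenerate | ~converged | ~np.isfinite(se_z) | (np.abs(beta) > 50)
    converged = converged & ~bad

    beta_raw = beta / sd_safe
    se_raw = se_z / sd_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se_z  # scale-invariant Wald z
    if p_method == "wald":
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        lr = 2.0 * (ll_fit - ll0)
        p = stats.chi2.sf(np.maximum(lr, 0.0), df=1)
    p = np.where(converged, p, 1.0)
    z = np.where(converged, z, 0.0)
    beta_raw = np.where(converged, beta_raw, 0.0)
    se_raw = np.where(converged, se_raw, np.inf)
    return CoxScreenResult(
        beta=beta_raw, se=se_raw, z=z, p=p, converged=converged, gene_ids=gene_ids
    )


def select_top_genes(screen: CoxScreenResult, Ng: int) -> np.ndarray:
    """Indices of the ``Ng`` smallest screen p-values.

    Ties broken by ascending vocabulary index; asking for more genes than
    screened returns everything with a warning.
    """
    if Ng < 1:
        raise ValueError("Ng must be >= 1")
    g = len(screen.p)
    if Ng > g:
        warnings.warn(f"Ng={Ng} exceeds the {g} screened genes; returning all")
        Ng = g
    order = np.lexsort((np.arange(g), screen.p))
    return order[:Ng]


def mask_nonselected(expr_vocab, selected) -> np.ndarray | pd.DataFrame:
    """Zero every column not in ``selected``; shape and order preserved."""
    values = np.asarray(expr_vocab, dtype=float)
    selected = np.asarray(selected, dtype=int)
    if selected.size and (selected.min() < 0 or selected.max() >= values.shape[1]):
        raise IndexError("selected indices outside vocabulary")
    mask = np.zeros(values.shape[1], dtype=bool)
    mask[selected] = True
    out = values * mask[None, :]
    if isinstance(expr_vocab, pd.DataFrame):
        return pd.DataFrame(out, index=expr_vocab.index, columns=expr_vocab.columns)
    return out
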