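"""Mutual-information redundancy between embeddings and gene expression.

MI is the plug-in estimate ``I(X;Y) = sum p(x,y) log[p(x,y)/(p(x)p(y))]``
(natural log, nats) on equal-frequency discretized features. "Risk"
embedding dimensions are those with univariate Cox p < .05; a risk
embedding is "non-redundant" when its MI with every other embedding
dimension and every gene stays below a threshold (0.3 nats by default,
on the same scale as typical embedding-gene MI values of ~0.23-0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import univariate_cox_screen

__all__ = [
    "DiscretizationConfig",
    "MIEstimate",
    "RiskEmbeddingSet",
    "discretize",
    "mutual_information",
    "identify_risk_features",
    "identify_nonredundant",
    "summarize_redundancy",
]


@dataclass(frozen=True)
class DiscretizationConfig:
    """Equal-frequency binning; default bin count ``floor(n ** (1/3))``
    (integer truncation of the cube root, as in the classic discretized
    MI estimators)."""

    n_bins: int | None = None  # None -> cube-root rule

    def bins_for(self, n: int) -> int:
        k = self.n_bins if self.n_bins is not None else int(n ** (1.0 / 3.0))
        return max(k, 2)


@dataclass
class MIEstimate:
    value: float  # nats
    pair: tuple
    n: int


def discretize(x, config: DiscretizationConfig = DiscretizationConfig()) -> np.ndarray:
    """Equal-frequency integer codes; ties go to the lower bin.

    A constant vector collapses to a single bin with a warning.
    """
    x = np.asarray(x, float)
    n = len(x)
    if np.all(x == x[0]):
        warnings.warn("constant vector: single discretization bin")
        return np.zeros(n, dtype=int)
    k = config.bins_for(n)
    if n < k:
        raise ValueError(f"need at least n_bins={k} observations, got {n}")
    edges = np.quantile(x, np.arange(1, k) / k)
    # side="left": values equal to an edge fall in the lower bin
    return np.searchsorted(edges, x, side="left")


def mutual_information(x, y, config: DiscretizationConfig = DiscretizationConfig(),
                       discrete: bool = False) -> MIEstimate:
    """Plug-in MI (nats) of the empirical joint table of discretized x, y."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("x and y must be aligned")
    if not discrete:
        cx = discretize(x, config)
        cy = discretize(y, config)
    else:
        cx, cy = x.astype(int), y.astype(int)
    joint = pd.crosstab(cx, cy).to_numpy(float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    terms = p[nz] * np.log(p[nz] / (px @ py)[nz])
    # summation in sorted order keeps I(X;Y) == I(Y;X) bit-exact
    mi = float(np.sum(np.sort(terms.ravel())))
    return MIEstimate(value=max(mi, 0.0), pair=("x", "y"), n=len(x))


def identify_risk_features(features, time, event, alpha: float = 0.05) -> np.ndarray:
    """Indices of feature columns with univariate Cox p < alpha."""
    screen = univariate_cox_screen(features, time, event)
    return np.flatnonzero(screen.p < alpha)


def identify_nonredundant(risk_idx, embeddings, genes=None, threshold: float = 0.3,
                          config: DiscretizationConfig = DiscretizationConfig()) -> np.ndarray:
    """Risk embedding dimensions whose MI with *every* other embedding
    dimension and every gene stays below ``threshold``."""
    embeddings = np.asarray(embeddings, float)
    risk_idx = np.asarray(risk_idx, dtype=int)
    n, d = embeddings.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb_codes = [discretize(embeddings[:, j], config) for j in range(d)]
        gene_codes = (
            [discretize(np.asarray(genes, float)[:, j], config)
             for j in range(np.asarray(genes).shape[1])]
            if genes is not None
            else []
        )
    keep = []
    for j in risk_idx:
        redundant = False
        for k in range(d):
            if k == j:
                continue
            if mutual_information(emb_codes[j], emb_codes[k], discrete=True).value >= threshold:
                redundant = True
                break
        if not redundant:
            for gc in gene_codes:
                if mutual_information(emb_codes[j], gc, discrete=True).value >= threshold:
                    redundant = True
                    break
        if not redundant:
            keep.append(j)
    return np.asarray(keep, dtype=int)


@dataclass
class RiskEmbeddingSet:
    """Risk (Cox p < alpha) and non-redundant (MI below threshold)
    embedding indices for one cohort."""

    risk_indices: np.ndarray
    nonredundant_indices: np.ndarray

    def __post_init__(self):
        if not set(self.nonredundant_indices).issubset(set(self.risk_indices)):
            raise ValueError("non-redundant indices must be a subset of risk indices")

    @property
    def n_risk(self) -> int:
        return len(self.risk_indices)

    @property
    def n_nonredundant(self) -> int:
        return len(self.nonredundant_indices)


def summarize_redundancy(mi_by_cohort: dict, cindex_by_cohort: dict) -> pd.DataFrame:
    """Per-cohort contrast of two embedding sets (e.g. frozen vs pan-tuned).

    ``mi_by_cohort[cohort] = (mi_set_a, mi_set_b)`` and likewise for the
    C-indices; a cohort is flagged concordant when the lower-MI set also
    has the higher C-index. The aggregate concordant fraction is stored
    in ``df.attrs["concordant_fraction"]``.
    """
    rows = []
    for cohort, (mi_a, mi_b) in mi_by_cohort.items():
        if cohort not in cindex_by_cohort:
            raise ValueError(f"cohort {cohort!r} missing from C-index input")
        c_a, c_b = cindex_by_cohort[cohort]
        d_mi = mi_a - mi_b
        d_c = c_a - c_b
        rows.append(
            {
                "cohort": cohort,
                "mi_a": mi_a,
                "mi_b": mi_b,
                "delta_mi": d_mi,
                "delta_c": d_c,
                "concordant": bool(d_mi * d_c < 0 or (d_mi == 0 and d_c == 0)),
            }
        )
    extra = set(cindex_by_cohort) - set(mi_by_cohort)
    if extra:
        raise ValueError(f"cohorts missing from MI input: {sorted(extra)}")
    df = pd.DataFrame(rows)
    df.attrs["concordant_fraction"] = float(df["concordant"].mean()) if len(df) else np.nan
    return df
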