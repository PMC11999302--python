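"""Tier-4 fallback: a variance-proportion-weighted principal-component index.

When a whole vulnerability dimension has no data, the domain/dimension
hierarchy cannot support an SVI.  The fallback builds a composite over
whatever indicators exist: eigendecompose their correlation matrix, weight
each (sign-oriented) component score by the proportion of total variance it
explains, and sum over the retained components.  Multicollinear indicators
then share influence through a common component instead of each pulling the
index separately.  The output is explicitly flagged as *not* a Social
Vulnerability Index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DegenerateColumnError, SviError
from .normalize import ZScoreMatrix
from .weighting import ScoreTable

__all__ = [
    "PCADecomposition",
    "correlation_matrix",
    "pca_decompose",
    "pca_index",
    "NOT_AN_SVI_FLAG",
]

NOT_AN_SVI_FLAG = (
    "not a Social Vulnerability Index (tier 4): variance-weighted "
    "principal-component composite over available indicators"
)


@dataclass(frozen=True)
class PCADecomposition:
    loadings: pd.DataFrame  # indicator × component
    variance_proportions: np.ndarray  # per component, sums to 1
    component_scores: pd.DataFrame  # area × component
    retained: tuple[int, ...]


def _check_matrix(z: ZScoreMatrix) -> pd.DataFrame:
    df = z.df
    if df.shape[1] < 2:
        raise SviError("principal-component index needs at least 2 indicators")
    if df.shape[0] < 3:
        raise SviError("principal-component index needs at least 3 areas")
    if df.isna().any().any():
        raise ConsistencyError(
            "z-score matrix has missing cells; impute before the PCA path"
        )
    for col in df.columns:
        if float(df[col].std(ddof=1)) == 0.0:
            raise DegenerateColumnError(f"indicator {col!r} is constant")
    return df


def correlation_matrix(z: ZScoreMatrix) -> pd.DataFrame:
    """Pearson correlation matrix of the aligned indicators (symmetric, unit
    diagonal, entries in [−1, 1])."""
    df = _check_matrix(z)
    corr = np.corrcoef(df.to_numpy(), rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)


def pca_decompose(
    z: ZScoreMatrix, *, variance_target: float = 0.80, retain_all: bool = False
) -> PCADecomposition:
    """Eigendecomposition of the indicator correlation matrix.

    Components are ordered by decreasing eigenvalue; the variance proportion
    of component k is λ_k / p (p = number of indicators, the trace of the
    correlation matrix).  Retention keeps the smallest leading set whose
    cumulative variance proportion reaches ``variance_target`` (all
    components when ``retain_all``).  Each component's sign is oriented so
    its loadings sum to a non-negative value (first nonzero loading positive
    on a tie), making the index direction deterministic.
    """
    df = _check_matrix(z)
    corr = correlation_matrix(z).to_numpy()
    try:
        eigvals, eigvecs = np.linalg.eigh(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise SviError(f"eigendecomposition failed: {exc}")
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    p = df.shape[1]
    props = eigvals / p
    # deterministic sign orientation
    for k in range(p):
        s = eigvecs[:, k].sum()
        if s < 0:
            eigvecs[:, k] = -eigvecs[:, k]
        elif s == 0:
            nz = np.nonzero(eigvecs[:, k])[0]
            if nz.size and eigvecs[nz[0], k] < 0:
                eigvecs[:, k] = -eigvecs[:, k]
    scores = df.to_numpy() @ eigvecs
    comp_names = [f"PC{k + 1}" for k in range(p)]
    if retain_all:
        retained = tuple(range(p))
    else:
        cum = np.cumsum(props)
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        retained = tuple(range(min(k, p)))
    return PCADecomposition(
        loadings=pd.DataFrame(eigvecs, index=df.columns, columns=comp_names),
        variance_proportions=props,
        component_scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
        retained=retained,
    )


def pca_index(
    z: ZScoreMatrix, decomposition: PCADecomposition, *, normalize: bool = False
) -> ScoreTable:
    """Composite score: Σ_k variance_proportion_k · component_score_k over the
    retained components (divided by the retained proportions' sum when
    ``normalize`` — a weighted mean; rankings are identical either way)."""
    d = decomposition
    if list(d.component_scores.index) != list(z.df.index):
        raise ConsistencyError(
            "decomposition was computed for a different set of areas"
        )
    w = d.variance_proportions[list(d.retained)]
    cols = [d.component_scores.columns[k] for k in d.retained]
    svi = pd.Series(
        d.component_scores[cols].to_numpy() @ w, index=z.df.index, name="svi"
    )
    if normalize:
        total = w.sum()
        if total > 0:
            svi = svi / total
    return ScoreTable(
        domain_scores=pd.DataFrame(index=z.df.index),
        svi=svi,
        contributing_weights=None,
        flags=(NOT_AN_SVI_FLAG,),
    )
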