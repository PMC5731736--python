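"""Principal component analysis of the cells x predictors z-score matrix.

Mapping the per-cell regression z-scores onto their leading principal
components reveals which combinations of seasonal climate variables dominate
spatial variation in the drivers of burned area.  Components are computed as
a singular value decomposition of the column-standardized matrix, which is
the eigendecomposition of the correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DriverComponents:
    """PCA decomposition of a z-score matrix.

    ``loadings``: predictors x components (orthonormal columns);
    ``scores``: cells x components (indexed by cell id);
    ``explained_pct``: percent of total variance per component (sums to 100);
    ``n_dropped``: cells removed for missing entries.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_pct: np.ndarray
    n_dropped: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca_zscores(Z: pd.DataFrame) -> DriverComponents:
    """PCA of a cells x predictors z-score matrix via SVD.

    Columns are standardized to zero mean / unit variance over cells (so the
    decomposition is of the correlation matrix); cells with any missing
    entry are dropped.  Each component is oriented so its largest-|loading|
    predictor loads positively.
    """
    if Z.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    complete = Z.dropna()
    n_dropped = len(Z) - len(complete)
    X = complete.to_numpy(dtype=float)
    n, k = X.shape
    if n < k:
        import warnings
        warnings.warn(f"fewer complete cells ({n}) than predictors ({k})")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = complete.columns[np.flatnonzero(sd == 0)].tolist()
        raise ValueError(f"constant z-score column(s): {bad}")
    Xs = (X - X.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    eig = s**2 / (n - 1)
    pct = eig / eig.sum() * 100.0
    loadings = vt.T
    scores = u * s
    # deterministic sign: dominant predictor of each component loads positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return DriverComponents(
        loadings=pd.DataFrame(loadings, index=complete.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=complete.index, columns=comp_names),
        explained_pct=pct,
        n_dropped=n_dropped,
    )


def label_components(components: DriverComponents, Z: pd.DataFrame,
                     threshold: float = 0.5,
                     n_components: int | None = None) -> dict[str, list[tuple[str, int]]]:
    """Label each component by the predictors correlated with its cell scores.

    For each component, predictors whose z-score column correlates with the
    component's cell scores at |r| >= ``threshold`` are listed as
    (name, sign) pairs, strongest first.
    """
    complete = Z.dropna().loc[components.scores.index]
    labels: dict[str, list[tuple[str, int]]] = {}
    comps = components.scores.columns[:n_components] if n_components else components.scores.columns
    for comp in comps:
        sc = components.scores[comp].to_numpy()
        entries = []
        for name in complete.columns:
            col = complete[name].to_numpy(dtype=float)
            if np.std(col) == 0 or np.std(sc) == 0:
                continue
            r = float(np.corrcoef(col, sc)[0, 1])
            if abs(r) >= threshold:
                entries.append((name, 1 if r > 0 else -1, abs(r)))
        entries.sort(key=lambda e: -e[2])
        labels[comp] = [(nm, sign) for nm, sign, _ in entries]
    return labels
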