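"""Composite principal-component traits from the line-mean trait matrix.

PCA is performed on the Pearson correlation matrix (i.e. on standardized
traits), so eigenvalues sum to the number of traits and the Kaiser rule
(retain components with eigenvalue >= 1) applies. Retained component scores
are used downstream as additional mapping phenotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class KernelTraitPCA:
    """Correlation-matrix PCA over a set of trait columns.

    Parameters
    ----------
    traits : list of str, optional
        Trait columns to use; default = every non-identifier column passed to
        :meth:`fit`.
    kaiser_threshold : float
        Minimum eigenvalue for a component to be retained (default 1.0).

    Attributes (after ``fit``)
    ----------
    traits_ : list of str
    mean_, scale_ : per-trait standardization mean and SD (ddof=1)
    eigenvalues_ : descending eigenvalues of the correlation matrix
    loadings_ : (n_traits, n_traits) array, column j = eigenvector j, with the
        sign fixed so the largest-magnitude loading is positive
    explained_variance_ratio_ : eigenvalue / n_traits
    retained_ : indices of components with eigenvalue >= kaiser_threshold
    n_retained_ : len(retained_)
    """

    def __init__(self, traits: list[str] | None = None, kaiser_threshold: float = 1.0):
        self.traits = traits
        self.kaiser_threshold = kaiser_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"traits": self.traits, "kaiser_threshold": self.kaiser_threshold}

    def set_params(self, **params) -> "KernelTraitPCA":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _trait_matrix(self, means: pd.DataFrame, traits: list[str]) -> np.ndarray:
        X = means[traits].to_numpy(float)
        if np.isnan(X).any():
            X = X[~np.isnan(X).any(axis=1)]
        return X

    def fit(self, means: pd.DataFrame, y=None) -> "KernelTraitPCA":
        traits = self.traits or [
            c for c in means.columns if c not in ("line_id", "population")
        ]
        if len(traits) < 2:
            raise ValueError("PCA needs at least 2 traits")
        X = self._trait_matrix(means, traits)
        if X.shape[0] <= len(traits):
            raise ValueError("need more lines than traits")
        sd = X.std(axis=0, ddof=1)
        const = np.flatnonzero(sd == 0)
        if const.size:
            raise ValueError(f"constant trait: {traits[const[0]]!r}")
        self.traits_ = list(traits)
        self.mean_ = X.mean(axis=0)
        self.scale_ = sd
        corr = np.corrcoef(X, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # eigenvector sign is arbitrary; fix largest-|loading| positive
        for j in range(evecs.shape[1]):
            k = np.argmax(np.abs(evecs[:, j]))
            if evecs[k, j] < 0:
                evecs[:, j] = -evecs[:, j]
        self.eigenvalues_ = np.clip(evals, 0.0, None)
        self.loadings_ = evecs
        self.explained_variance_ratio_ = self.eigenvalues_ / len(traits)
        self.retained_ = [int(j) for j, ev in enumerate(self.eigenvalues_)
                          if ev >= self.kaiser_threshold]
        self.n_retained_ = len(self.retained_)
        return self

    def transform(self, means: pd.DataFrame, components: str = "retained") -> pd.DataFrame:
        """Score lines on the fitted components.

        Lines with a missing input trait get missing scores. ``components``
        is ``"retained"`` (default) or ``"all"``.
        """
        X = means[self.traits_].to_numpy(float)
        Z = (X - self.mean_) / self.scale_
        S = Z @ self.loadings_
        cols = self.retained_ if components == "retained" else range(S.shape[1])
        out = means[[c for c in ("line_id", "population") if c in means.columns]].copy()
        for rank, j in enumerate(cols, start=1):
            out[f"PC{rank}"] = S[:, j]
        return out

    def fit_transform(self, means: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(means).transform(means)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings_, index=self.traits_,
            columns=[f"PC{j + 1}" for j in range(len(self.traits_))],
        )

    def scree_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": [f"PC{j + 1}" for j in range(len(self.eigenvalues_))],
            "eigenvalue": self.eigenvalues_,
            "variance_explained": self.explained_variance_ratio_,
            "retained": [j in self.retained_ for j in range(len(self.eigenvalues_))],
        })


def fit_pca(means: pd.DataFrame, traits: list[str] | None = None) -> KernelTraitPCA:
    return KernelTraitPCA(traits=traits).fit(means)


def retain_components(model: KernelTraitPCA) -> list[int]:
    """Kaiser rule: component indices with eigenvalue >= 1, in order."""
    return list(model.retained_)


def score_lines(model: KernelTraitPCA, means: pd.DataFrame) -> pd.DataFrame:
    """Line means augmented with retained PC scores."""
    scores = model.transform(means)
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    out = means.copy()
    for c in pc_cols:
        out[c] = scores[c].to_numpy()
    return out
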