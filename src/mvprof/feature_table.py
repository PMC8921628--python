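"""The variant × score matrix: named feature groups, imputation, embedding.

Features come in two groups: *functional* assay readouts (yeast promoter
transactivation on eight promoters plus their average and median, a
cell-cycle-arrest screen covering only the DNA-binding domain, and three
mammalian-screen readouts — 14 in total) and *computational* predictor
outputs (28 by default).  Missing values — typically domain-restricted, as
an assay measured only inside a codon interval — are filled with the
per-feature median.  Features are used untransformed: the downstream tree
ensembles are scale-invariant, so no standardization is applied.

A classical (Torgerson) multidimensional scaling of the pairwise Euclidean
distances provides the two-dimensional representativeness check: training
variants should disperse evenly among the unlabeled remainder of the
variant space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

FeatureGroup = Literal["functional", "computational"]


@dataclass(frozen=True)
class FeatureSpec:
    """Metadata for one score column."""

    name: str
    group: FeatureGroup
    source: str = ""
    higher_is_deleterious: bool | None = None


@dataclass
class FeatureMatrix:
    """Variants × features with a missingness mask and group metadata."""

    values: pd.DataFrame
    specs: list[FeatureSpec]
    mask: pd.DataFrame = None  # True where the value was observed

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if list(self.values.columns) != names:
            raise ValueError("value columns must match feature specs in order")
        if self.mask is None:
            self.mask = self.values.notna()

    @property
    def variants(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def group_names(self, group: FeatureGroup) -> list[str]:
        return [s.name for s in self.specs if s.group == group]

    @property
    def is_complete(self) -> bool:
        return not self.values.isna().any().any()


def impute_median(
    m: FeatureMatrix, fit_on: Sequence[str] | Literal["all"] = "all"
) -> FeatureMatrix:
    """Fill missing cells with per-feature medians.

    Medians are computed over ``fit_on`` (default: every variant, matching
    whole-table imputation; pass the training keys to avoid train→test
    leakage).  Observed entries are never altered and the original mask is
    retained for audit.
    """
    imp = MedianImputer(fit_on=fit_on)
    return imp.fit_transform_matrix(m)


class MedianImputer(BaseEstimator, TransformerMixin):
    """Per-feature median imputation, sklearn-style.

    Parameters
    ----------
    fit_on : "all" or sequence of index keys
        Rows used to compute the medians when transforming a
        :class:`FeatureMatrix`; plain-array usage fits on all rows given
        to :meth:`fit`.
    """

    def __init__(self, fit_on: Sequence[str] | Literal["all"] = "all"):
        self.fit_on = fit_on

    def fit(self, X: pd.DataFrame, y=None) -> "MedianImputer":
        X = pd.DataFrame(X)
        medians = X.median(axis=0, skipna=True)
        empty = medians[medians.isna()]
        if len(empty):
            raise ValueError(
                "feature(s) entirely missing in the fitting rows: "
                f"{list(empty.index)}"
            )
        self.medians_ = medians
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "medians_")
        X = pd.DataFrame(X)
        return X.fillna(self.medians_)

    def fit_transform_matrix(self, m: FeatureMatrix) -> FeatureMatrix:
        rows = m.values if self.fit_on == "all" else m.values.loc[list(self.fit_on)]
        self.fit(rows)
        return FeatureMatrix(self.transform(m.values), list(m.specs), m.mask.copy())


def select_features(
    m: FeatureMatrix, set_id: Literal["all", "functional", "computational"]
) -> FeatureMatrix:
    """Column-subset by feature group; group metadata is preserved."""
    if set_id == "all":
        return FeatureMatrix(m.values.copy(), list(m.specs), m.mask.copy())
    if set_id not in ("functional", "computational"):
        raise ValueError(f"unknown feature set {set_id!r}")
    specs = [s for s in m.specs if s.group == set_id]
    cols = [s.name for s in specs]
    return FeatureMatrix(m.values[cols].copy(), specs, m.mask[cols].copy())


class ClassicalMDS(BaseEstimator, TransformerMixin):
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared Euclidean distance matrix,
    B = -1/2 · J D² J, and embeds on the top eigenvectors scaled by the
    square roots of the eigenvalues.  For Euclidean input this equals PCA
    scores of the centered data and is deterministic up to sign.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 3:
            raise ValueError("classical MDS needs at least 3 points")
        d2 = squareform(pdist(X, metric="euclidean")) ** 2
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        # symmetric eigendecomposition, descending
        vals, vecs = np.linalg.eigh((b + b.T) / 2)
        order = np.argsort(vals)[::-1][: self.n_components]
        lam = np.clip(vals[order], 0.0, None)
        self.eigenvalues_ = vals[np.argsort(vals)[::-1]]
        coords = vecs[:, order] * np.sqrt(lam)
        self.embedding_ = coords
        return coords


def mds_embed(m: FeatureMatrix) -> pd.DataFrame:
    """2-D classical MDS embedding of an imputed feature matrix."""
    if not m.is_complete:
        raise ValueError("impute the feature matrix before embedding")
    coords = ClassicalMDS(n_components=2).fit_transform(m.values.to_numpy())
    return pd.DataFrame(coords, index=m.values.index, columns=["mds1", "mds2"])


def default_feature_specs() -> list[FeatureSpec]:
    """The default 42-feature panel: 14 functional + 28 computational.

    Functional: eight yeast promoter transactivation readouts, their
    average and median, one cell-cycle-arrest readout (DNA-binding domain
    only) and three mammalian-screen readouts.  Computational: 28
    conservation / structural / ensemble predictor scores.
    """
    promoters = [
        "WAF1", "MDM2", "BAX", "h1433s", "AIP1", "GADD45", "NOXA", "P53R2",
    ]
    functional = (
        [FeatureSpec(f"trans_{p}", "functional", "yeast transactivation", False)
         for p in promoters]
        + [
            FeatureSpec("trans_avg", "functional", "yeast transactivation", False),
            FeatureSpec("trans_median", "functional", "yeast transactivation", False),
            FeatureSpec("cell_cycle_arrest", "functional",
                        "cell-cycle-arrest screen (DNA-binding domain)", False),
            FeatureSpec("dominant_negative", "functional", "mammalian screen", True),
            FeatureSpec("lof_screen", "functional", "mammalian screen", True),
            FeatureSpec("etoposide_response", "functional", "mammalian screen", False),
        ]
    )
    computational_names = [
        "sift", "polyphen2_hdiv", "polyphen2_hvar", "lrt", "mutationtaster",
        "mutationassessor", "fathmm", "provean", "vest4", "metasvm", "metalr",
        "m_cap", "revel", "mutpred", "mvp", "primateai", "deogen2", "cadd",
        "dann", "eigen", "genocanyon", "fitcons", "gerp", "phylop100way",
        "phylop30way", "phastcons100way", "siphy", "eve",
    ]
    computational = [
        FeatureSpec(n, "computational", "precomputed in-silico predictor", True)
        for n in computational_names
    ]
    return functional + computational
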