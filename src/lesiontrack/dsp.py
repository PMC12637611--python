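"""Spatial-profiling compartment assignment and clustered-vs-scattered DE.

AOI-level transcript counts (genes x AOIs) are upper-quartile normalized; each
gene is assigned to the tissue compartment — myeloid (GFP+), epithelial
(PanCK+) or other (double negative) — in which its mean normalized expression
is highest. Differential expression between myeloid AOIs of clustered versus
scattered lesions first aggregates AOIs to lesion-level means of log2
normalized counts (respecting within-lesion correlation), then compares lesion
means per gene; a gene is significant when |log2FC| > 1 and p < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "COMPARTMENTS",
    "upper_quartile_normalize",
    "assign_compartments",
    "differential_expression",
    "CompartmentAssigner",
    "ClusteredScatteredDE",
]

#: Compartment names in tie-break priority order.
COMPARTMENTS = ("myeloid", "epithelial", "other")


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each AOI (column) by its upper quartile of positive counts.

    Columns are divided by their Q3 over genes with nonzero counts and
    multiplied by the geometric mean of the per-AOI Q3 values, so the output
    stays on a count-like scale. AOIs with no positive counts are rejected.
    """
    counts = counts.astype(float)
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    q3 = counts.apply(lambda col: np.percentile(col[col > 0], 75) if (col > 0).any() else np.nan)
    if q3.isna().any():
        bad = list(counts.columns[q3.isna()])
        raise ValueError(f"AOIs with no positive counts cannot be normalized: {bad}")
    return counts.div(q3, axis=1) * float(np.exp(np.log(q3).mean()))


class CompartmentAssigner(BaseEstimator):
    """Assign genes to tissue compartments from AOI-class expression.

    ``fit(counts, aoi_class)`` normalizes the matrix (upper quartile), averages
    normalized expression per AOI class and assigns each gene to the class with
    the highest mean. Ties break toward myeloid > epithelial > other and are
    flagged. Fitted attribute ``compartments_`` is a DataFrame indexed by gene
    with columns ``compartment`` and ``tie``.
    """

    def __init__(self, normalize: bool = True):
        self.normalize = normalize

    def fit(self, X: pd.DataFrame, y=None):
        """``X``: genes x AOIs counts; ``y``: AOI class per column of X."""
        aoi_class = pd.Series(y, index=X.columns) if not isinstance(y, pd.Series) else y
        missing = [c for c in COMPARTMENTS if (aoi_class == c).sum() == 0]
        if missing:
            raise ValueError(f"AOI classes with zero AOIs: {missing}")
        norm = upper_quartile_normalize(X) if self.normalize else X.astype(float)
        class_means = pd.DataFrame(
            {c: norm.loc[:, (aoi_class == c).to_numpy()].mean(axis=1) for c in COMPARTMENTS}
        )
        ranked = class_means[list(COMPARTMENTS)]  # priority order for argmax ties
        best = ranked.idxmax(axis=1)
        row_max = ranked.max(axis=1)
        tie = (ranked.eq(row_max, axis=0).sum(axis=1) > 1)
        self.class_means_ = class_means
        self.compartments_ = pd.DataFrame({"compartment": best, "tie": tie})
        return self

    def predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        if y is not None:
            self.fit(X, y)
        return self.compartments_["compartment"].to_numpy(dtype=object)


def assign_compartments(counts: pd.DataFrame, aoi_class) -> pd.DataFrame:
    """Functional wrapper over :class:`CompartmentAssigner`."""
    return CompartmentAssigner().fit(counts, aoi_class).compartments_


class ClusteredScatteredDE(BaseEstimator):
    """Differential expression between clustered and scattered myeloid AOIs.

    ``fit(counts, annotation)`` restricts to AOIs of class ``myeloid`` whose
    lesion group is ``clustered`` or ``scattered`` (and, if ``genes`` is
    given, to that gene subset — typically the myeloid compartment genes).
    Counts are upper-quartile normalized, log2(x + pseudocount) transformed,
    averaged to one value per lesion, and compared per gene with a Welch
    t-test across lesion means. log2FC is clustered minus scattered, so
    positive values mean higher in clustered lesions. Significance requires
    |log2FC| > ``lfc_min`` (default 1) and p < ``alpha`` (default 0.05).

    Fitted attribute ``results_``: DataFrame indexed by gene with columns
    ``log2fc``, ``p_value``, ``significant``.
    """

    def __init__(
        self,
        lfc_min: float = 1.0,
        alpha: float = 0.05,
        pseudocount: float = 1.0,
        genes=None,
    ):
        self.lfc_min = lfc_min
        self.alpha = alpha
        self.pseudocount = pseudocount
        self.genes = genes

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        """``X``: genes x AOIs counts; ``y``: AOI annotation indexed by AOI id
        with columns ``class``, ``lesion_id``, ``group``."""
        annot = y.loc[X.columns]
        sel = (annot["class"] == "myeloid") & annot["group"].isin(["clustered", "scattered"])
        if self.genes is not None:
            X = X.loc[list(self.genes)]
        norm = upper_quartile_normalize(X)
        norm = norm.loc[:, sel.to_numpy()]
        annot = annot[sel]
        log2 = np.log2(norm + self.pseudocount)
        lesion_means = log2.T.groupby(annot["lesion_id"]).mean().T  # genes x lesions
        lesion_group = annot.groupby("lesion_id")["group"].first()
        cl = lesion_means.loc[:, (lesion_group == "clustered").to_numpy()]
        sc = lesion_means.loc[:, (lesion_group == "scattered").to_numpy()]
        if cl.shape[1] < 2 or sc.shape[1] < 2:
            raise ValueError(
                f"need >= 2 lesions per group; got {cl.shape[1]} clustered, {sc.shape[1]} scattered"
            )
        lfc = cl.mean(axis=1) - sc.mean(axis=1)
        t, p = stats.ttest_ind(cl, sc, axis=1, equal_var=False)
        results = pd.DataFrame(
            {"log2fc": lfc, "p_value": p},
            index=X.index,
        )
        # zero-variance genes with equal means: not significant, p undefined -> 1
        results["p_value"] = results["p_value"].fillna(1.0)
        results["significant"] = (results["log2fc"].abs() > self.lfc_min) & (
            results["p_value"] < self.alpha
        )
        self.n_lesions_ = {"clustered": int(cl.shape[1]), "scattered": int(sc.shape[1])}
        self.results_ = results
        return self


def differential_expression(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    genes=None,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Functional wrapper over :class:`ClusteredScatteredDE`."""
    de = ClusteredScatteredDE(lfc_min=lfc_min, alpha=alpha, genes=genes)
    return de.fit(counts, annotation).results_
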