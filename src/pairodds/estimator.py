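"""scikit-learn style front end for the association pipeline.

:class:`SpeciesAssociation` wraps prevalence filtering, all-pairs
directed odds-ratio estimation and network assembly behind the familiar
``fit`` / ``get_params`` / ``set_params`` surface, so the analysis drops
into sklearn pipelines and parameter sweeps. The functional layer in
:mod:`pairodds.estimation` and :mod:`pairodds.assemble` does the work.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .assemble import AssemblyConfig, classify_edges, filter_by_prevalence
from .estimation import SurveyTable, estimate_all_pairs, estimates_to_frame

__all__ = ["SpeciesAssociation"]


class SpeciesAssociation(BaseEstimator):
    """Directed odds-ratio association network from presence/absence data.

    Parameters
    ----------
    estimator : {"raw", "logistic", "glmm"}
        Per-pair odds-ratio estimator; "glmm" adds a random site
        intercept and needs ``sites`` passed to :meth:`fit`.
    prevalence_min : float
        Species present in fewer than this proportion of surveys are
        dropped before estimation.
    or_upper, or_lower : float
        Classification thresholds; ``or_lower=None`` means
        ``1 / or_upper``. Strict inequalities.
    alpha : float
        Significance level for the Wald test of log OR = 0.
    multiplicity : {"none", "bonferroni_by_species", "bonferroni_by_pairs"}
        Adjustment used for the conservative significance flag.
    ci_level : float
        Confidence level of the reported odds-ratio intervals.

    Attributes
    ----------
    species_names_ : list of retained species
    prevalences_ : Series of retained-species prevalences
    filter_report_ : DataFrame of dropped species
    estimates_ : list of PairEstimate, one per ordered retained pair
    network_ : AssociationNetwork of classified edges

    Examples
    --------
    >>> model = SpeciesAssociation(estimator="raw").fit(presence_frame)
    >>> model.network_.n_indications  # doctest: +SKIP
    """

    def __init__(
        self,
        estimator: str = "raw",
        prevalence_min: float = 0.10,
        or_upper: float = 3.0,
        or_lower: float | None = None,
        alpha: float = 0.05,
        multiplicity: str = "bonferroni_by_species",
        ci_level: float = 0.95,
    ):
        self.estimator = estimator
        self.prevalence_min = prevalence_min
        self.or_upper = or_upper
        self.or_lower = or_lower
        self.alpha = alpha
        self.multiplicity = multiplicity
        self.ci_level = ci_level

    def _assembly_config(self) -> AssemblyConfig:
        lower = self.or_lower if self.or_lower is not None else 1.0 / self.or_upper
        return AssemblyConfig(
            prevalence_min=self.prevalence_min,
            or_upper=self.or_upper,
            or_lower=lower,
            alpha=self.alpha,
            multiplicity=self.multiplicity,
            ci_level=self.ci_level,
        )

    def fit(self, X, y=None, *, sites=None):
        """Estimate the association network from a presence matrix.

        Parameters
        ----------
        X : DataFrame, array or SurveyTable
            Survey x species binary matrix. Array columns are named
            ``species_0`` ... ``species_{k-1}``.
        sites : sequence, optional
            Site label per survey (ignored if ``X`` is a SurveyTable).
        """
        if isinstance(X, SurveyTable):
            data = X
        else:
            if not isinstance(X, pd.DataFrame):
                X = np.asarray(X)
                if X.ndim != 2:
                    raise ValueError("X must be a 2-d survey x species matrix")
                X = pd.DataFrame(
                    X, columns=[f"species_{k}" for k in range(X.shape[1])]
                )
            data = SurveyTable(X, sites=sites)
        self.n_features_in_ = data.n_species
        self.feature_names_in_ = np.asarray(data.species_names, dtype=object)

        filtered, self.filter_report_ = filter_by_prevalence(data, self.prevalence_min)
        self.species_names_ = filtered.species_names
        self.prevalences_ = filtered.prevalence()
        self.estimates_ = estimate_all_pairs(
            filtered, estimator=self.estimator, ci_level=self.ci_level
        )
        self.network_ = classify_edges(
            self.estimates_,
            self._assembly_config(),
            prevalences=self.prevalences_,
            estimator=self.estimator,
        )
        return self

    def estimates_frame(self) -> pd.DataFrame:
        """All directed estimates as a tidy table (requires fit)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "estimates_")
        return estimates_to_frame(self.estimates_)

    def odds_ratio_matrix(self) -> pd.DataFrame:
        """Directed OR matrix, entry [target, predictor] (requires fit)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "estimates_")
        mat = pd.DataFrame(
            np.nan, index=self.species_names_, columns=self.species_names_
        )
        for e in self.estimates_:
            mat.loc[e.target, e.predictor] = e.or_value
        return mat
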