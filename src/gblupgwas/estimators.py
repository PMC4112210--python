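"""Scikit-learn style estimators wrapping the GBLUP scan machinery.

:class:`GBLUP` is a genomic ridge regressor: ``fit(X, y)`` takes complete
allele dosages and a phenotype, estimates variance components by REML under
the genomic-relationship covariance, and exposes breeding values and
back-transformed marker effects; ``predict`` scores new animals through the
marker effects.  :class:`SnpAssociationScan` runs the whole per-marker
association scan and stores the results table.  Both follow sklearn
conventions (``get_params``/``set_params``, trailing-underscore fitted
attributes, input validation) and compose with pipelines and model
selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .grm import compute_grm, standardize
from .mixedmodel import DesignData, reml_fit
from .snptests import snp_effect_estimates


def _design_from(y, covariates):
    if covariates is None:
        X = np.ones((len(y), 1))
    else:
        covariates = check_array(covariates, ensure_2d=True)
        X = np.column_stack([np.ones(len(y)), covariates])
    return DesignData(y=y, X=X)


class GBLUP(RegressorMixin, BaseEstimator):
    """Genomic BLUP regressor with REML variance components.

    Parameters
    ----------
    tol, max_iter : REML convergence controls.
    p : optional reference-allele frequencies used for centring/scaling;
        estimated from the training dosages when None.

    Attributes
    ----------
    p_ : frequencies used; sigma2_a_, sigma2_e_, h2_ : variance components;
    beta_ : fixed-effect solutions (intercept first); gebv_ : fitted
    breeding values; marker_effects_ : back-transformed per-marker effects;
    loglik_ : restricted log-likelihood; converged_, n_iter_.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200,
                 p=None):
        self.tol = tol
        self.max_iter = max_iter
        self.p = p

    def fit(self, X, y, covariates=None):
        X, y = check_X_y(X, y, y_numeric=True)
        if np.isnan(X).any():
            raise ValueError("GBLUP requires imputed (complete) dosages")
        p = (X.mean(axis=0) / 2.0 if self.p is None
             else np.asarray(self.p, dtype=float))
        Z = standardize(X, p)
        G = compute_grm(Z)
        data = _design_from(y, covariates)
        fit = reml_fit(data, G, tol=self.tol, max_iter=self.max_iter)
        est = snp_effect_estimates(fit, G, Z)
        self.p_ = p
        self.scale_ = np.sqrt(Z.m_divisor * 2.0 * p * (1.0 - p))
        self.sigma2_a_ = fit.vc.sigma2_a
        self.sigma2_e_ = fit.vc.sigma2_e
        self.h2_ = fit.vc.h2
        self.beta_ = fit.beta
        self.gebv_ = fit.ahat
        self.marker_effects_ = est.ghat
        self.marker_effect_vars_ = est.var_ghat
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        self.reml_fit_ = fit
        self.grm_ = G
        self.Z_ = Z
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, covariates=None):
        """Fixed part plus marker-effect score of new dosages."""
        check_is_fitted(self, "marker_effects_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("dosage matrix has wrong number of markers")
        Z_new = (X - 2.0 * self.p_) / self.scale_
        fixed = np.full(X.shape[0], self.beta_[0])
        if covariates is not None:
            covariates = check_array(covariates, ensure_2d=True)
            fixed = fixed + covariates @ self.beta_[1:]
        elif len(self.beta_) > 1:
            raise ValueError("model was fitted with covariates; supply them")
        return fixed + Z_new @ self.marker_effects_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = False
        return tags


class SnpAssociationScan(BaseEstimator):
    """Per-marker association scan from a GBLUP fit.

    After ``fit``, ``results_`` holds the scan table (effects, SNP_ej,
    SNP_epj, p-values) and ``gblup_`` the underlying fitted regressor.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200, p=None):
        self.tol = tol
        self.max_iter = max_iter
        self.p = p

    def fit(self, X, y, covariates=None, markers=None):
        from .geno_io import MarkerMap
        from .snptests import scan_table

        model = GBLUP(tol=self.tol, max_iter=self.max_iter, p=self.p)
        model.fit(X, y, covariates=covariates)
        if markers is None:
            m = model.n_features_in_
            markers = MarkerMap(
                np.array([f"snp{j}" for j in range(m)], dtype=object),
                np.array(["0"] * m, dtype=object),
                np.arange(1, m + 1))
        self.gblup_ = model
        self.results_ = scan_table(model.reml_fit_, model.grm_, model.Z_,
                                   markers)
        self.n_features_in_ = model.n_features_in_
        return self
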