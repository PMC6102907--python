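"""Scikit-learn-style estimators wrapping the MCMC machinery.

``BKMRRegressor`` (continuous outcomes) and ``BKMRProbitClassifier``
(binary outcomes) follow the sklearn estimator contract: hyperparameters in
``__init__``, ``fit(Z, y, covariates=..., cluster_id=...)``, fitted
attributes with trailing underscores, ``get_params``/``set_params`` for
pipeline and model-selection compatibility. The feature matrix passed to
``fit``/``predict`` is the exposure matrix Z (the argument of the
exposure-response surface h); covariates enter linearly and are passed as a
keyword, mirroring how sample weights travel in sklearn.

Everything the estimators do is also available functionally: the fitted
``samples_`` object feeds :mod:`kmrmix.summaries` and
:mod:`kmrmix.diagnostics` directly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import summaries
from .data import MixtureDataset, standardize_exposures
from .kernels import select_knots
from .mcmc import McmcControl, run_mcmc
from .params import GroupSpec, PriorSpec

__all__ = ["BKMRRegressor", "BKMRProbitClassifier"]


class _BaseBKMR(BaseEstimator):
    _family = "gaussian"

    def __init__(
        self,
        n_iter: int = 10000,
        burn_frac: float = 0.5,
        thin: int = 1,
        varsel: bool = True,
        groups=None,
        n_knots: int | None = None,
        knot_method: str = "kmeans",
        standardize: bool = True,
        priors: PriorSpec | None = None,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.n_iter = n_iter
        self.burn_frac = burn_frac
        self.thin = thin
        self.varsel = varsel
        self.groups = groups
        self.n_knots = n_knots
        self.knot_method = knot_method
        self.standardize = standardize
        self.priors = priors
        self.random_state = random_state
        self.verbose = verbose

    # -- fitting -----------------------------------------------------------
    def fit(self, Z, y, covariates=None, cluster_id=None):
        """Run the MCMC sampler on (y, Z, X) and store the posterior.

        Parameters
        ----------
        Z : array-like (n, M)
            Exposure matrix.
        y : array-like (n,)
            Outcome (0/1 for the probit classifier).
        covariates : array-like (n, P), optional
            Linear-adjustment covariates X.
        cluster_id : array-like (n,), optional
            Cluster labels; adds a marginalized random intercept.
        """
        Z = check_array(Z, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        X = (
            check_array(covariates, dtype=float, ensure_2d=False)
            if covariates is not None
            else np.zeros((Z.shape[0], 0))
        )
        if X.ndim == 1:
            X = X[:, None]
        data = MixtureDataset(
            y=y, Z=Z, X=X, cluster_id=cluster_id, family=self._family
        )
        if self.standardize:
            Zs, centers, scales = standardize_exposures(data.Z)
        else:
            Zs = data.Z
            centers = np.zeros(data.M)
            scales = np.ones(data.M)
        data = MixtureDataset(
            y=data.y, Z=Zs, X=data.X, cluster_id=data.cluster_id,
            family=self._family, exposure_names=data.exposure_names,
            covariate_names=data.covariate_names,
        )
        groups = self.groups
        if groups is not None and not isinstance(groups, GroupSpec):
            groups = GroupSpec({k: tuple(v) for k, v in dict(groups).items()})
        knots = None
        if self.n_knots is not None:
            knots = select_knots(
                Zs, self.n_knots, method=self.knot_method,
                seed=self.random_state,
            )
        control = McmcControl(
            n_iter=self.n_iter,
            burn_frac=self.burn_frac,
            thin=self.thin,
            seed=self.random_state,
            varsel=self.varsel,
            verbose=self.verbose,
        )
        self.samples_ = run_mcmc(
            data, priors=self.priors, groups=groups, control=control,
            knots=knots, centers=centers, scales=scales,
        )
        self.n_features_in_ = data.M
        self.acceptance_rates_ = self.samples_.acceptance
        if self.varsel:
            self.pips_ = summaries.extract_pips(self.samples_)
        return self

    # -- posterior summaries (thin delegation) ------------------------------
    def predict_h(self, Z, mode: str = "mean-only"):
        check_is_fitted(self, "samples_")
        return summaries.predict_h(self.samples_, Z, mode=mode)

    def overall_effect(self, quantile_pairs=((0.25, 0.75),)):
        check_is_fitted(self, "samples_")
        return summaries.overall_effect(self.samples_, quantile_pairs)

    def single_exposure_effects(self, fix_quantiles=(0.25, 0.50, 0.75)):
        check_is_fitted(self, "samples_")
        return summaries.single_exposure_effects(self.samples_, fix_quantiles)

    def interactive_effects(self):
        check_is_fitted(self, "samples_")
        return summaries.interactive_effects(self.samples_)

    def univariate_cross_section(self, m, **kwargs):
        check_is_fitted(self, "samples_")
        return summaries.univariate_cross_section(self.samples_, m, **kwargs)

    def bivariate_cross_section(self, m1, m2, **kwargs):
        check_is_fitted(self, "samples_")
        return summaries.bivariate_cross_section(self.samples_, m1, m2, **kwargs)

    def _linear_predictor(self, Z, covariates):
        """Posterior-mean h(Z) plus the covariate contribution."""
        check_is_fitted(self, "samples_")
        Z = check_array(Z, dtype=float)
        hmean = summaries.predict_h(self.samples_, Z, mode="mean-only").mean()
        if self.samples_.beta.shape[1]:
            if covariates is None:
                raise ValueError("fit used covariates; pass covariates to predict")
            X = check_array(covariates, dtype=float, ensure_2d=False)
            if X.ndim == 1:
                X = X[:, None]
            hmean = hmean + X @ self.samples_.beta.mean(axis=0)
        return hmean


class BKMRRegressor(RegressorMixin, _BaseBKMR):
    """Bayesian kernel machine regression for a continuous outcome.

    Model: y_i = h(z_i1..z_iM) + x_i' beta + eps_i with eps_i ~ N(0, sigma^2)
    and a Gaussian-process prior on h induced by the component-weighted
    Gaussian kernel; spike-and-slab priors on the kernel weights perform
    exposure selection.

    Examples
    --------
    >>> from kmrmix import BKMRRegressor, simulate_continuous
    >>> data, truth = simulate_continuous()
    >>> fit = BKMRRegressor(n_iter=500, random_state=1).fit(
    ...     data.Z, data.y, covariates=data.X)
    >>> fit.pips_.shape[0]
    7
    """

    _family = "gaussian"

    def predict(self, Z, covariates=None):
        """Posterior-mean outcome E[y | Z, X]."""
        return self._linear_predictor(Z, covariates)


class BKMRProbitClassifier(ClassifierMixin, _BaseBKMR):
    """Probit kernel machine regression for a binary outcome.

    Model: P(Y_i = 1) = Phi(h(z_i) + x_i' beta), fit through the latent
    normal representation Y_i = 1{Y_i* > 0} with Y_i* = h + x'beta + e_i,
    e_i ~ N(0, 1). The surface h lives on the latent (probit) scale.
    """

    _family = "binomial-probit"

    def fit(self, Z, y, covariates=None, cluster_id=None):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        return super().fit(Z, y, covariates=covariates, cluster_id=cluster_id)

    def predict_proba(self, Z, covariates=None):
        """Posterior-mean event probability, shape (n, 2) sklearn-style."""
        lin = self._linear_predictor(Z, covariates)
        p1 = stats.norm.cdf(lin)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, Z, covariates=None):
        return (self.predict_proba(Z, covariates)[:, 1] >= 0.5).astype(int)

    def risk_difference(self, z_a, z_b, x_settings=None):
        check_is_fitted(self, "samples_")
        return summaries.risk_difference(self.samples_, z_a, z_b, x_settings)
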