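"""Phylogenetic signal statistics and PGLS regression.

The statistics here quantify whether a continuous trait measured across the
tips of a phylogeny carries phylogenetic signal — whether close relatives
resemble each other more than species drawn at random from the tree — and
fit regressions whose error covariance respects that structure:

* ``PagelLambda``: maximum-likelihood estimate of Pagel's λ, the multiplier
  on the off-diagonal of the Brownian covariance V.  λ = 1 is strict
  Brownian motion, λ = 0 phylogenetic independence.  Likelihood-ratio tests
  against both boundaries use the 50:50 χ²₀/χ²₁ boundary mixture.
* ``BlombergK``: the observed-to-Brownian-expected MSE ratio, K = 1 under
  Brownian motion, with a tip-shuffling permutation test.
* ``PGLS``: generalized least squares with error covariance V (Brownian
  mode) or V(λ̂) with λ re-estimated from the regression residuals
  (ml_lambda mode, the default for binary-trait analyses).

All models follow the fit()-returns-results convention; every result object
carries the numbers its JSON serialization needs plus a text ``summary()``.

Estimation is ML throughout (not REML); log-determinants come from Cholesky
factors, with a 1e-10 diagonal jitter added only when factorization fails.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .exceptions import (
    AlignmentError,
    NumericalError,
    RankDeficiencyError,
    UndefinedStatisticError,
)
from .phylo import PhyloCov, Phylogeny, align_traits_to_tree, lambda_transform

__all__ = [
    "bm_loglik", "lr_test", "BMLoglik",
    "PagelLambda", "LambdaResults",
    "BlombergK", "KResults",
    "PGLS", "PGLSResults",
]

logger = logging.getLogger(__name__)

_JITTER = 1e-10


def _cholesky(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, with a logged jitter retry on failure."""
    try:
        return scipy.linalg.cholesky(V, lower=True)
    except scipy.linalg.LinAlgError:
        logger.warning("covariance factorization failed; retrying with %g jitter", _JITTER)
        try:
            return scipy.linalg.cholesky(V + _JITTER * np.eye(V.shape[0]), lower=True)
        except scipy.linalg.LinAlgError as exc:
            cond = np.linalg.cond(V)
            raise NumericalError(
                f"covariance matrix is singular (condition estimate {cond:.3g})"
            ) from exc


class BMLoglik(NamedTuple):
    """Profiled Brownian-motion log-likelihood and its closed-form MLEs."""

    loglik: float
    root_mean: float   # GLS estimate of the root state
    sigma2: float      # ML Brownian rate (variance per unit branch length)
    degenerate: bool   # True when the trait is constant (sigma2 == 0)


def bm_loglik(x: np.ndarray, V: PhyloCov) -> BMLoglik:
    """Multivariate-normal log-likelihood of a trait under covariance V.

    The mean (ancestral/root state) and rate are profiled out analytically:
    â = (1ᵀV⁻¹1)⁻¹ 1ᵀV⁻¹x, σ̂² = (x−â1)ᵀV⁻¹(x−â1)/n, and
    ℓ = −(n/2)·ln(2πσ̂²) − ½·ln|V| − n/2.

    A constant trait gives σ̂² = 0 and a degenerate flag with ℓ = +inf
    rather than an exception, so optimizers can observe it.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = V.n
    if x.size != n:
        raise AlignmentError(f"trait length {x.size} != covariance dimension {n}")
    L = _cholesky(V.matrix)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ones = np.ones(n)
    # whitened solves through the factor
    Li_x = scipy.linalg.solve_triangular(L, x, lower=True)
    Li_1 = scipy.linalg.solve_triangular(L, ones, lower=True)
    denom = Li_1 @ Li_1
    ahat = float((Li_1 @ Li_x) / denom)
    resid = Li_x - ahat * Li_1
    q = float(resid @ resid)
    sigma2 = q / n
    if sigma2 <= 0.0 or not np.isfinite(sigma2):
        return BMLoglik(loglik=np.inf, root_mean=ahat, sigma2=0.0, degenerate=True)
    ll = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet - 0.5 * n
    return BMLoglik(loglik=float(ll), root_mean=ahat, sigma2=float(sigma2), degenerate=False)


def lr_test(loglik_restricted: float, loglik_full: float, boundary: bool = False) -> float:
    """Likelihood-ratio p-value from χ²₁, halved for a boundary null.

    When the restricted value sits on the edge of the parameter space the
    LR statistic is asymptotically a 50:50 mixture of a point mass at 0 and
    χ²₁, so the χ²₁ tail probability is halved; Λ slightly below 0 (within
    optimizer tolerance 1e-6) is clamped to 0.
    """
    lam = 2.0 * (loglik_full - loglik_restricted)
    if lam < -1e-6:
        raise NumericalError(
            f"full-model log-likelihood below restricted ({lam/2:.3g}); optimizer failure")
    lam = max(lam, 0.0)
    if lam == 0.0:
        return 1.0
    p = scipy.stats.chi2.sf(lam, df=1)
    if boundary:
        p *= 0.5
    return float(p)


def _align(trait, tree: Phylogeny):
    """Accept pandas data keyed by species, aligned to the tree tips."""
    if not isinstance(trait, (pd.Series, pd.DataFrame)):
        raise TypeError("trait data must be a pandas Series/DataFrame keyed by species")
    pruned, aligned, report = align_traits_to_tree(trait, tree)
    if report.dropped_from_tree or report.dropped_from_table:
        logger.info("trait/tree alignment: %s", report)
    return pruned, aligned


# ---------------------------------------------------------------------------
# Pagel's lambda


def _optimize_lambda(loglik_at):
    """Maximize a log-likelihood profile over λ ∈ [0, 1].

    101-point coarse grid, then bounded golden-section/Brent refinement in
    the bracketing interval; ties broken toward smaller λ; λ tolerance 1e-8.
    Returns (λ̂, ℓ(λ̂), degenerate_flat_profile).
    """
    grid = np.linspace(0.0, 1.0, 101)
    lls = np.array([loglik_at(l) for l in grid])
    if not np.all(np.isfinite(lls)):
        # constant trait: profile is +inf everywhere — flag, report lambda 0
        return 0.0, float(lls[0]), True
    flat = np.ptp(lls) < 1e-10
    i = int(np.argmax(lls))  # argmax takes the first (smallest λ) on ties
    if flat:
        return float(grid[i]), float(lls[i]), True
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, 100)]
    res = scipy.optimize.minimize_scalar(
        lambda l: -loglik_at(l), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    lam, ll = float(res.x), float(-res.fun)
    if lls[i] >= ll or (abs(lls[i] - ll) < 1e-12 and grid[i] < lam):
        lam, ll = float(grid[i]), float(lls[i])
    return lam, ll, False


@dataclass
class LambdaResults:
    """Maximum-likelihood fit of Pagel's λ for one trait on one tree."""

    lam: float
    sigma2: float
    root_mean: float
    loglik: float
    loglik_lambda0: float
    loglik_lambda1: float
    p_vs_zero: float
    p_vs_one: float
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam, "sigma2": self.sigma2, "root_mean": self.root_mean,
            "loglik": self.loglik, "p_vs_zero": self.p_vs_zero, "p_vs_one": self.p_vs_one,
        }

    def summary(self) -> str:
        lines = [
            "Pagel's lambda (ML)",
            "-" * 46,
            f"n species            {self.n:>12d}",
            f"lambda               {self.lam:>12.6g}",
            f"sigma^2              {self.sigma2:>12.6g}",
            f"root mean            {self.root_mean:>12.6g}",
            f"log-likelihood       {self.loglik:>12.6g}",
            f"LR p (vs lambda=0)   {self.p_vs_zero:>12.4g}",
            f"LR p (vs lambda=1)   {self.p_vs_one:>12.4g}",
        ]
        if self.degenerate:
            lines.append("warning: flat/degenerate likelihood profile")
        return "\n".join(lines)


class PagelLambda:
    """Model: a continuous trait under λ-transformed Brownian motion.

    Parameters
    ----------
    trait : pandas Series keyed by species label.
    tree : Phylogeny whose tips cover the trait's species.
    """

    def __init__(self, trait: pd.Series, tree: Phylogeny):
        self.tree, self.trait = _align(trait, tree)
        if self.tree.n_tips < 4:
            raise ValueError("Pagel's lambda needs at least 4 species")
        self._V = self.tree.vcv()
        self._x = self.trait.to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, column: str, tree: Phylogeny,
                       species_column: str = "species") -> "PagelLambda":
        t = table.set_index(species_column)[column] if species_column in table.columns \
            else table[column]
        return cls(t, tree)

    def loglik(self, lam: float) -> float:
        return bm_loglik(self._x, lambda_transform(self._V, lam)).loglik

    def fit(self) -> LambdaResults:
        lam, ll, degenerate = _optimize_lambda(self.loglik)
        at_hat = bm_loglik(self._x, lambda_transform(self._V, lam))
        ll0 = self.loglik(0.0)
        ll1 = self.loglik(1.0)
        if degenerate and not np.isfinite(ll):
            # constant trait: no information about lambda at all
            return LambdaResults(
                lam=lam, sigma2=0.0, root_mean=at_hat.root_mean, loglik=np.inf,
                loglik_lambda0=ll0, loglik_lambda1=ll1,
                p_vs_zero=1.0, p_vs_one=1.0, n=self.tree.n_tips, degenerate=True)
        # the reported optimum must dominate both boundaries
        for bll, blam in ((ll0, 0.0), (ll1, 1.0)):
            if bll > ll:
                lam, ll = blam, bll
                at_hat = bm_loglik(self._x, lambda_transform(self._V, lam))
        return LambdaResults(
            lam=lam, sigma2=at_hat.sigma2, root_mean=at_hat.root_mean, loglik=ll,
            loglik_lambda0=ll0, loglik_lambda1=ll1,
            p_vs_zero=lr_test(ll0, ll, boundary=True),
            p_vs_one=lr_test(ll1, ll, boundary=True),
            n=self.tree.n_tips, degenerate=degenerate,
        )


# ---------------------------------------------------------------------------
# Blomberg's K


@dataclass
class KResults:
    """Blomberg's K with (optionally) its permutation p-value."""

    k: float
    mse0: float
    mse: float
    expected_ratio: float
    n: int
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {"k": self.k}
        if self.p_perm is not None:
            d.update({"p_perm": self.p_perm, "n_perm": self.n_perm, "seed": self.seed})
        return d

    def summary(self) -> str:
        lines = [
            "Blomberg's K",
            "-" * 46,
            f"n species            {self.n:>12d}",
            f"K                    {self.k:>12.6g}",
            f"MSE0 / MSE           {self.mse0 / self.mse:>12.6g}",
            f"E[MSE0/MSE | BM]     {self.expected_ratio:>12.6g}",
        ]
        if self.p_perm is not None:
            lines.append(f"permutation p        {self.p_perm:>12.4g}"
                         f"   ({self.n_perm} permutations, seed {self.seed})")
        return "\n".join(lines)


class BlombergK:
    """Model: phylogenetic signal of one trait as Blomberg's K.

    K compares the observed ratio of the ordinary mean squared error around
    the GLS mean (MSE0) to the phylogenetically corrected one (MSE) with
    the value that ratio takes in expectation under Brownian motion:

        K = (MSE0/MSE) / E_BM[MSE0/MSE],
        E_BM = [tr(V) − n / (1ᵀV⁻¹1)] / (n − 1).

    K = 1 under Brownian motion (exactly 1 on a star tree for any trait);
    K < 1 means trait variance sits within subclades rather than between.
    """

    def __init__(self, trait: pd.Series, tree: Phylogeny):
        self.tree, self.trait = _align(trait, tree)
        if self.tree.n_tips < 4:
            raise ValueError("Blomberg's K needs at least 4 species")
        self._V = self.tree.vcv()
        self._x = self.trait.to_numpy(dtype=float)
        if np.ptp(self._x) == 0:
            raise UndefinedStatisticError("K undefined for a constant trait")
        L = _cholesky(self._V.matrix)
        n = self._V.n
        self._Li = scipy.linalg.solve_triangular(L, np.eye(n), lower=True)
        self._Li_1 = self._Li @ np.ones(n)
        self._denom = float(self._Li_1 @ self._Li_1)
        self._expected_ratio = float(
            (np.trace(self._V.matrix) - n / self._denom) / (n - 1))

    def _mses(self, x: np.ndarray) -> tuple[float, float]:
        n = self._V.n
        Li_x = self._Li @ x
        ahat = float((self._Li_1 @ Li_x) / self._denom)
        dev = x - ahat
        mse0 = float(dev @ dev) / (n - 1)
        w = Li_x - ahat * self._Li_1
        mse = float(w @ w) / (n - 1)
        return mse0, mse

    def fit(self, n_perm: int | None = None, seed: int | None = None) -> KResults:
        """Compute K; with ``n_perm`` also the tip-shuffling permutation p.

        The permutation null shuffles trait values across tips; the test
        statistic is the GLS MSE (smaller = more signal), and the p-value
        uses the add-one estimator (1 + #{MSE* <= MSE_obs}) / (n_perm + 1).
        """
        mse0, mse = self._mses(self._x)
        k = (mse0 / mse) / self._expected_ratio
        res = KResults(k=float(k), mse0=mse0, mse=mse,
                       expected_ratio=self._expected_ratio, n=self._V.n)
        if n_perm is not None:
            if n_perm < 99:
                raise ValueError("n_perm must be at least 99")
            if seed is None:
                raise ValueError("a seed is required for the permutation test")
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(n_perm):
                _, mse_p = self._mses(rng.permutation(self._x))
                if mse_p <= mse:
                    hits += 1
            res.p_perm = (1 + hits) / (n_perm + 1)
            res.n_perm = n_perm
            res.seed = seed
        return res


# ---------------------------------------------------------------------------
# PGLS


@dataclass
class PGLSResults:
    """Generalized least squares fit under a phylogenetic error covariance."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    df_resid: int
    nobs: int
    correlation_mode: str
    lambda_used: float
    loglik: float

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        t = scipy.stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"low": self.params - t * self.bse, "high": self.params + t * self.bse})

    def to_dict(self) -> dict:
        return {
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "t_values": self.tvalues.to_dict(),
            "p_values": self.pvalues.to_dict(),
            "sigma2": self.sigma2, "df": self.df_resid,
            "correlation_mode": self.correlation_mode, "lambda_used": self.lambda_used,
        }

    def summary(self) -> str:
        head = [
            "Phylogenetic GLS",
            "-" * 64,
            f"n = {self.nobs}, df = {self.df_resid}, mode = {self.correlation_mode}, "
            f"lambda = {self.lambda_used:.4g}, sigma^2 = {self.sigma2:.4g}",
            f"{'term':<28}{'coef':>10}{'se':>9}{'t':>8}{'p':>9}",
        ]
        for name in self.params.index:
            head.append(
                f"{str(name):<28}{self.params[name]:>10.4g}{self.bse[name]:>9.3g}"
                f"{self.tvalues[name]:>8.3g}{self.pvalues[name]:>9.3g}")
        return "\n".join(head)


class PGLS:
    """Model: y = Xβ + ε with ε ~ N(0, σ²·V(λ)) on a phylogeny.

    ``mode="brownian"`` fixes λ = 1 (strict Brownian errors);
    ``mode="ml_lambda"`` profiles λ out of the regression residual
    likelihood by ML before the final GLS solve.
    """

    def __init__(self, y: pd.Series, X: pd.DataFrame, tree: Phylogeny,
                 mode: str = "ml_lambda"):
        if mode not in ("brownian", "ml_lambda"):
            raise ValueError(f"unknown PGLS mode {mode!r}")
        self.mode = mode
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame keyed by species label")
        data = X.copy()
        if "const" not in data.columns:
            data.insert(0, "const", 1.0)
        data = data.join(y.rename("__y__"), how="inner")
        self.tree, aligned = _align(data, tree)
        self._y = aligned["__y__"].to_numpy(dtype=float)
        self._X = aligned.drop(columns="__y__")
        n, p = self._X.shape
        if np.linalg.matrix_rank(self._X.to_numpy()) < p:
            raise RankDeficiencyError(
                f"design matrix is rank deficient (columns {list(self._X.columns)})")
        if n <= p:
            raise ValueError("need more species than coefficients")
        self._V = self.tree.vcv()

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, response: str, predictors: list,
                       tree: Phylogeny, mode: str = "ml_lambda",
                       species_column: str = "species") -> "PGLS":
        df = table.set_index(species_column) if species_column in table.columns else table
        df = df[[response] + list(predictors)].dropna()
        return cls(df[response], df[list(predictors)].astype(float), tree, mode=mode)

    def _gls(self, lam: float):
        """GLS solve under V(λ); returns (β̂, rss_gls, ml loglik, XtWiX_inv)."""
        W = lambda_transform(self._V, lam)
        L = _cholesky(W.matrix)
        Xw = scipy.linalg.solve_triangular(L, self._X.to_numpy(dtype=float), lower=True)
        yw = scipy.linalg.solve_triangular(L, self._y, lower=True)
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        n = len(self._y)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        s2_ml = rss / n
        if s2_ml <= 0:
            ll = np.inf
        else:
            ll = -0.5 * n * np.log(2.0 * np.pi * s2_ml) - 0.5 * logdet - 0.5 * n
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        return beta, rss, float(ll), XtX_inv

    def fit(self) -> PGLSResults:
        if self.mode == "brownian":
            lam = 1.0
            _, _, ll, _ = self._gls(1.0)
        else:
            lam, ll, _ = _optimize_lambda(lambda l: self._gls(l)[2])
        beta, rss, ll, XtX_inv = self._gls(lam)
        n, p = self._X.shape
        df = n - p
        sigma2 = rss / df
        se = np.sqrt(sigma2 * np.diag(XtX_inv))
        t = beta / se
        pv = 2.0 * scipy.stats.t.sf(np.abs(t), df)
        cols = self._X.columns
        return PGLSResults(
            params=pd.Series(beta, index=cols),
            bse=pd.Series(se, index=cols),
            tvalues=pd.Series(t, index=cols),
            pvalues=pd.Series(pv, index=cols),
            sigma2=float(sigma2), df_resid=int(df), nobs=int(n),
            correlation_mode=self.mode, lambda_used=float(lam), loglik=float(ll),
        )
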