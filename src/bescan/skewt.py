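"""Skew-t distribution and a two-component skew-t mixture.

The component family is the Azzalini skew-t: with z = (x − ξ)/ω,

    f(x) = (2/ω) · t_ν(z) · T_{ν+1}( α z √((ν+1)/(ν+z²)) )

where t_ν / T_{ν+1} are the Student density and CDF, ξ is the location, ω>0
the scale, ν>1 the degrees of freedom and α the skewness (α=0 recovers the
symmetric location-scale t exactly).  The mixture is fit by a generalized
EM: responsibilities in the E-step, then each component's weighted
log-likelihood is improved numerically (L-BFGS-B on an unconstrained
reparametrisation) from the current parameters, so the observed
log-likelihood never decreases.

``SkewTMixture`` follows the scikit-learn estimator protocol (get_params /
set_params / fit / predict_proba, fitted attributes with a trailing
underscore) and is the engine behind guide-to-cell assignment.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats

_DF_MIN = 1.0 + 1e-6
_DF_MAX = 200.0

# M-step box constraints (loc, log scale, log(df-1), skew): the scale floor
# and skew cap keep a component from collapsing onto a discrete spike of
# repeated values (e.g. the zero-UMI mass after the log transform)
_BOUNDS = [
    (None, None),
    (np.log(1e-2), np.log(1e3)),
    (np.log(5e-2), np.log(199.0)),
    (-30.0, 30.0),
]


def skewt_logpdf(x, loc=0.0, scale=1.0, df=5.0, skew=0.0):
    """Log density of the Azzalini skew-t distribution."""
    x = np.asarray(x, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if df <= 1:
        raise ValueError("df must be > 1")
    z = (x - loc) / scale
    core = stats.t.logpdf(z, df) - np.log(scale)
    if skew == 0.0:
        return core + np.log(2.0) + stats.t.logcdf(0.0, df + 1)  # log 2 + log 0.5 = 0
    arg = skew * z * np.sqrt((df + 1.0) / (df + z * z))
    return np.log(2.0) + core + stats.t.logcdf(arg, df + 1.0)


def skewt_pdf(x, loc=0.0, scale=1.0, df=5.0, skew=0.0):
    return np.exp(skewt_logpdf(x, loc, scale, df, skew))


def skewt_rvs(n, loc=0.0, scale=1.0, df=5.0, skew=0.0, rng=None):
    """Draws via the normal/half-normal construction scaled by √(ν/χ²_ν)."""
    rng = np.random.default_rng(rng)
    delta = skew / np.sqrt(1.0 + skew * skew)
    z0 = np.abs(rng.standard_normal(n))
    z1 = rng.standard_normal(n)
    sn = delta * z0 + np.sqrt(1.0 - delta * delta) * z1  # skew-normal(0,1,skew)
    w = rng.chisquare(df, n) / df
    return loc + scale * sn / np.sqrt(w)


def _pack(loc, scale, df, skew):
    return np.array([loc, np.log(scale), np.log(df - 1.0), skew])


def _unpack(theta):
    loc, lscale, ldf, skew = theta
    return loc, float(np.exp(lscale)), float(min(1.0 + np.exp(ldf), _DF_MAX)), skew


class SkewTMixture:
    """Two-component skew-t mixture fit by (generalized) EM.

    Parameters
    ----------
    n_components : int, default 2
        Mixture size; the guide-assignment model uses exactly two
        (background vs guide-present).
    tol : float, default 1e-6
        Absolute log-likelihood improvement below which EM stops.
    max_iter : int, default 500
    random_state : int or None
        Seeds nothing directly (the init is deterministic, quantile-based)
        but is kept for pipeline compatibility.

    Attributes (after fit)
    ----------------------
    locations_, scales_, dfs_, skews_, weights_ : ndarray, shape (k,)
        Components sorted by location (ascending: background first).
    loglik_ : float
    loglik_path_ : ndarray — per-iteration observed log-likelihood.
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-6,
                 max_iter: int = 500, random_state=None):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep=True):
        return {
            "n_components": self.n_components,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- core ---------------------------------------------------------------
    def _component_logpdf(self, x, thetas):
        return np.stack(
            [skewt_logpdf(x, *_unpack(t)) for t in thetas], axis=1
        )  # (n, k)

    def _init(self, x):
        k = self.n_components
        spread = max(np.std(x) / k, 1e-3)
        if k == 2:
            # split at the midrange: robust when one mode is rare (a few
            # percent of guide-present entries among background entries)
            lo, hi = np.quantile(x, [0.02, 0.98])
            cut = (lo + hi) / 2.0
            lower, upper = x[x <= cut], x[x > cut]
            if len(lower) >= 5 and len(upper) >= 5:
                thetas = [
                    _pack(np.median(g), max(np.std(g), 1e-2), 5.0, 0.0)
                    for g in (lower, upper)
                ]
                w = len(lower) / len(x)
                return thetas, np.array([w, 1.0 - w])
        locs = np.quantile(x, np.linspace(0.1, 0.9, k))
        thetas = [_pack(loc, spread, 5.0, 0.0) for loc in locs]
        return thetas, np.full(k, 1.0 / k)

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 10 * self.n_components:
            raise ValueError("too few observations to fit the mixture")
        thetas, weights = self._init(x)
        path = []
        prev = -np.inf
        converged = False
        for it in range(self.max_iter):
            comp = self._component_logpdf(x, thetas) + np.log(weights)
            loglik = float(special.logsumexp(comp, axis=1).sum())
            path.append(loglik)
            if loglik - prev < self.tol and it > 0:
                converged = True
                break
            prev = loglik
            resp = np.exp(comp - special.logsumexp(comp, axis=1, keepdims=True))
            weights = np.clip(resp.mean(axis=0), 1e-10, None)
            weights = weights / weights.sum()
            for j in range(self.n_components):
                r = resp[:, j]

                def nll(theta, r=r):
                    loc, scale, df, skew = _unpack(theta)
                    val = -float(np.dot(r, skewt_logpdf(x, loc, scale, df, skew)))
                    return val if np.isfinite(val) else 1e30

                res = optimize.minimize(
                    nll, thetas[j], method="L-BFGS-B", bounds=_BOUNDS,
                    options={"maxiter": 15, "ftol": 1e-12},
                )
                # GEM: only accept an M-step that does not hurt the weighted
                # log-likelihood, preserving monotonicity exactly
                if np.isfinite(res.fun) and res.fun <= nll(thetas[j]):
                    thetas[j] = res.x
        order = np.argsort([_unpack(t)[0] for t in thetas])
        params = [_unpack(thetas[j]) for j in order]
        self.locations_ = np.array([p[0] for p in params])
        self.scales_ = np.array([p[1] for p in params])
        self.dfs_ = np.array([p[2] for p in params])
        self.skews_ = np.array([p[3] for p in params])
        self.weights_ = np.asarray(weights)[order]
        self.loglik_ = path[-1]
        self.loglik_path_ = np.array(path)
        self.converged_ = converged
        self.n_iter_ = len(path)
        return self

    def component_logpdf(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return np.stack(
            [
                skewt_logpdf(x, self.locations_[j], self.scales_[j],
                             self.dfs_[j], self.skews_[j])
                for j in range(self.n_components)
            ],
            axis=1,
        )

    def predict_proba(self, X):
        """Posterior responsibilities, components ordered by location."""
        comp = self.component_logpdf(X) + np.log(self.weights_)
        return np.exp(comp - special.logsumexp(comp, axis=1, keepdims=True))

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None):
        comp = self.component_logpdf(X) + np.log(self.weights_)
        return float(special.logsumexp(comp, axis=1).sum())
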