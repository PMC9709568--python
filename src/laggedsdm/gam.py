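"""Penalized-spline Tweedie count regression with effort offsets.

The habitat-model core: counts of individuals per effort segment are
modelled as Tweedie (power 1 < p < 2: compound Poisson-gamma, handling
exact zeros and overdispersed positive totals) with a log link,

    E[y_i] = exp(log(a_i) + b0 + sum_j f_j(x_ij)),

where ``a_i = 2 ESW L_i`` is the effectively sampled area of segment i.
Each smooth f_j is a cubic spline with basis dimension 4, centred
(sum-to-zero over the calibration sample) for identifiability and
penalized by squared second differences of its coefficients; the shared
smoothing parameter is chosen by GCV (with the usual complexity
inflation gamma = 1.4 guarding against undersmoothing) on the Tweedie
deviance over a deterministic log-spaced grid.  The Tweedie log-likelihood (hence AIC)
is evaluated exactly with the Dunn-Smyth series expansion of the
density, with the dispersion estimated by the Pearson statistic and the
power profiled on a 1.1..1.9 grid when not fixed.

AIC is the penalized-model form -2 loglik + 2 (edf + 1), with edf the
trace of the influence matrix and one extra degree for the dispersion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, special

OFFSET_CONVENTION = "log(2 * ESW * segment_length_km)"
POWER_GRID = tuple(np.round(np.arange(1.1, 1.95, 0.1), 2))
ALPHA_GRID = tuple(np.logspace(-4, 6, 21))


class GamError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Tweedie density (Dunn-Smyth series) and deviance


def tweedie_loglik(y, mu, phi: float, p: float):
    """Elementwise log-density of the Tweedie(p) distribution, 1 < p < 2.

    Exact zeros have mass exp(-mu^(2-p) / (phi (2-p))); positive values
    use the series expansion of the compound Poisson-gamma density.
    """
    if not 1.0 < p < 2.0:
        raise GamError("Tweedie power must lie strictly between 1 and 2")
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta_part = (y * mu ** (1.0 - p) / (1.0 - p) - mu ** (2.0 - p) / (2.0 - p)) / phi
    out = np.array(theta_part, dtype=float)
    pos = y > 0
    if np.any(pos):
        yp = y[pos]
        a = (2.0 - p) / (p - 1.0)
        log_z = a * np.log(yp) - (1.0 + a) * np.log(phi) - np.log(2.0 - p) - a * np.log(p - 1.0)
        j_mode = np.maximum(yp ** (2.0 - p) / (phi * (2.0 - p)), 1.0)
        j_hi = int(min(max(3.0 * j_mode.max() + 30.0, 40.0), 3000.0))
        j = np.arange(1, j_hi + 1, dtype=float)[:, None]
        log_w = j * log_z[None, :] - special.gammaln(j + 1.0) - special.gammaln(a * j)
        out[pos] += special.logsumexp(log_w, axis=0) - np.log(yp)
    return out


def tweedie_deviance(y, mu, p: float):
    """Elementwise Tweedie unit deviance."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    term1 = np.where(y > 0, y ** (2.0 - p) / ((1.0 - p) * (2.0 - p)), 0.0)
    term2 = np.where(y > 0, y * mu ** (1.0 - p) / (1.0 - p), 0.0)
    return 2.0 * (term1 - term2 + mu ** (2.0 - p) / (2.0 - p))


# ---------------------------------------------------------------------------
# spline basis


K_BASIS = 4  # basis dimension per smooth (max complexity of each term)
_DEGREE = 3
_KNOTS = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])


def _raw_basis(u: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis (4 columns) on the unit interval, clamped ends."""
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    return interpolate.BSpline.design_matrix(u, _KNOTS, _DEGREE).toarray()


@dataclass
class SplineTerm:
    """One smooth term: scaled cubic basis with a sum-to-zero constraint."""

    name: str
    xmin: float
    xmax: float
    constraint: np.ndarray = field(repr=False)  # (K, K-1) null-space basis

    @classmethod
    def build(cls, name: str, x: np.ndarray) -> "SplineTerm":
        xmin, xmax = float(np.min(x)), float(np.max(x))
        if xmax <= xmin:
            raise GamError(f"term {name!r}: covariate has no variation")
        u = (x - xmin) / (xmax - xmin)
        c = _raw_basis(u).mean(axis=0)
        z = linalg.null_space(c[None, :])
        return cls(name, xmin, xmax, z)

    @property
    def n_coef(self) -> int:
        return self.constraint.shape[1]

    def design(self, x) -> np.ndarray:
        """Constrained basis; values beyond the calibration range clamp."""
        u = (np.asarray(x, dtype=float) - self.xmin) / (self.xmax - self.xmin)
        return _raw_basis(u) @ self.constraint

    def penalty(self) -> np.ndarray:
        d2 = np.diff(np.eye(K_BASIS), n=2, axis=0)
        s = self.constraint.T @ (d2.T @ d2) @ self.constraint
        return s / np.trace(s)


# ---------------------------------------------------------------------------
# penalized IRLS


def _build_design(terms: list[SplineTerm], data: pd.DataFrame) -> np.ndarray:
    cols = [np.ones((len(data), 1))]
    for t in terms:
        if t.name not in data.columns:
            raise GamError(f"missing covariate column {t.name!r}")
        cols.append(t.design(data[t.name].values))
    return np.hstack(cols)


def _penalty_matrix(terms: list[SplineTerm], alpha: float) -> np.ndarray:
    size = 1 + sum(t.n_coef for t in terms)
    pen = np.zeros((size, size))
    pos = 1
    for t in terms:
        k = t.n_coef
        pen[pos:pos + k, pos:pos + k] = alpha * t.penalty()
        pos += k
    return pen


def _pirls(y, X, pen, offset, p, term_names, max_iter=200, tol=1e-8, mu0=None):
    n = len(y)
    mu = np.maximum(mu0 if mu0 is not None else (y + np.mean(y) + 0.1) / 2.0, 1e-8)
    eta = np.log(mu)
    dev_old = np.inf
    trace = []
    for it in range(max_iter):
        wgt = mu ** (2.0 - p)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * wgt
        a = xtw @ X + pen
        try:
            beta = linalg.solve(a, xtw @ z, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise GamError(
                f"rank-deficient design (collinear terms among {term_names})"
            ) from exc
        eta = np.clip(offset + X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        dev = float(np.sum(tweedie_deviance(y, mu, p)))
        trace.append(dev)
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            h = linalg.solve(a, xtw @ X, assume_a="pos")
            return beta, mu, eta, dev, a, h, wgt
        dev_old = dev
    raise GamError(f"IRLS did not converge in {max_iter} iterations; deviance trace {trace[-5:]}")


@dataclass
class FittedHabitatModel:
    """A fitted penalized-spline Tweedie count model."""

    terms: list[SplineTerm]
    coef: np.ndarray
    cov: np.ndarray = field(repr=False)    # Bayesian posterior covariance
    power: float
    phi: float
    alpha: float
    edf_total: float
    edf_by_term: dict[str, float]
    loglik: float
    aic: float
    deviance_null: float
    deviance_resid: float
    n_obs: int
    response: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    offset_convention: str = OFFSET_CONVENTION

    @property
    def explained_deviance(self) -> float:
        if self.deviance_null <= 0:
            return 0.0
        return max(1.0 - self.deviance_resid / self.deviance_null, 0.0)

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def design(self, newdata: pd.DataFrame) -> np.ndarray:
        return _build_design(self.terms, newdata)

    def predict(self, newdata: pd.DataFrame, offset=None, se: bool = False):
        """Response-scale prediction; with ``offset=None`` the prediction is
        per unit area (offset area 1 km^2, i.e. log-offset 0)."""
        X = self.design(newdata)
        off = np.zeros(len(X)) if offset is None else np.asarray(offset, dtype=float)
        eta = off + X @ self.coef
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        if not se:
            return mu
        se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        return mu, mu * se_eta  # delta method on the response scale

    def to_json(self) -> str:
        payload = {
            "terms": [
                {"name": t.name, "xmin": t.xmin, "xmax": t.xmax,
                 "constraint": t.constraint.tolist()}
                for t in self.terms
            ],
            "coef": self.coef.tolist(),
            "cov": self.cov.tolist(),
            "power": self.power, "phi": self.phi, "alpha": self.alpha,
            "edf_total": self.edf_total, "edf_by_term": self.edf_by_term,
            "loglik": self.loglik, "aic": self.aic,
            "deviance_null": self.deviance_null, "deviance_resid": self.deviance_resid,
            "n_obs": self.n_obs,
            "response": np.asarray(self.response).tolist(),
            "fitted": np.asarray(self.fitted).tolist(),
            "offset_convention": self.offset_convention,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "FittedHabitatModel":
        d = json.loads(text)
        terms = [
            SplineTerm(t["name"], t["xmin"], t["xmax"], np.array(t["constraint"]))
            for t in d["terms"]
        ]
        return cls(
            terms=terms, coef=np.array(d["coef"]), cov=np.array(d["cov"]),
            power=d["power"], phi=d["phi"], alpha=d["alpha"],
            edf_total=d["edf_total"], edf_by_term=d["edf_by_term"],
            loglik=d["loglik"], aic=d["aic"],
            deviance_null=d["deviance_null"], deviance_resid=d["deviance_resid"],
            n_obs=d["n_obs"], response=np.array(d["response"]),
            fitted=np.array(d["fitted"]), offset_convention=d["offset_convention"],
        )


def _fit_at(y, X, terms, offset, p, alpha, mu0=None):
    pen = _penalty_matrix(terms, alpha)
    names = [t.name for t in terms]
    beta, mu, eta, dev, a, h, wgt = _pirls(y, X, pen, offset, p, names, mu0=mu0)
    edf_diag = np.diag(h)
    return beta, mu, dev, a, edf_diag, wgt


def fit_gam(covariates: pd.DataFrame, terms, response: str = "n_individuals",
            offset: str = "offset_area_km2", power: float | None = None,
            alpha: float | None = None, alphas=ALPHA_GRID) -> FittedHabitatModel:
    """Fit the penalized-spline Tweedie model.

    Parameters
    ----------
    covariates : table with one row per segment, holding the covariate
        columns, the count response and the offset area (km^2, positive).
    terms : covariate column names to give a smooth each (possibly empty
        for the null model).
    power : fixed Tweedie power in (1, 2); ``None`` profiles it over
        1.1..1.9 by the series log-likelihood.
    alpha : fixed smoothing parameter; ``None`` selects it by GCV over a
        log-spaced grid.

    Constant (zero-variance) covariates are dropped with a warning.
    """
    y = covariates[response].values.astype(float)
    off_area = covariates[offset].values.astype(float)
    if np.any(off_area <= 0):
        raise GamError("offset areas must be strictly positive")
    off = np.log(off_area)

    built: list[SplineTerm] = []
    for name in terms:
        if name not in covariates.columns:
            raise GamError(f"missing covariate column {name!r}")
        x = covariates[name].values.astype(float)
        if np.ptp(x) <= 0:
            warnings.warn(f"dropping constant covariate {name!r} (no variance)", stacklevel=2)
            continue
        built.append(SplineTerm.build(name, x))
    X = _build_design(built, covariates)

    def select_alpha(p_val, mu0=None):
        if alpha is not None or not built:
            return alpha if alpha is not None else 0.0, mu0
        best = (np.inf, None)
        mu_ws = mu0
        n = len(y)
        for a_try in alphas:
            try:
                _, mu_fit, dev, _, edf_diag, _ = _fit_at(y, X, built, off, p_val, a_try, mu0=mu_ws)
            except GamError:
                continue
            edf = float(edf_diag.sum())
            # gamma = 1.4 inflates the complexity cost, the standard guard
            # against occasional severe GCV undersmoothing
            gcv = n * dev / max(n - 1.4 * edf, 1.0) ** 2
            mu_ws = mu_fit
            if gcv < best[0]:
                best = (gcv, a_try)
        if best[1] is None:
            raise GamError("smoothing selection failed for every grid value")
        return best[1], mu_ws

    def loglik_of(p_val, a_val, mu0=None):
        beta, mu, dev, a_mat, edf_diag, wgt = _fit_at(y, X, built, off, p_val, a_val, mu0=mu0)
        edf = float(edf_diag.sum())
        pearson = float(np.sum((y - mu) ** 2 / mu**p_val))
        phi = pearson / max(len(y) - edf, 1.0)
        llf = float(np.sum(tweedie_loglik(y, mu, phi, p_val)))
        return llf, (beta, mu, dev, a_mat, edf_diag, wgt, phi)

    if power is None:
        a0, mu_ws = select_alpha(1.3)
        prof = [(loglik_of(p_try, a0, mu0=mu_ws)[0], p_try) for p_try in POWER_GRID]
        power = max(prof)[1]
    a_sel, mu_ws = select_alpha(power)
    llf, (beta, mu, dev, a_mat, edf_diag, wgt, phi) = loglik_of(power, a_sel, mu0=mu_ws)

    edf = float(edf_diag.sum())
    edf_by_term: dict[str, float] = {}
    pos = 1
    for t in built:
        edf_by_term[t.name] = float(edf_diag[pos:pos + t.n_coef].sum())
        pos += t.n_coef
    # Bayesian posterior covariance of the coefficients (penalty as prior)
    cov = phi * linalg.inv(a_mat)
    aic = -2.0 * llf + 2.0 * (edf + 1.0)

    # null deviance: intercept-only fit at the same power
    if built:
        Xn = np.ones((len(y), 1))
        _, _, _, dev_null, *_ = _pirls(y, Xn, np.zeros((1, 1)), off, power, ["intercept"])
    else:
        dev_null = dev
    return FittedHabitatModel(
        terms=built, coef=beta, cov=cov, power=float(power), phi=float(phi),
        alpha=float(a_sel), edf_total=edf, edf_by_term=edf_by_term,
        loglik=llf, aic=float(aic), deviance_null=float(dev_null),
        deviance_resid=float(dev), n_obs=len(y), response=y, fitted=mu,
    )


def predict_gam(model: FittedHabitatModel, newdata: pd.DataFrame):
    """Mean intensity (per km^2) and delta-method standard error per row."""
    return model.predict(newdata, se=True)


def rmse(model: FittedHabitatModel) -> float:
    """Root mean squared error of fitted vs observed counts."""
    return float(np.sqrt(np.mean((model.response - model.fitted) ** 2)))


def akaike_weights(aics, labels=None) -> pd.DataFrame:
    """Delta AIC, relative likelihood and Akaike weight for a model set.

    Non-finite AICs are excluded with a warning; weights sum to one over
    the finite models and the best model's delta is zero.
    """
    aics = np.asarray(list(aics), dtype=float)
    if labels is None:
        labels = list(range(len(aics)))
    finite = np.isfinite(aics)
    if not finite.any():
        raise GamError("no finite AIC values")
    if not finite.all():
        warnings.warn("excluding models with non-finite AIC", stacklevel=2)
    out = pd.DataFrame({"model": np.asarray(labels, dtype=object)[finite],
                        "aic": aics[finite]})
    out["delta_aic"] = out["aic"] - out["aic"].min()
    out["rel_likelihood"] = np.exp(-0.5 * out["delta_aic"])
    out["weight"] = out["rel_likelihood"] / out["rel_likelihood"].sum()
    return out.sort_values("aic", kind="mergesort").reset_index(drop=True)
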