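"""Per-channel GLM machinery: design matrix, short-channel nuisance regressors,
AR prewhitening, robust (Tukey biweight) regression, and BH-FDR correction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import signal, stats
from sklearn.decomposition import PCA
from statsmodels.regression.linear_model import yule_walker

from .errors import DesignError, ParameterError
from .hrf import task_regressor
from .preprocess import HemoSeries
from .recording import Channel, EventSchedule, Probe


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n_samples, k)
    labels: list[str]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.X[:, self.labels.index(label)]

    def with_columns(self, cols: np.ndarray, labels: list[str]) -> "DesignMatrix":
        cols = np.atleast_2d(np.asarray(cols, float))
        if cols.shape[0] != self.n_samples:
            cols = cols.T
        return DesignMatrix(np.column_stack([self.X, cols]), self.labels + labels)


def build_design_matrix(events: EventSchedule, sampling_rate: float,
                        n_samples: int, add_drift: bool = False,
                        **hrf_kw) -> DesignMatrix:
    """Intercept + HRF-convolved, peak-normalized task regressor (+ linear drift).

    Raises DesignError when a non-trivial task column makes the matrix rank
    deficient (e.g. an all-task schedule whose regressor is collinear with
    the intercept).
    """
    task = task_regressor(events, sampling_rate, n_samples, **hrf_kw)
    cols = [np.ones(n_samples), task]
    labels = ["intercept", "task"]
    if add_drift:
        cols.append(np.linspace(-0.5, 0.5, n_samples))
        labels.append("drift")
    X = np.column_stack(cols)
    if np.any(task != 0):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("design matrix is rank deficient")
        # an all-task schedule leaves only the onset transient to distinguish
        # the task column from the intercept; reject it as degenerate
        steady = task[min(len(task) - 1, int(32 * sampling_rate)):]
        if steady.size and np.ptp(steady) < 1e-8 * max(np.max(np.abs(task)), 1e-30):
            raise DesignError(
                "task regressor is constant in steady state (no rest epochs)")
    return DesignMatrix(X, labels)


def short_channel_regressors(hemo_short: HemoSeries, probe: Probe, strategy: str,
                             long_channels: tuple[Channel, ...] | None = None,
                             chromophore: str = "hbo",
                             pca_variance: float = 0.9
                             ) -> dict[str, np.ndarray]:
    """Nuisance regressor sets per long channel from the short channels.

    Strategies: ``nearest`` (the short channel whose source is nearest the
    long channel's source optode), ``all`` (every good short channel), and
    ``pca`` (principal components of the short channels up to
    ``pca_variance`` cumulative explained variance). Returns a mapping from
    long-channel name to an (n_samples, m) column block; empty mapping (with
    a warning) when no good short channel exists.
    """
    if strategy not in ("nearest", "all", "pca"):
        raise ParameterError(f"unknown short-channel strategy {strategy!r}")
    long_channels = long_channels if long_channels is not None else probe.long_channels
    mat = np.asarray(getattr(hemo_short, chromophore), float)
    if mat.shape[1] == 0:
        warnings.warn("no good short channels; skipping short-channel regression")
        return {}
    if strategy == "all":
        return {ch.name: mat.copy() for ch in long_channels}
    if strategy == "pca":
        n_comp = min(mat.shape[1], mat.shape[0] - 1)
        if n_comp == 1:
            comps = mat - mat.mean(axis=0)
        else:
            pca = PCA(n_components=pca_variance if n_comp > 1 else 1, svd_solver="full")
            comps = pca.fit_transform(mat)
        return {ch.name: comps.copy() for ch in long_channels}
    # nearest: short detectors sit under the sources, so distance is measured
    # from the long channel's source optode to each short channel's source
    out = {}
    short_pos = np.array([probe.optode_position(ch.source)
                          for ch in hemo_short.channels])
    for ch in long_channels:
        pos = probe.optode_position(ch.source)
        k = int(np.argmin(np.linalg.norm(short_pos - pos, axis=1)))
        out[ch.name] = mat[:, [k]].copy()
    return out


def _ar_information(resid: np.ndarray, order: int, ic: str) -> tuple[np.ndarray, float]:
    n = len(resid)
    if order == 0:
        sigma2 = float(np.mean(resid**2))
        rho = np.array([])
    else:
        rho, sigma = yule_walker(resid, order=order, method="mle")
        sigma2 = float(sigma**2)
    sigma2 = max(sigma2, 1e-300)
    penalty = 2.0 if ic == "aic" else np.log(n)
    return rho, n * np.log(sigma2) + penalty * order


def ar_prewhiten(y: np.ndarray, X: np.ndarray, max_order: int = 8,
                 ic: str = "bic") -> tuple[np.ndarray, np.ndarray, int]:
    """Prewhiten a series and its design with an AR filter fit to OLS residuals.

    AR coefficients come from Yule-Walker estimates on the OLS residuals; the
    order is selected in 0..max_order by an information criterion (BIC by
    default, "aic" selectable). The chosen AR filter is applied to ``y`` and
    to every column of ``X``; the first ``order`` samples are dropped.
    Non-stationary fits (characteristic roots on/inside the unit circle) are
    reduced in order until stable.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if max_order < 0:
        raise ParameterError("max_order must be >= 0")
    if max_order == 0:
        return y, X, 0
    if len(y) <= 10 * max_order:
        raise ParameterError("series too short for requested AR order")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if np.allclose(resid, 0):
        return y, X, 0
    best_order, best_ic, best_rho = 0, np.inf, np.array([])
    for p in range(max_order + 1):
        rho, crit = _ar_information(resid, p, ic)
        if crit < best_ic:
            best_order, best_ic, best_rho = p, crit, rho
    # stationarity guard: companion roots must lie inside the unit circle
    while best_order > 0:
        roots = np.roots(np.concatenate([[1.0], -best_rho]))
        if np.all(np.abs(roots) < 1 - 1e-8):
            break
        warnings.warn("non-stationary AR fit; reducing order")
        best_order -= 1
        best_rho = yule_walker(resid, order=best_order, method="mle")[0] \
            if best_order > 0 else np.array([])
    if best_order == 0:
        return y, X, 0
    a = np.concatenate([[1.0], -best_rho])
    yw = signal.lfilter(a, [1.0], y)[best_order:]
    Xw = signal.lfilter(a, [1.0], X, axis=0)[best_order:]
    return yw, Xw, best_order


def robust_glm(y: np.ndarray, X: np.ndarray, tukey_c: float = 4.685
               ) -> dict[str, np.ndarray]:
    """Robust GLM fit: IRLS with Tukey's biweight and MAD scale.

    Returns beta, se, t and two-sided p per column, with t referred to a
    Student distribution on n - rank(X) degrees of freedom. Near-perfect fits
    (robust scale ~ 0) fall back to the exact least-squares solution.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise DesignError("design matrix is rank deficient")
    if n <= k + 2:
        raise ParameterError("series too short for the design")
    df = n - rank

    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    scale = sm.robust.scale.mad(resid, center=0)
    yscale = max(1.0, float(np.max(np.abs(y)))) if y.size else 1.0
    if scale < 1e-12 * yscale:
        se = np.zeros(k)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(beta_ols == 0, 0.0, np.sign(beta_ols) * np.inf)
        p = np.where(beta_ols == 0, 1.0, 0.0)
        return {"beta": beta_ols, "se": se, "t": t, "p": p, "df": df,
                "converged": True}

    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=tukey_c))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=50, tol=1e-6, conv="coefs", scale_est="mad")
    beta = res.params
    se = res.bse
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return {"beta": beta, "se": se, "t": t, "p": p, "df": df,
            "converged": bool(getattr(res, "converged", True))}


def fdr_bh(p_values, q_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q_i = min_{j >= rank(i)} m p_(j) / j, capped
    at 1; reject iff q < q_threshold. Empty input gives empty output."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q < q_threshold
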