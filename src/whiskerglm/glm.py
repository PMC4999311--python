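"""Bernoulli GLM of spiking at 1 ms resolution.

The model: the probability of a spike in the 1 ms bin at time t is

    p(t) = f( beta_0 + sum_j sum_{t'=0}^{tau} alpha_j(t') x_j(t - t') ),
    f(u) = 1 / (1 + exp(-u)),

with one temporal filter alpha_j per predictor.  Each filter is expanded in
a small basis of log-time-stretched raised cosines b_l, alpha_j(t') =
sum_l b_l(t') beta_lj, which turns the fit into a convex logistic regression
on "convolved predictors" x~_lj(t) = sum_{t'} b_l(t') x_j(t - t').  Raw
predictors are whitened (zero mean, unit SD) before convolution so that
coefficients are comparable across predictors on different physical scales.

The default basis has five bumps peaking at 0, 1, 3, 8 and 17 ms, covering
75 ms of stimulus history.  The full model uses six predictors (30 convolved
columns + intercept = 31 coefficients); the mechanical and kinematic subset
models use three predictors each (16 coefficients).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .neural import SpikeTrain
from .predictors import KINEMATIC, MECHANICAL, PREDICTOR_NAMES, PredictorSet

__all__ = [
    "CosineBasis",
    "DesignMatrix",
    "GLMFit",
    "make_basis",
    "build_design",
    "fit",
    "predict",
    "crossval",
    "compute_sta",
    "sigmoid",
]

log = logging.getLogger(__name__)

SUBSETS = {
    "full": PREDICTOR_NAMES,
    "mechanical": MECHANICAL,
    "kinematic": KINEMATIC,
}


def sigmoid(u):
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


# ---------------------------------------------------------------------------
# raised-cosine basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CosineBasis:
    """Log-time-stretched raised cosine bumps sampled on 0..support ms."""

    functions: np.ndarray      # (L, support+1), each in [0, 1]
    peak_times_ms: tuple
    support_ms: int
    stretch: float             # a in a*log(t + c)
    offset: float              # c

    @property
    def n_funcs(self) -> int:
        return self.functions.shape[0]

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.support_ms + 1, dtype=float)


def make_basis(
    n_funcs: int = 5,
    peak_times_ms=(0.0, 1.0, 3.0, 8.0, 17.0),
    support_ms: int = 75,
) -> CosineBasis:
    """Construct the raised-cosine bump basis.

    Each bump is b_l(t) = (cos(clip(a*log(t + c) - phi_l, -pi, pi)) + 1)/2
    with phi_l = a*log(p_l + c), so every bump peaks exactly at its peak time
    p_l.  The two stretch parameters are solved numerically from: (i) the
    last bump reaches zero exactly at the support, and (ii) the warped peaks
    are spaced pi/2 apart on average (the standard tiling of this family).
    """
    peaks = tuple(float(p) for p in peak_times_ms)
    if len(peaks) != n_funcs:
        raise ValueError("need one peak time per basis function")
    if any(p2 <= p1 for p1, p2 in zip(peaks, peaks[1:])):
        raise ValueError("peak times must be strictly increasing")
    if peaks[0] < 0 or peaks[-1] >= support_ms:
        raise ValueError("peaks must lie in [0, support)")

    p_last, p_first = peaks[-1], peaks[0]
    if n_funcs == 1:
        c = 1.0
        a = np.pi / (np.log(support_ms + c) - np.log(p_last + c))
    else:
        # spacing condition reduces to a single equation in c
        def g(c):
            span = np.log(p_last + c) - np.log(p_first + c)
            tail = np.log(support_ms + c) - np.log(p_last + c)
            return span / (n_funcs - 1) - 0.5 * tail

        lo, hi = 1e-6, 1e6
        if g(lo) * g(hi) > 0:
            raise ValueError("cannot solve basis stretch for these peak times")
        c = brentq(g, lo, hi, xtol=1e-12)
        a = np.pi / (np.log(support_ms + c) - np.log(p_last + c))

    t = np.arange(support_ms + 1, dtype=float)
    warped = a * np.log(t + c)
    funcs = np.empty((n_funcs, t.size))
    for l, p in enumerate(peaks):
        phi = a * np.log(p + c)
        funcs[l] = 0.5 * (np.cos(np.clip(warped - phi, -np.pi, np.pi)) + 1.0)

    basis = CosineBasis(funcs, peaks, int(support_ms), float(a), float(c))
    grid_peaks = np.argmax(funcs, axis=1)
    if np.any(np.abs(grid_peaks - np.asarray(peaks)) > 0.5):
        raise ValueError("basis peaks missed the requested times on the ms grid")
    return basis


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Convolved-predictor design with intercept column.

    Columns: [1, x~_{l=1,j=1}, ..., x~_{l=L,j=1}, x~_{l=1,j=2}, ...] — the
    predictor index j is the outer loop, the basis index l the inner one.
    """

    X: np.ndarray              # (n_bins, 1 + L*K)
    predictor_names: tuple
    basis: CosineBasis
    whiten_mean: np.ndarray    # (K,)
    whiten_sd: np.ndarray      # (K,)
    contact: np.ndarray
    subset: str = "full"

    @property
    def n_coefficients(self) -> int:
        return self.X.shape[1]


def _causal_convolve(z: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """sum_{t'=0}^{tau} kernel(t') z(t - t'), zeros before the trial start."""
    return np.convolve(z, kernel)[: z.size]


def build_design(
    predictors: PredictorSet,
    basis: CosineBasis,
    subset: str = "full",
    whiten_scope: np.ndarray | None = None,
) -> DesignMatrix:
    """Whiten each raw predictor and convolve it with every basis function.

    ``whiten_scope`` optionally restricts the bins over which the whitening
    mean/SD are computed (e.g. a training split); statistics default to the
    whole recording.
    """
    names = SUBSETS[subset]
    raw = predictors.subset_values(names)
    if np.any(~np.isfinite(raw)):
        raise ValueError("non-finite predictor values; impute before building the design")
    scope = slice(None) if whiten_scope is None else whiten_scope
    mu = raw[scope].mean(axis=0)
    sd = raw[scope].std(axis=0)
    zero_var = sd < 1e-12
    if np.any(zero_var):
        bad = [names[i] for i in np.flatnonzero(zero_var)]
        raise ValueError(f"zero-variance predictor(s): {bad}")
    z = (raw - mu) / sd

    n = predictors.n_bins
    L = basis.n_funcs
    X = np.empty((n, 1 + L * len(names)))
    X[:, 0] = 1.0
    for j in range(len(names)):
        for l in range(L):
            X[:, 1 + j * L + l] = _causal_convolve(z[:, j], basis.functions[l])
    return DesignMatrix(
        X=X, predictor_names=tuple(names), basis=basis,
        whiten_mean=mu, whiten_sd=sd, contact=predictors.contact, subset=subset,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    coef: np.ndarray           # (1 + L*K,): [beta_0, beta_lj ...]
    predictor_names: tuple
    basis: CosineBasis
    subset: str
    log_likelihood: float
    converged: bool
    n_iter: int
    se: np.ndarray | None = None
    ridge: float = 1e-6
    whiten_mean: np.ndarray | None = None
    whiten_sd: np.ndarray | None = None

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def beta(self) -> np.ndarray:
        """Coefficients beta_lj as an (L, K) array (basis x predictor)."""
        L = self.basis.n_funcs
        K = len(self.predictor_names)
        return self.coef[1:].reshape(K, L).T

    def filters(self) -> dict[str, np.ndarray]:
        """Reconstructed temporal filters alpha_j(t') = sum_l b_l(t') beta_lj."""
        b = self.basis.functions
        return {
            name: b.T @ self.beta[:, j]
            for j, name in enumerate(self.predictor_names)
        }


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), stable via logaddexp
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit(
    design: DesignMatrix,
    spikes: SpikeTrain | np.ndarray,
    ridge: float = 1e-6,
    rows: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    init: np.ndarray | None = None,
) -> GLMFit:
    """Maximum-likelihood fit by damped Newton iteration (IRLS).

    ``ridge`` adds a tiny L2 penalty on the non-intercept coefficients for
    robustness against perfect separation; ridge=0 gives the pure MLE (which
    can diverge on separable data — the fit is then flagged unconverged with
    the runaway coefficients preserved).  ``rows`` restricts fitting to a
    subset of bins (used by cross-validation).
    """
    y = spikes.binary if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    y = y.astype(float)
    X = design.X
    if rows is not None:
        X = X[rows]
        y = y[rows]
    if y.sum() == 0:
        raise ValueError("no spikes in the training data")
    n, p = X.shape
    pen = np.full(p, ridge)
    pen[0] = 0.0  # never penalize the intercept

    beta = np.zeros(p) if init is None else np.array(init, dtype=float)
    eta = X @ beta
    ll = _bernoulli_ll(y, eta) - 0.5 * np.sum(pen * beta**2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = sigmoid(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - pen * beta
        h = (X.T * w) @ X
        h[np.diag_indices_from(h)] += pen + 1e-12
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            break
        # backtracking line search on the penalized log-likelihood
        t_step = 1.0
        for _ in range(30):
            cand = beta + t_step * step
            eta_c = X @ cand
            ll_c = _bernoulli_ll(y, eta_c) - 0.5 * np.sum(pen * cand**2)
            if ll_c >= ll - 1e-12:
                break
            t_step *= 0.5
        beta, eta, ll_prev, ll = cand, eta_c, ll, ll_c
        if np.max(np.abs(t_step * step)) < tol or abs(ll - ll_prev) < tol * (1 + abs(ll)):
            converged = True
            break

    mu = sigmoid(eta)
    w = mu * (1.0 - mu)
    h = (X.T * w) @ X
    h[np.diag_indices_from(h)] += pen + 1e-12
    try:
        se = np.sqrt(np.diag(np.linalg.inv(h)))
    except np.linalg.LinAlgError:
        se = None
    return GLMFit(
        coef=beta, predictor_names=design.predictor_names, basis=design.basis,
        subset=design.subset, log_likelihood=_bernoulli_ll(y, eta),
        converged=converged, n_iter=it, se=se, ridge=ridge,
        whiten_mean=design.whiten_mean, whiten_sd=design.whiten_sd,
    )


def predict(fitted: GLMFit, design: DesignMatrix) -> np.ndarray:
    """Per-bin spike probability p(t) from a fitted model."""
    if design.X.shape[1] != fitted.coef.size:
        raise ValueError("design column count does not match the fit")
    return sigmoid(design.X @ fitted.coef)


def predict_from_filters(fitted: GLMFit, predictors: PredictorSet) -> np.ndarray:
    """p(t) computed directly from the reconstructed filters alpha_j.

    Algebraically identical to ``predict`` on the convolved design (the
    basis expansion is exact); used as a consistency check.
    """
    names = fitted.predictor_names
    raw = predictors.subset_values(names)
    z = (raw - fitted.whiten_mean) / fitted.whiten_sd
    eta = np.full(predictors.n_bins, fitted.intercept)
    for j, name in enumerate(names):
        alpha = fitted.filters()[name]
        eta += _causal_convolve(z[:, j], alpha)
    return sigmoid(eta)


def crossval(
    design: DesignMatrix,
    spikes: SpikeTrain | np.ndarray,
    k: int = 10,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, list[GLMFit]]:
    """K-fold cross-validated prediction with contiguous temporal folds.

    Each fold's bins are predicted by a model fit on the other k-1 folds, so
    the returned series is a full-length out-of-fold prediction.
    """
    y = spikes.binary if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    n = design.X.shape[0]
    if y.size != n:
        raise ValueError("spike train length does not match the design")
    if k < 2:
        raise ValueError("need at least 2 folds")
    bounds = np.linspace(0, n, k + 1).astype(int)
    p_oof = np.empty(n)
    fits = []
    prev = None
    for i in range(k):
        test = np.zeros(n, dtype=bool)
        test[bounds[i]:bounds[i + 1]] = True
        if design.contact is not None and not design.contact[test].any():
            log.warning("crossval: fold %d contains no contact bins", i)
        f = fit(design, y, ridge=ridge, rows=~test,
                init=None if prev is None else prev.coef)
        p_oof[test] = sigmoid(design.X[test] @ f.coef)
        fits.append(f)
        prev = f
    return p_oof, fits


def compute_sta(
    predictors: PredictorSet,
    spikes: SpikeTrain,
    window_ms: int = 75,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Spike-triggered average of every predictor over [-window, 0] ms.

    Returns {name: (mean, sem)} with arrays of length window+1, index 0 being
    ``window`` ms before the spike.  Spikes closer than ``window`` to the
    trial start are skipped.
    """
    times = spikes.spike_times_ms
    if times.size == 0:
        raise ValueError("no spikes")
    if window_ms > predictors.n_bins:
        raise ValueError("window exceeds the trial length")
    valid = times[times >= window_ms]
    if valid.size == 0:
        raise ValueError("no spikes with a full pre-spike window")
    idx = valid[:, None] + np.arange(-window_ms, 1)[None, :]
    out = {}
    for j, name in enumerate(PREDICTOR_NAMES):
        segs = predictors.values[idx, j]
        mean = segs.mean(axis=0)
        sem = segs.std(axis=0, ddof=1) / np.sqrt(segs.shape[0]) if segs.shape[0] > 1 \
            else np.zeros_like(mean)
        out[name] = (mean, sem)
    return out
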