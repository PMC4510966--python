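"""Brownian-motion and multi-regime Ornstein–Uhlenbeck (Hansen) models.

The OU model follows the stochastic dynamics

    dX(t) = alpha * (theta - X(t)) dt + sigma * dB(t)

where ``alpha`` (1/Myr) is the pull toward the optimum ``theta`` of the
regime painting the current branch, and ``sigma**2`` is the Brownian
rate.  The root state is fixed at the root regime's optimum (the
standard ouch-style Hansen convention), so tip means are W @ theta with
W the exponentially discounted regime-weight matrix, and the tip
covariance has the fixed-root OU form, valid on non-ultrametric trees.

Fits profile sigma^2 analytically and the optima by GLS at each alpha,
reducing maximum-likelihood estimation to a bounded 1-D search on
log(alpha).  Model comparison uses the finite-sample AIC:

    AICc = -2 logL + 2 p + 2 p (p + 1) / (n - p - 1)

with Akaike weights proportional to exp(-dAICc / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import minimize_scalar

from .tree import PhyloTree, RegimePainting

__all__ = [
    "PhyloCovariance",
    "BMModel",
    "HansenModel",
    "ModelFit",
    "bm_covariance",
    "bm_loglik",
    "fit_bm",
    "hansen_weights",
    "ou_covariance",
    "hansen_loglik",
    "fit_hansen",
    "aicc",
    "compare_models",
    "multivariate_fit",
]

# below alpha * height ~ 1e-8 the OU covariance is evaluated through
# expm1, which degrades gracefully to the BM limit sigma^2 * C
ALPHA_FLOOR_SCALE = 1e-8
ALPHA_CEIL_SCALE = 1e3


@dataclass
class PhyloCovariance:
    tip_labels: list
    matrix: np.ndarray


@dataclass
class BMModel:
    sigma2: float
    mu: float


@dataclass
class HansenModel:
    painting: RegimePainting
    alpha: float
    sigma2: float
    theta: dict  # regime label -> optimum
    root_convention: str = "root at root-regime optimum"


@dataclass
class ModelFit:
    model: object
    loglik: float
    n_params: int
    n: int
    aicc: float
    name: str = ""
    flags: list = field(default_factory=list)
    delta_aicc: float | None = None
    akaike_weight: float | None = None
    per_trait: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "model_name": self.name,
            "logL": self.loglik,
            "p": self.n_params,
            "n": self.n,
            "AICc": self.aicc,
            "delta_aicc": self.delta_aicc,
            "weight": self.akaike_weight,
            "flags": list(self.flags),
        }
        if isinstance(self.model, HansenModel):
            d["painting"] = self.model.painting.to_dict()
        if self.per_trait:
            d["traits"] = []
            for name, fit in self.per_trait:
                m = fit.model
                if isinstance(m, HansenModel):
                    d["traits"].append(
                        {"trait": name, "alpha": m.alpha, "sigma2": m.sigma2,
                         "theta": dict(m.theta), "logL": fit.loglik}
                    )
                else:
                    d["traits"].append(
                        {"trait": name, "sigma2": m.sigma2, "mu": m.mu,
                         "logL": fit.loglik}
                    )
        return d


# ---------------------------------------------------------------------------
# covariances

def bm_covariance(tree: PhyloTree) -> PhyloCovariance:
    """C[i, j] = shared root-to-MRCA path length of tips i and j."""
    return PhyloCovariance(tree.tip_labels, tree.shared_depth_matrix().copy())


def ou_covariance(tree: PhyloTree, alpha: float, sigma2: float) -> PhyloCovariance:
    """Fixed-root OU tip covariance.

    V[i,j] = sigma^2/(2 alpha) * exp(-alpha (T_i + T_j - 2 s_ij))
             * (1 - exp(-2 alpha s_ij))

    with s_ij the shared path length and T_i the root-to-tip depth.
    Evaluated through expm1 so that alpha -> 0 tends continuously to
    the BM covariance sigma^2 * s_ij.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    S = tree.shared_depth_matrix()
    T = tree.depths()[tree.tips]
    D = T[:, None] + T[None, :] - 2.0 * S
    V = sigma2 * np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha)
    return PhyloCovariance(tree.tip_labels, V)


def _tip_path_segments(tree: PhyloTree, painting: RegimePainting, labels):
    """Flattened root-to-tip path segments for vectorized weight sums.

    Returns arrays (tip index, segment start depth, segment end depth,
    regime index) over all tips, plus the tip depth vector.  The
    geometry is cached on the tree; only the regime lookup depends on
    the painting.
    """
    tip_idx, starts, ends, branch = tree.path_segments()
    lab_index = {l: k for k, l in enumerate(labels)}
    regs = np.fromiter(
        (lab_index[painting.branch_regime[int(b)]] for b in branch),
        dtype=int,
        count=len(branch),
    )
    return tip_idx, starts, ends, regs, tree.depths()[tree.tips]


def hansen_weights(
    tree: PhyloTree, painting: RegimePainting, alpha: float, labels=None
) -> np.ndarray:
    """Tip-by-regime weight matrix W; tip means under Hansen are W @ theta.

    W[i, r] sums exp(-alpha (T_i - t_end)) - exp(-alpha (T_i - t_start))
    over the root-to-tip-i path segments painted r, and the residual
    root weight exp(-alpha T_i) accrues to the root regime (the root
    state being fixed at that regime's optimum).  Rows sum to one.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if labels is None:
        labels = painting.labels
    tip_idx, t0, t1, regs, T = _tip_path_segments(tree, painting, labels)
    W = np.zeros((tree.n_tips, len(labels)))
    contrib = np.exp(-alpha * (T[tip_idx] - t1)) - np.exp(-alpha * (T[tip_idx] - t0))
    np.add.at(W, (tip_idx, regs), contrib)
    W[:, list(labels).index(painting.root_label)] += np.exp(-alpha * T)
    return W


def _tree_matrices(tree: PhyloTree):
    """Cached (shared-depth S, tip depths T, distance D) for OU evaluation."""
    if "ou_geom" not in tree._cache:
        S = tree.shared_depth_matrix()
        T = tree.depths()[tree.tips]
        D = T[:, None] + T[None, :] - 2.0 * S
        tree._cache["ou_geom"] = (S, T, D)
    return tree._cache["ou_geom"]


# ---------------------------------------------------------------------------
# likelihoods

def _mvn_loglik(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    n = len(x)
    try:
        cho = linalg.cho_factor(cov, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular phylogenetic covariance ({exc}); check for duplicate or "
            "zero-length tips"
        ) from exc
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    r = x - mean
    q = float(r @ linalg.cho_solve(cho, r, check_finite=False))
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + q)


def bm_loglik(tree: PhyloTree, x, sigma2: float, mu: float) -> float:
    """Log density of tip data under BM with rate sigma2 and root state mu."""
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    xv = _as_tip_vector(tree, x)
    C = tree.shared_depth_matrix()
    return _mvn_loglik(xv, np.full(len(xv), mu), sigma2 * C)


def hansen_loglik(
    tree: PhyloTree,
    painting: RegimePainting,
    x,
    alpha: float,
    sigma2: float,
    theta,
) -> float:
    """Log density of tip data under the multi-regime OU model.

    ``theta`` maps regime labels to optima (or is a vector in painting
    label order).
    """
    xv = _as_tip_vector(tree, x)
    labels = painting.labels
    if isinstance(theta, dict):
        th = np.array([theta[l] for l in labels], dtype=float)
    else:
        th = np.asarray(theta, dtype=float)
    W = hansen_weights(tree, painting, alpha, labels)
    V = ou_covariance(tree, alpha, sigma2).matrix
    return _mvn_loglik(xv, W @ th, V)


def _as_tip_vector(tree: PhyloTree, x) -> np.ndarray:
    """Coerce a mapping/Series/array of tip values into tip order."""
    if hasattr(x, "loc") and hasattr(x, "index"):  # pandas Series
        missing = [l for l in tree.tip_labels if l not in x.index]
        if missing:
            raise KeyError(f"trait values missing for tips: {missing}")
        return np.asarray([float(x.loc[l]) for l in tree.tip_labels])
    if isinstance(x, dict):
        missing = [l for l in tree.tip_labels if l not in x]
        if missing:
            raise KeyError(f"trait values missing for tips: {missing}")
        return np.asarray([float(x[l]) for l in tree.tip_labels])
    xv = np.asarray(x, dtype=float)
    if xv.shape != (tree.n_tips,):
        raise ValueError(f"expected {tree.n_tips} tip values, got shape {xv.shape}")
    return xv


# ---------------------------------------------------------------------------
# fitting

def fit_bm(tree: PhyloTree, x, name: str = "BM") -> ModelFit:
    """ML Brownian-motion fit: GLS phylogenetic mean and profiled rate."""
    xv = _as_tip_vector(tree, x)
    n = len(xv)
    if n < 3:
        raise ValueError("BM fit needs at least 3 tips")
    C = tree.shared_depth_matrix()
    cho = linalg.cho_factor(C, lower=True, check_finite=False)
    one = np.ones(n)
    Ci1 = linalg.cho_solve(cho, one, check_finite=False)
    Cix = linalg.cho_solve(cho, xv, check_finite=False)
    mu = float(one @ Cix) / float(one @ Ci1)
    r = xv - mu
    q = float(r @ linalg.cho_solve(cho, r, check_finite=False))
    sigma2 = q / n
    flags = []
    if sigma2 <= 0 or not np.isfinite(sigma2):
        flags.append("degenerate: zero rate (constant trait)")
        sigma2 = 0.0
        ll = math.inf
    else:
        ll = _mvn_loglik(xv, np.full(n, mu), sigma2 * C)
    p = 2
    return ModelFit(BMModel(sigma2, mu), ll, p, n, _safe_aicc(ll, p, n, flags),
                    name, flags)


def _hansen_profile(xv, S, T, D, seg, labels, root_first, alpha):
    """Profiled (theta, sigma2, logL) at a fixed alpha.

    The covariance is evaluated at sigma^2 = 1 and rescaled: with
    V = sigma^2 V1, the GLS optima are free of sigma^2 and the profiled
    rate is the V1-quadratic-form mean of the residuals.
    """
    tip_idx, t0, t1, regs = seg
    n = len(xv)
    W = np.zeros((n, len(labels)))
    contrib = np.exp(-alpha * (T[tip_idx] - t1)) - np.exp(-alpha * (T[tip_idx] - t0))
    np.add.at(W, (tip_idx, regs), contrib)
    W[:, root_first] += np.exp(-alpha * T)
    V1 = np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha)
    # a non-root regime with no weight on any tip is unreachable (a
    # painting bug); the root column may legitimately decay to zero at
    # large alpha, where lstsq profiles it as rank-deficient
    col_mass = np.abs(W).sum(axis=0)
    bad = [labels[k] for k in np.flatnonzero(col_mass < 1e-12) if k != root_first]
    if bad:
        raise ValueError(f"regime(s) with no weight on any tip: {bad}")
    try:
        L = linalg.cholesky(V1, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    # whitened GLS: min ||L^-1 (x - W theta)||^2; lstsq keeps the profile
    # finite when the weight columns go collinear in the BM limit
    Wl = linalg.solve_triangular(L, W, lower=True, check_finite=False)
    xl = linalg.solve_triangular(L, xv, lower=True, check_finite=False)
    theta = np.linalg.lstsq(Wl, xl, rcond=None)[0]
    rl = xl - Wl @ theta
    q = float(rl @ rl)
    if q <= 0:
        return None
    sigma2 = q / n
    logdet1 = 2.0 * np.log(np.diag(L)).sum()
    ll = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet1 + n)
    return theta, sigma2, ll


def fit_hansen(
    tree: PhyloTree,
    painting: RegimePainting,
    x,
    name: str = "OU",
    alpha_tol: float = 1e-8,
) -> ModelFit:
    """ML multi-regime OU fit by bounded 1-D search on log(alpha).

    At each alpha the optima are profiled by GLS and sigma^2
    analytically; p = 2 + (number of regimes).  ``alpha_tol`` is the
    relative tolerance of the log-alpha search.
    """
    xv = _as_tip_vector(tree, x)
    n = len(xv)
    labels = painting.labels
    if n < len(labels) + 3:
        raise ValueError(
            f"need at least {len(labels) + 3} tips to fit {len(labels)} regimes"
        )
    S, T, D = _tree_matrices(tree)
    tip_idx, t0, t1, regs, _ = _tip_path_segments(tree, painting, labels)
    seg = (tip_idx, t0, t1, regs)
    root_first = labels.index(painting.root_label)
    h = tree.height
    lo, hi = math.log(ALPHA_FLOOR_SCALE / h), math.log(ALPHA_CEIL_SCALE / h)

    def neg_ll(loga: float) -> float:
        prof = _hansen_profile(xv, S, T, D, seg, labels, root_first, math.exp(loga))
        if prof is None:
            return np.inf
        return -prof[2]

    res = minimize_scalar(
        neg_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": alpha_tol * (hi - lo)},
    )
    # ties / flat profiles resolve toward smaller alpha
    best = res.x
    if neg_ll(lo) <= res.fun + 1e-12:
        best = lo
    alpha = math.exp(best)
    prof = _hansen_profile(xv, S, T, D, seg, labels, root_first, alpha)
    if prof is None:
        raise FloatingPointError("Hansen profile likelihood undefined at optimum")
    theta, sigma2, ll = prof
    flags = []
    if best <= lo + 1e-9 * (hi - lo):
        flags.append("alpha at lower bound: BM-like behaviour")
    if best >= hi - 1e-9 * (hi - lo):
        flags.append("alpha at upper bound: white-noise-like behaviour")
    p = 2 + len(labels)
    model = HansenModel(painting, alpha, sigma2, dict(zip(labels, theta)))
    return ModelFit(model, ll, p, n, _safe_aicc(ll, p, n, flags), name, flags)


def _safe_aicc(loglik: float, p: int, n: int, flags: list) -> float:
    """AICc, or +inf with a flag when n is too small for the penalty."""
    if n - p - 1 <= 0:
        flags.append(f"AICc undefined: n={n} too small for p={p}")
        return math.inf
    return aicc(loglik, p, n)


def aicc(loglik: float, p: int, n: int) -> float:
    """Finite-sample Akaike information criterion."""
    if n - p - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for p={p} parameters")
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def compare_models(fits: list[ModelFit]) -> list[ModelFit]:
    """Attach dAICc and Akaike weights; fits must share data (equal n)."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits are on different sample sizes: {sorted(ns)}")
    best = min(f.aicc for f in fits)
    deltas = np.array([f.aicc - best for f in fits])
    w = np.exp(-0.5 * deltas)
    w /= w.sum()
    for f, d, wi in zip(fits, deltas, w):
        f.delta_aicc = float(d)
        f.akaike_weight = float(wi)
    return fits


def multivariate_fit(
    tree: PhyloTree,
    painting: RegimePainting | None,
    X,
    model: str = "hansen",
    name: str = "",
    alpha_tol: float = 1e-8,
) -> ModelFit:
    """Shared-painting multivariate fit: traits independent given the painting.

    Each trait (column of ``X``, a DataFrame indexed by tip label) is
    fitted separately; the joint log-likelihood and parameter count are
    the sums, and the joint AICc uses n = tips x traits.
    """
    cols = list(X.columns)
    if not cols:
        raise ValueError("trait matrix has no columns")
    fits = []
    for c in cols:
        if model == "bm":
            fits.append(fit_bm(tree, X[c]))
        else:
            fits.append(fit_hansen(tree, painting, X[c], alpha_tol=alpha_tol))
    ll = sum(f.loglik for f in fits)
    p = sum(f.n_params for f in fits)
    n = tree.n_tips * len(cols)
    flags = [f"{c}: {fl}" for c, f in zip(cols, fits) for fl in f.flags]
    joint = ModelFit(
        fits[0].model if model == "bm" else HansenModel(
            painting,
            float(np.nan),
            float(np.nan),
            {},
        ),
        ll, p, n, aicc(ll, p, n), name or model, flags,
        per_trait=list(zip(cols, fits)),
    )
    return joint
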