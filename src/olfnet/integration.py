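"""Two-stage Elastic Net -> multi-set CCA integration of connectome edges,
behavioral outcomes, and risk traits.

Stage 1 screens the vectorized connectome (upper-triangle edge features,
log1p + z-score) by elastic-net regression onto the behavioral outcome
matrix, keeping edges with nonzero coefficients at the cross-validated
penalty.  Stage 2 fits the SUMCOR multi-set canonical correlation model

    max_{w_1..w_m}  sum_{i<j} corr(X_i w_i, X_j w_j)

subject to unit-variance canonical variates, by Horst-style alternating
updates (block coordinate ascent, monotone in the objective).  Inference is
by subject bootstrap (percentile CI on the summed correlation) and by
permutation of one domain's rows; the connectome-domain weights are
back-projected to region pairs and thresholded into a reportable
subnetwork.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .exceptions import ConfigurationError, DataIntegrityError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Connectome container and edge vectorization
# ---------------------------------------------------------------------------


@dataclass
class Connectome:
    """Labeled symmetric nonnegative streamline-count matrix."""

    region_labels: list
    adjacency: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise DataIntegrityError("adjacency must be square")
        if A.shape[0] != len(self.region_labels):
            raise DataIntegrityError("adjacency dimensions do not match labels")
        if not np.array_equal(A, A.T):
            raise DataIntegrityError("adjacency must be symmetric")
        if np.any(A < 0):
            raise DataIntegrityError("streamline counts must be nonnegative")
        if np.any(np.diag(A) != 0):
            raise DataIntegrityError("adjacency diagonal must be zero")
        self.adjacency = A


@dataclass
class EdgeFeatureMatrix:
    """Subjects x edges feature matrix with the edge bookkeeping needed to
    back-project weights into brain space."""

    X: np.ndarray
    edge_index: list  # (region_i, region_j) label pairs, i < j in atlas order
    transform_tag: str
    dropped_edges: list = field(default_factory=list)


def _standardize(X: np.ndarray) -> np.ndarray:
    """Column z-score; constant columns map to zero instead of NaN."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def vectorize_connectomes(connectomes) -> EdgeFeatureMatrix:
    """Stack upper-triangle (i < j, row-major) edges across subjects, apply
    log(1 + count), z-score each edge column, and drop zero-variance edges
    with a logged report."""
    if not connectomes:
        raise DataIntegrityError("no connectomes given")
    labels = connectomes[0].region_labels
    for c in connectomes:
        if list(c.region_labels) != list(labels):
            raise DataIntegrityError("connectomes have mismatched region labels")
    p = len(labels)
    iu = np.triu_indices(p, k=1)
    raw = np.stack([c.adjacency[iu] for c in connectomes]).astype(float)
    X = np.log1p(raw)
    pairs = [(labels[i], labels[j]) for i, j in zip(iu[0], iu[1])]

    keep = ~np.all(raw == raw[0], axis=0)  # exact constancy on the counts
    dropped = [pairs[k] for k in np.flatnonzero(~keep)]
    if dropped:
        logger.info("dropping %d zero-variance edges", len(dropped))
    X = _standardize(X[:, keep])
    kept_pairs = [pairs[k] for k in np.flatnonzero(keep)]
    return EdgeFeatureMatrix(X=X, edge_index=kept_pairs,
                             transform_tag="log1p+zscore", dropped_edges=dropped)


# ---------------------------------------------------------------------------
# Elastic net screening
# ---------------------------------------------------------------------------


@dataclass
class ElasticNetSpec:
    alpha: float = 0.5  # L1/L2 mixing weight
    lambda_grid: np.ndarray | None = None
    n_folds: int = 10
    seed: int = 0
    max_iter: int = 20000

    def grid(self) -> np.ndarray:
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if np.any(g < 0):
                raise ConfigurationError("lambda grid must be nonnegative")
            return g
        return np.logspace(-3, 1, 30)


def elastic_net_loss(beta, X, Y, lam: float, alpha: float = 0.5) -> float:
    """(1/2n)||Y - X beta||^2 + lambda (alpha ||beta||_1 + (1-alpha)/2 ||beta||^2)."""
    if lam < 0:
        raise ConfigurationError("lambda must be nonnegative")
    if not 0 <= alpha <= 1:
        raise ConfigurationError("alpha must be in [0, 1]")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float).reshape(len(X), -1)
    beta = np.asarray(beta, float).reshape(X.shape[1], -1)
    resid = Y - X @ beta
    n = X.shape[0]
    penalty = lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * (beta**2).sum())
    return float(0.5 / n * (resid**2).sum() + penalty)


@dataclass
class ElasticNetResult:
    coef: np.ndarray           # features x outcomes
    lambdas: np.ndarray        # chosen lambda per outcome
    selected: np.ndarray       # sorted union of nonzero-coefficient features
    fold_assignment: np.ndarray


def fit_elastic_net(X, Y, spec: ElasticNetSpec | None = None) -> ElasticNetResult:
    """Coordinate-descent elastic net per outcome column; for each outcome
    the penalty minimizing mean 10-fold CV MSE is chosen and features with
    nonzero coefficients in any outcome form the selected set.

    X is assumed column-standardized (as produced by
    :func:`vectorize_connectomes`); outcome columns are centered.  Constant
    outcomes raise an error."""
    spec = spec or ElasticNetSpec()
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n < 2 * spec.n_folds:
        raise ConfigurationError(
            f"need at least {2 * spec.n_folds} subjects for {spec.n_folds}-fold CV"
        )
    if np.any(Y.std(axis=0) == 0):
        raise DataIntegrityError("constant outcome column: elastic net is degenerate")
    Yc = Y - Y.mean(axis=0)

    cv = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    fold_assignment = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(cv.split(X)):
        fold_assignment[test] = f
    logger.info("elastic net: %d folds, seed %d", spec.n_folds, spec.seed)

    grid = np.sort(spec.grid())[::-1]
    coef = np.zeros((p, Y.shape[1]))
    lambdas = np.empty(Y.shape[1])
    for q in range(Y.shape[1]):
        model = ElasticNetCV(
            l1_ratio=spec.alpha, alphas=grid, cv=cv, fit_intercept=False,
            max_iter=spec.max_iter, tol=1e-8,
        )
        model.fit(X, Yc[:, q])
        coef[:, q] = model.coef_
        lambdas[q] = model.alpha_
    selected = np.flatnonzero(np.any(coef != 0, axis=1))
    return ElasticNetResult(coef=coef, lambdas=lambdas, selected=selected,
                            fold_assignment=fold_assignment)


def elastic_net_path_fit(X, y, lam: float, alpha: float = 0.5,
                         max_iter: int = 20000):
    """Single coordinate-descent fit at a fixed penalty (no CV)."""
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                       max_iter=max_iter, tol=1e-10)
    model.fit(np.asarray(X, float), np.asarray(y, float))
    return model.coef_


# ---------------------------------------------------------------------------
# SUMCOR multi-set CCA (Horst alternating updates)
# ---------------------------------------------------------------------------


@dataclass
class MCCAModel:
    weights: list            # per-domain canonical vectors
    variates: np.ndarray     # subjects x domains canonical scores (unit variance)
    pairwise_corr: np.ndarray
    sumcor: float
    converged: bool
    n_iter: int
    history: np.ndarray      # sumcor per sweep (monotone non-decreasing)


def _unit_variance(Xw: np.ndarray, w: np.ndarray):
    sd = Xw.std(ddof=1)
    if sd == 0:
        return Xw, w
    return Xw / sd, w / sd


def fit_mcca(domains, tol: float = 1e-8, max_iter: int = 500,
             ridge: float = 1e-8, method: str = "sumcor") -> MCCAModel:
    """Fit the first multi-set canonical component.

    SUMCOR (default): Horst block-coordinate ascent — each sweep updates
    every domain's weight vector to maximize its variate's summed
    correlation with the other current variates, subject to unit sample
    variance; each update solves a ridge-stabilized normal system, so the
    objective is non-decreasing.  Initialization is the leading right
    singular vector of each domain (deterministic).  Sign convention: the
    largest-|weight| entry of the first domain is positive (a global sign
    flip, which leaves all pairwise correlations unchanged).

    ``method='maxvar'`` instead solves the classical largest-eigenvalue
    formulation via a generalized eigenproblem on the block covariance.

    Non-convergence within ``max_iter`` sweeps is flagged on the returned
    model, not raised."""
    if len(domains) < 2:
        raise ConfigurationError("MCCA needs at least 2 domains")
    Xs = [_standardize(np.asarray(X, float)) for X in domains]
    n = Xs[0].shape[0]
    for X in Xs:
        if X.shape[0] != n:
            raise DataIntegrityError("domains have unequal subject counts")
    if method == "maxvar":
        return _fit_maxvar(Xs, ridge)
    if method != "sumcor":
        raise ConfigurationError(f"unknown MCCA method {method!r}")

    m = len(Xs)
    covs = [X.T @ X / (n - 1) for X in Xs]
    sols = []
    for X, S in zip(Xs, covs):
        # deterministic init: leading right singular vector, unit-variance variate
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        w = vt[0]
        z = X @ w
        z, w = _unit_variance(z, w)
        sols.append([w, z])

    def sumcor_of(variates):
        c = np.corrcoef(np.stack(variates))
        return float(np.triu(c, 1).sum())

    history = [sumcor_of([z for _, z in sols])]
    converged = False
    it = 0
    eyes = [ridge * np.eye(S.shape[0]) for S in covs]
    for it in range(1, max_iter + 1):
        for k in range(m):
            target = np.sum([sols[j][1] for j in range(m) if j != k], axis=0)
            b = Xs[k].T @ target / (n - 1)
            w = np.linalg.solve(covs[k] + eyes[k], b)
            z = Xs[k] @ w
            if z.std(ddof=1) == 0:
                continue  # degenerate update; keep previous weights
            z, w = _unit_variance(z, w)
            sols[k] = [w, z]
        history.append(sumcor_of([z for _, z in sols]))
        if history[-1] < history[-2] - 1e-10:
            raise RuntimeError(
                f"SUMCOR objective decreased at sweep {it}: "
                f"{history[-2]:.12f} -> {history[-1]:.12f}"
            )
        if abs(history[-1] - history[-2]) < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCCA did not converge in %d sweeps", max_iter)

    weights = [w for w, _ in sols]
    variates = np.stack([z for _, z in sols], axis=1)
    w0 = weights[0]
    if w0[np.argmax(np.abs(w0))] < 0:
        weights = [-w for w in weights]
        variates = -variates
    C = np.corrcoef(variates.T)
    return MCCAModel(weights=weights, variates=variates, pairwise_corr=C,
                     sumcor=float(np.triu(C, 1).sum()), converged=converged,
                     n_iter=it, history=np.asarray(history))


def _fit_maxvar(Xs, ridge):
    from scipy.linalg import eigh

    n = Xs[0].shape[0]
    sizes = [X.shape[1] for X in Xs]
    Xall = np.hstack(Xs)
    C = Xall.T @ Xall / (n - 1)
    D = np.zeros_like(C)
    off = 0
    for X, p in zip(Xs, sizes):
        D[off:off + p, off:off + p] = X.T @ X / (n - 1) + ridge * np.eye(p)
        off += p
    vals, vecs = eigh(C, D)
    v = vecs[:, -1]
    weights, variates = [], []
    off = 0
    for X, p in zip(Xs, sizes):
        w = v[off:off + p]
        z = X @ w
        z, w = _unit_variance(z, w)
        weights.append(w)
        variates.append(z)
        off += p
    variates = np.stack(variates, axis=1)
    w0 = weights[0]
    if w0[np.argmax(np.abs(w0))] < 0:
        weights = [-w for w in weights]
        variates = -variates
    Cp = np.corrcoef(variates.T)
    return MCCAModel(weights=weights, variates=variates, pairwise_corr=Cp,
                     sumcor=float(np.triu(Cp, 1).sum()), converged=True,
                     n_iter=1, history=np.asarray([float(np.triu(Cp, 1).sum())]))


# ---------------------------------------------------------------------------
# Resampling inference
# ---------------------------------------------------------------------------


@dataclass
class ResamplingResult:
    sumcor_observed: float
    bootstrap_draws: np.ndarray
    ci95: tuple
    permutation_draws: np.ndarray
    permutation_p: float


def resample_sumcor(domains, B: int = 1000, P: int = 10000, seed: int = 0,
                    permute_domain: int = 1, domain_builder=None,
                    **mcca_kwargs) -> ResamplingResult:
    """Bootstrap CI and permutation p-value for the summed canonical
    correlation.

    Bootstrap: resample subjects with replacement, refit MCCA on the fixed
    (already selected) feature columns, percentile 95% CI.  Passing
    ``domain_builder`` (a callable mapping a subject index array to fresh
    domain matrices) instead re-runs upstream steps — e.g. elastic-net
    selection — inside every resample, at the corresponding cost.
    Permutation: shuffle the rows of one domain (default the second, i.e.
    behavior), breaking all of its pairwise couplings symmetrically;
    p = (1 + #{perm >= observed}) / (P + 1)."""
    if B < 100:
        logger.warning("B=%d bootstrap draws is low; CI will be noisy", B)
    rng = np.random.default_rng(seed)
    Xs = [np.asarray(X, float) for X in domains]
    n = Xs[0].shape[0]
    observed = fit_mcca(Xs, **mcca_kwargs).sumcor

    boot = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        resampled = (domain_builder(idx) if domain_builder is not None
                     else [X[idx] for X in Xs])
        boot[b] = fit_mcca(resampled, **mcca_kwargs).sumcor
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    if not ci[0] <= observed <= ci[1]:
        logger.info(
            "observed sumcor %.4f outside bootstrap CI [%.4f, %.4f] — "
            "expected under optimism when features are many relative to subjects",
            observed, ci[0], ci[1])

    perm = np.empty(P)
    for b in range(P):
        idx = rng.permutation(n)
        perm_domains = [X if k != permute_domain else X[idx] for k, X in enumerate(Xs)]
        perm[b] = fit_mcca(perm_domains, **mcca_kwargs).sumcor
    p = (1.0 + np.sum(perm >= observed)) / (P + 1.0)
    return ResamplingResult(sumcor_observed=observed, bootstrap_draws=boot,
                            ci95=ci, permutation_draws=perm, permutation_p=float(p))


# ---------------------------------------------------------------------------
# Back-projection and thresholding
# ---------------------------------------------------------------------------


@dataclass
class SubnetworkResult:
    retained_edges: list     # (region_a, region_b, weight), |weight| descending
    stagecounts: tuple       # (n after EN, n after MCCA, n after threshold)
    weight_threshold: float


def backproject_and_threshold(model: MCCAModel, edge_index, threshold: float = 0.05,
                              domain: int = 0, mcca_cutoff: float = 1e-3) -> SubnetworkResult:
    """Map the connectome-domain canonical weights back to region pairs.

    Both cutoffs apply to the canonical weights on their natural scale
    (the variate has unit sample variance): entries with
    |w| <= ``mcca_cutoff`` count as zeroed by the canonical fit, and the
    remaining edges are thresholded at ``threshold``.  Stage counts record
    the EN-selected / MCCA-nonzero / post-threshold sizes."""
    w = np.asarray(model.weights[domain], float)
    if len(w) != len(edge_index):
        raise ConfigurationError(
            f"weight vector has {len(w)} entries but edge_index has {len(edge_index)}"
        )
    n_en = len(w)
    nonzero = np.abs(w) > mcca_cutoff
    retained_mask = np.abs(w) >= threshold
    order = np.argsort(-np.abs(w), kind="stable")
    retained = [
        (edge_index[k][0], edge_index[k][1], float(w[k]))
        for k in order if retained_mask[k]
    ]
    return SubnetworkResult(
        retained_edges=retained,
        stagecounts=(n_en, int(nonzero.sum()), int(retained_mask.sum())),
        weight_threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Trait encoding for the risk-trait MCCA domain
# ---------------------------------------------------------------------------


def encode_traits(traits: pd.DataFrame,
                  factors=("apoe", "diet", "sex", "age_group", "nos2")) -> np.ndarray:
    """One-hot encode categorical risk traits with sum-to-zero centering,
    then column-standardize (the MCCA entry format)."""
    cols = []
    for f in factors:
        levels = sorted(traits[f].unique().tolist())
        for lev in levels[:-1]:  # full-rank: drop one level per factor
            cols.append((traits[f] == lev).astype(float).to_numpy())
    X = np.stack(cols, axis=1)
    X = X - X.mean(axis=0)
    return _standardize(X)
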