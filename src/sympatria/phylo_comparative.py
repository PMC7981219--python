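"""Continuous-trait evolution models, phylogenetic signal, and dispersion.

All model fits are Gaussian phylogenetic GLS computations on the tree's
variance-covariance matrix C (shared root-to-MRCA path lengths):

* BM: x ~ N(mu 1, sigma2 C); mu and sigma2 have closed forms.
* OU (ultrametric trees): V_ij = sigma2/(2 alpha) e^{-2 alpha d_ij}
  (1 - e^{-2 alpha t_ij}) with d_ij the MRCA-to-tip height and t_ij the MRCA
  depth; alpha -> 0 recovers BM.
* EB: rate decays as sigma2 e^{r t}; C_ij -> (e^{r t_ij} - 1)/r.
* Pagel's lambda: off-diagonal elements of C scaled by lambda in [0, 1].

sigma2 and the root are concentrated out analytically, so OU/EB/lambda are
one-dimensional bounded searches from multiple deterministic starts.
Assemblage dispersion uses mean pairwise patristic distance (MPD) against a
tip-label-shuffling null.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .occurrence_io import TraitTable
from .trees import Phylogeny
from .utils import StatResult, ValidationError

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# profiled Gaussian likelihood
# ---------------------------------------------------------------------------
def _profile_gls(V: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """(mu_hat, sigma2_hat, logL) for x ~ N(mu 1, sigma2 V), ML over mu and sigma2."""
    n = len(x)
    cf = linalg.cho_factor(V, lower=True)
    one = np.ones(n)
    Vi1 = linalg.cho_solve(cf, one)
    mu = float(one @ linalg.cho_solve(cf, x) / (one @ Vi1))
    resid = x - mu
    quad = float(resid @ linalg.cho_solve(cf, resid))
    sigma2 = quad / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if sigma2 <= 0:
        return mu, 0.0, np.inf  # degenerate: all residual variance vanished
    logL = -0.5 * (n * _LOG2PI + n * np.log(sigma2) + logdet + n)
    return mu, sigma2, logL


@dataclass
class ComparativeFit:
    model: str  # BM | OU | EB
    sigma2: float
    root_state: float
    log_likelihood: float
    alpha: float | None = None  # OU pull strength (1/length)
    r: float | None = None  # EB rate-decay exponent (1/length)
    converged: bool = True

    def as_row(self) -> dict:
        return {
            "model": self.model, "sigma2": self.sigma2, "alpha": self.alpha, "r": self.r,
            "root_state": self.root_state, "log_likelihood": self.log_likelihood,
            "converged": self.converged,
        }


def bm_fit(tree: Phylogeny, traits: TraitTable | dict) -> ComparativeFit:
    """Closed-form ML Brownian-motion fit (no iteration)."""
    svl = traits.svl_mm if isinstance(traits, TraitTable) else traits
    x = tree.trait_vector(svl)
    C = tree.vcv()
    if tree.depth() <= 0:
        raise ValidationError("tree has zero depth")
    mu, sigma2, logL = _profile_gls(C, x)
    return ComparativeFit("BM", sigma2, mu, logL, converged=True)


def _ou_corr(C: np.ndarray, T: float, alpha: float) -> np.ndarray:
    if alpha == 0.0:
        return C
    height = T - C  # MRCA-to-tip height (ultrametric)
    # expm1 keeps the alpha -> 0 limit numerically continuous
    return np.exp(-2.0 * alpha * height) * (-np.expm1(-2.0 * alpha * C)) / (2.0 * alpha)


def _eb_corr(C: np.ndarray, r: float) -> np.ndarray:
    if r == 0.0:
        return C
    return np.expm1(r * C) / r


def _fit_1d(tree, traits, model, corr, bounds, starts) -> ComparativeFit:
    svl = traits.svl_mm if isinstance(traits, TraitTable) else traits
    x = tree.trait_vector(svl)

    def nll(theta: float) -> float:
        V = corr(theta)
        try:
            return -_profile_gls(V, x)[2]
        except linalg.LinAlgError:
            return np.inf

    best_theta, best_val, ok = None, np.inf, False
    for t0 in starts:
        res = optimize.minimize(lambda v: nll(v[0]), [t0], method="L-BFGS-B",
                                bounds=[bounds])
        if res.fun < best_val - 1e-10:
            best_theta, best_val, ok = float(res.x[0]), float(res.fun), bool(res.success)
        elif abs(res.fun - best_val) <= 1e-6:
            ok = ok or bool(res.success)
    # bounds themselves are admissible optima (alpha = 0 reduces to BM)
    for edge in bounds:
        v = nll(edge)
        if v < best_val - 1e-10:
            best_theta, best_val, ok = float(edge), float(v), True
    mu, sigma2, logL = _profile_gls(corr(best_theta), tree.trait_vector(svl))
    fit = ComparativeFit(model, sigma2, mu, logL, converged=ok)
    if model == "OU":
        fit.alpha = best_theta
    else:
        fit.r = best_theta
    return fit


def ou_fit(tree: Phylogeny, traits: TraitTable | dict) -> ComparativeFit:
    """Ornstein-Uhlenbeck fit (requires an ultrametric tree)."""
    if not tree.is_ultrametric(1e-6):
        raise ValidationError("OU fit requires an ultrametric tree")
    C = tree.vcv()
    T = tree.depth()
    starts = [0.0, 0.1 / T, 0.5 / T, 2.0 / T, 10.0 / T]
    return _fit_1d(tree, traits, "OU", lambda a: _ou_corr(C, T, a), (0.0, 50.0 / T), starts)


def eb_fit(tree: Phylogeny, traits: TraitTable | dict) -> ComparativeFit:
    """Early-burst fit: exponentially decaying (r < 0) or rising rate."""
    C = tree.vcv()
    T = tree.depth()
    starts = [-5.0 / T, -1.0 / T, 0.0, 1.0 / T, 5.0 / T]
    return _fit_1d(tree, traits, "EB", lambda r: _eb_corr(C, r), (-10.0 / T, 10.0 / T), starts)


@dataclass
class LambdaFit:
    lambda_: float
    log_likelihood: float
    sigma2: float
    root_state: float


def pagels_lambda(tree: Phylogeny, traits: TraitTable | dict) -> LambdaFit:
    """ML Pagel's lambda in [0, 1] by profile search (sigma2, root concentrated out)."""
    svl = traits.svl_mm if isinstance(traits, TraitTable) else traits
    x = tree.trait_vector(svl)
    C = tree.vcv()
    D = np.diag(np.diag(C))

    def V(lam: float) -> np.ndarray:
        return lam * C + (1.0 - lam) * D

    def nll(lam: float) -> float:
        try:
            return -_profile_gls(V(lam), x)[2]
        except linalg.LinAlgError:
            return np.inf

    res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    cands = [(nll(0.0), 0.0), (nll(1.0), 1.0), (float(res.fun), float(res.x))]
    best_val, best_lam = min(cands)
    mu, sigma2, logL = _profile_gls(V(best_lam), x)
    return LambdaFit(best_lam, logL, sigma2, mu)


# ---------------------------------------------------------------------------
# ancestral states and PGLS
# ---------------------------------------------------------------------------
@dataclass
class AncestralStates:
    """Internal-node conditional expectations under the fitted BM model."""

    estimates: dict[str, float]
    variances: dict[str, float]
    root_label: str

    @property
    def root(self) -> float:
        return self.estimates[self.root_label]


def _node_labels(tree: Phylogeny) -> dict:
    """Stable labels for internal nodes: existing label or nd<preorder index>."""
    labels = {}
    for i, node in enumerate(tree.dendropy_tree.preorder_node_iter()):
        if node.is_leaf():
            continue
        labels[id(node)] = node.label if node.label else f"nd{i}"
    return labels


def ancestral_states_bm(tree: Phylogeny, traits: TraitTable | dict) -> AncestralStates:
    """GLS ancestral states: conditional means/variances of internal nodes given tips."""
    svl = traits.svl_mm if isinstance(traits, TraitTable) else traits
    fit = bm_fit(tree, svl)
    x = tree.trait_vector(svl)
    C = tree.vcv()
    depths = tree.node_depths()
    dt = tree.dendropy_tree
    labels = _node_labels(tree)
    tip_index = {lab: i for i, lab in enumerate(tree.tip_labels)}

    # ancestor id chains let us find MRCA depth for (internal, tip) pairs
    anc_chain: dict[int, list[int]] = {}
    for node in dt.preorder_node_iter():
        parent = node.parent_node
        anc_chain[id(node)] = (anc_chain[id(parent)] + [id(parent)]) if parent else []

    internals = [n for n in dt.preorder_node_iter() if not n.is_leaf()]
    tips = {id(l): l.taxon.label for l in dt.leaf_node_iter()}
    m = len(internals)
    n = len(x)
    Sat = np.zeros((m, n))  # cov(internal, tip) / sigma2
    Saa = np.zeros(m)
    for a, node in enumerate(internals):
        Saa[a] = depths[id(node)]
        node_anc = set(anc_chain[id(node)]) | {id(node)}
        for leaf in dt.leaf_node_iter():
            j = tip_index[tips[id(leaf)]]
            # MRCA = deepest shared ancestor of the internal node and the tip
            shared = [nid for nid in anc_chain[id(leaf)] + [id(leaf)] if nid in node_anc]
            mrca_depth = max(depths[nid] for nid in shared)
            Sat[a, j] = mrca_depth
    cf = linalg.cho_factor(C, lower=True)
    resid = x - fit.root_state
    est = fit.root_state + Sat @ linalg.cho_solve(cf, resid)
    var = fit.sigma2 * (Saa - np.einsum("ij,ji->i", Sat, linalg.cho_solve(cf, Sat.T)))
    estimates = {labels[id(node)]: float(est[a]) for a, node in enumerate(internals)}
    variances = {labels[id(node)]: float(max(var[a], 0.0)) for a, node in enumerate(internals)}
    return AncestralStates(estimates, variances, labels[id(dt.seed_node)])


def pgls_residuals(tree: Phylogeny, traits: TraitTable | dict) -> dict[str, float]:
    """Intercept-only PGLS under BM: residual = trait - GLS grand mean.

    With no predictor, the residuals are phylogenetically detrended body
    sizes; the GLS mean equals the BM root estimate.
    """
    svl = traits.svl_mm if isinstance(traits, TraitTable) else traits
    fit = bm_fit(tree, svl)
    x = tree.trait_vector(svl)
    return {lab: float(v) for lab, v in zip(tree.tip_labels, x - fit.root_state)}


# ---------------------------------------------------------------------------
# assemblage dispersion
# ---------------------------------------------------------------------------
def mpd(assemblage, tree: Phylogeny) -> float:
    """Mean pairwise patristic distance over unordered pairs; nan below 2 species."""
    members = sorted(set(assemblage) & set(tree.tip_labels))
    if len(members) < 2:
        return float("nan")
    idx = [tree.tip_labels.index(s) for s in members]
    D = tree.patristic_matrix()[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), 1)
    return float(D[iu].mean())


@dataclass
class MPDResult:
    region: object
    observed_mpd: float
    null_mean: float
    null_sd: float
    ses: float
    p_quantile: float
    n_null: int
    degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "region": self.region, "observed_mpd": self.observed_mpd,
            "null_mean": self.null_mean, "null_sd": self.null_sd, "ses": self.ses,
            "p_quantile": self.p_quantile, "n_null": self.n_null, "degenerate": self.degenerate,
        }


def mpd_ses(
    assemblages: dict, tree: Phylogeny, n_null: int = 999, seed: int = 1
) -> list[MPDResult]:
    """MPD standardized effect sizes against a tip-label-shuffling null.

    The pool is the union of assemblage members found on the tree; each null
    draw permutes tip labels within the pool and recomputes every
    assemblage's MPD. Negative SES = phylogenetic clustering. p_quantile uses
    the (r+1)/(n+1) rank convention.
    """
    tips = tree.tip_labels
    pool = sorted(set().union(*assemblages.values()) & set(tips))
    if len(pool) < 3:
        raise ValidationError("species pool too small for a shuffling null")
    pool_idx = {sp: i for i, sp in enumerate(pool)}
    tip_idx = {sp: tips.index(sp) for sp in pool}
    D = tree.patristic_matrix()[np.ix_([tip_idx[s] for s in pool], [tip_idx[s] for s in pool])]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(len(pool)) for _ in range(n_null)])
    results = []
    for region in sorted(assemblages, key=str):
        members = sorted(set(assemblages[region]) & set(tips))
        if len(members) < 2:
            results.append(MPDResult(region, float("nan"), float("nan"), float("nan"),
                                     float("nan"), float("nan"), n_null, degenerate=True))
            continue
        mi = np.array([pool_idx[s] for s in members])
        iu = np.triu_indices(len(mi), 1)
        obs = float(D[np.ix_(mi, mi)][iu].mean())
        null_members = perms[:, mi]  # (n_null, k) pool indices under shuffled labels
        sub = D[null_members[:, :, None], null_members[:, None, :]]
        nulls = sub[:, iu[0], iu[1]].mean(axis=1)
        null_mean = float(nulls.mean())
        null_sd = float(nulls.std(ddof=1))
        p = float((np.sum(nulls <= obs) + 1) / (n_null + 1))
        if null_sd <= 1e-10 * max(1.0, abs(null_mean)):
            results.append(MPDResult(region, obs, null_mean, 0.0, float("nan"), p,
                                     n_null, degenerate=True))
        else:
            results.append(MPDResult(region, obs, null_mean, null_sd,
                                     (obs - null_mean) / null_sd, p, n_null))
    return results


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------
def correlate(x, y, method: str = "pearson") -> StatResult:
    """Two-sided correlation test; df = n - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("correlate needs equal-length vectors, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("correlate requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(f"{method}", np.nan, len(x) - 2, np.nan, defined=False)
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return StatResult(method, float(r.statistic), len(x) - 2, float(r.pvalue))
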