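"""Discrete-region ancestral state reconstruction on a fixed time tree.

The dispersal of a lineage among K geographic regions is modelled as a
continuous-time Markov chain with rate matrix Q; tip regions are observed
and the marginal probability of each region at every internal node is
computed by Felsenstein's pruning algorithm combined with an
outside (pre-order) pass — empirical-Bayes marginals on a *fixed* tree.

This is a deliberate, documented simplification: it does not integrate
over tree topology or divergence-time uncertainty the way a joint
Bayesian reconstruction (e.g. BEAST-style MCMC) does.  Downstream
lineage-diversity code accepts externally produced node probabilities for
exact reproduction work; this module exists so the whole pipeline runs
from tip data alone.

Model surface follows the statsmodels convention::

    model = AncestralStateModel(tree, tip_regions, regions=DEFAULT_REGIONS)
    res = model.fit()
    res.rate, res.llf, res.converged
    post = res.state_posterior()     # StatePosterior over all nodes
    print(res.summary())
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .regions import DEFAULT_REGIONS, RegionSet, StatePosterior
from .treeio import TimeTree

__all__ = [
    "CTMCModel",
    "transition_probabilities",
    "tree_log_likelihood",
    "marginal_node_probabilities",
    "fit_rate",
    "AncestralStateModel",
    "AncestralStateResults",
    "enumeration_log_likelihood",
    "enumeration_marginals",
]

_STRUCTURES = ("equal_rates", "sym", "ard")


@dataclass(frozen=True)
class CTMCModel:
    """K-state continuous-time Markov chain: rate matrix Q and root prior π.

    Rows of Q sum to zero (diagonal is set from the off-diagonals at
    construction); π sums to one.  `structure` tags how Q was built:
    ``equal_rates`` (single symmetric rate q), ``sym`` (free symmetric) or
    ``ard`` (all rates differ).
    """

    rate_matrix: np.ndarray
    root_prior: np.ndarray
    structure: str = "ard"

    def __post_init__(self) -> None:
        Q = np.array(self.rate_matrix, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1] or Q.shape[0] < 2:
            raise ValueError(f"Q must be square K>=2, got shape {Q.shape}")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        np.fill_diagonal(Q, -off.sum(axis=1))
        pi = np.array(self.root_prior, dtype=float)
        if pi.shape != (Q.shape[0],) or np.any(pi < 0):
            raise ValueError("root prior must be a nonnegative length-K vector")
        s = pi.sum()
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"root prior sums to {s:.6g}, not 1")
        pi = pi / s
        if self.structure not in _STRUCTURES:
            raise ValueError(f"structure must be one of {_STRUCTURES}")
        object.__setattr__(self, "rate_matrix", Q)
        object.__setattr__(self, "root_prior", pi)

    @property
    def k(self) -> int:
        return self.rate_matrix.shape[0]

    @classmethod
    def equal_rates(cls, q: float, k: int, root_prior=None) -> "CTMCModel":
        """Symmetric chain with every off-diagonal rate equal to `q`."""
        if q < 0:
            raise ValueError("rate must be >= 0")
        Q = np.full((k, k), q, dtype=float)
        if root_prior is None:
            root_prior = np.full(k, 1.0 / k)
        return cls(Q, np.asarray(root_prior, dtype=float), "equal_rates")

    @classmethod
    def from_rates(cls, rates: np.ndarray, structure: str = "ard", root_prior=None) -> "CTMCModel":
        rates = np.asarray(rates, dtype=float)
        k = rates.shape[0]
        if structure == "sym" and not np.allclose(rates, rates.T):
            raise ValueError("structure='sym' requires a symmetric rate matrix")
        if root_prior is None:
            root_prior = cls(rates, np.full(k, 1.0 / k), structure).stationary_distribution()
        return cls(rates, np.asarray(root_prior, dtype=float), structure)

    def stationary_distribution(self) -> np.ndarray:
        """π with πQ = 0 (uniform for any symmetric structure)."""
        Q = self.rate_matrix
        k = self.k
        if np.allclose(Q, Q.T):
            return np.full(k, 1.0 / k)
        A = np.vstack([Q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    @property
    def equal_rate(self) -> float:
        """The single off-diagonal rate of an equal-rates chain."""
        if self.structure != "equal_rates":
            raise ValueError("only defined for equal_rates structure")
        k = self.k
        return float(self.rate_matrix[0, 1]) if k > 1 else 0.0


def transition_probabilities(model: CTMCModel, t: float) -> np.ndarray:
    """P(t) = exp(Q t): row-stochastic transition matrix over duration t (My).

    Equal-rates chains use the closed form
    ``P_ij(t) = 1/K + (δ_ij − 1/K) e^{−Kqt}``; symmetric Q uses a symmetric
    eigendecomposition; anything else (or a poorly conditioned
    decomposition) falls back to scipy's scaling-and-squaring expm.  The
    result is guaranteed row-stochastic to 1e-9 (tiny negative entries are
    clipped and rows renormalized).
    """
    if t < 0:
        raise ValueError(f"duration must be >= 0, got {t}")
    Q = model.rate_matrix
    k = model.k
    if model.structure == "equal_rates":
        q = model.rate_matrix[0, 1] if k > 1 else 0.0
        e = np.exp(-k * q * t)
        P = np.full((k, k), (1.0 - e) / k)
        np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
    elif np.allclose(Q, Q.T, atol=1e-13):
        w, V = np.linalg.eigh(Q)
        P = (V * np.exp(w * t)) @ V.T
    else:
        P = None
        try:
            w, V = np.linalg.eig(Q)
            if np.linalg.cond(V) < 1e8:
                P = np.real((V * np.exp(w * t)) @ np.linalg.inv(V))
        except np.linalg.LinAlgError:
            P = None
        if P is None or np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
            P = scipy.linalg.expm(Q * t)
    err = np.abs(P.sum(axis=1) - 1.0).max()
    if err > 1e-9:
        raise FloatingPointError(
            f"transition matrix rows deviate from 1 by {err:.3g} (> 1e-9)"
        )
    P = np.clip(P, 0.0, 1.0)
    return P / P.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# Tip-state handling
# --------------------------------------------------------------------------

#: sentinel region labels treated as missing data (all regions possible)
_AMBIGUOUS = {"?", "-", "NA", ""}


def _tip_state_matrix(tree: TimeTree, tip_states, regions: RegionSet) -> np.ndarray:
    """(n_nodes, K) matrix of tip likelihood vectors (rows for internals unused).

    `tip_states` maps tip label -> region label or probability/indicator
    vector; ambiguous labels ('?', '-', 'NA', None) become all-ones
    (standard missing-data treatment).
    """
    X = np.ones((tree.n_nodes, regions.k))
    for v in tree.tips:
        lab = tree.label(v)
        if lab not in tip_states:
            raise ValueError(f"tip {lab!r} has no state assignment")
        val = tip_states[lab]
        if val is None or (isinstance(val, str) and val.strip() in _AMBIGUOUS):
            continue  # ambiguous: all-ones
        if isinstance(val, str):
            X[v] = regions.one_hot(val)
        else:
            vec = np.asarray(val, dtype=float)
            if vec.shape != (regions.k,) or np.any(vec < 0) or vec.max() <= 0:
                raise ValueError(f"tip {lab!r}: invalid state vector {val!r}")
            X[v] = vec
    return X


# --------------------------------------------------------------------------
# Pruning likelihood and marginals
# --------------------------------------------------------------------------


def _branch_matrices(tree: TimeTree, model: CTMCModel) -> dict[int, np.ndarray]:
    mats: dict[int, np.ndarray] = {}
    cache: dict[float, np.ndarray] = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        t = tree.branch_length(v)
        if t not in cache:
            cache[t] = transition_probabilities(model, t)
        mats[v] = cache[t]
    return mats


def _inside_pass(tree, X, model, P):
    """Scaled post-order partials L[v][s] = P(data below v | state s) and log-scalers."""
    n, k = X.shape
    L = np.empty((n, k))
    logscale = np.zeros(n)
    for v in tree.postorder():
        if tree.is_tip(v):
            L[v] = X[v]
        else:
            acc = np.ones(k)
            for c in tree.children(v):
                acc = acc * (P[c] @ L[c])
                logscale[v] += logscale[c]
            L[v] = acc
        s = L[v].max()
        if s <= 0:
            raise FloatingPointError(
                f"zero partial likelihood at node {tree.describe(v)} "
                "(tip states impossible under the model)"
            )
        L[v] = L[v] / s
        logscale[v] += np.log(s)
    return L, logscale


def tree_log_likelihood(tree: TimeTree, tip_states, model: CTMCModel,
                        regions: RegionSet | None = None) -> float:
    """Log-likelihood of the tip regions under the CTMC, by pruning.

    Equals ``log Σ_s π_s · P(tip data | root state s)``; numerically
    stabilized by per-node rescaling so 300-tip trees with small rates do
    not underflow.
    """
    if regions is None:
        regions = DEFAULT_REGIONS if model.k == 4 else RegionSet(
            tuple(str(i) for i in range(model.k)))
    X = _tip_state_matrix(tree, tip_states, regions)
    P = _branch_matrices(tree, model)
    L, logscale = _inside_pass(tree, X, model, P)
    r = tree.root
    lik = float(model.root_prior @ L[r])
    return float(np.log(lik) + logscale[r])


def marginal_node_probabilities(tree: TimeTree, tip_states, model: CTMCModel,
                                regions: RegionSet | None = None) -> StatePosterior:
    """Marginal region probabilities at every node, given all tip states.

    Internal nodes get the exact conditional P(state | all tips) from the
    inside×outside product; tips return their own (normalized) one-hot or
    ambiguity vectors.
    """
    if regions is None:
        regions = DEFAULT_REGIONS if model.k == 4 else RegionSet(
            tuple(str(i) for i in range(model.k)))
    X = _tip_state_matrix(tree, tip_states, regions)
    P = _branch_matrices(tree, model)
    L, _ = _inside_pass(tree, X, model, P)

    n, k = X.shape
    O = np.empty((n, k))  # outside (above-node) partials, arbitrarily scaled
    O[tree.root] = model.root_prior
    for v in tree.preorder():
        if tree.is_tip(v):
            continue
        msgs = {c: P[c] @ L[c] for c in tree.children(v)}
        for c in tree.children(v):
            sib = O[v].copy()
            for w, m in msgs.items():
                if w != c:
                    sib = sib * m
            oc = P[c].T @ sib
            O[c] = oc / oc.max()

    probs: dict[int, np.ndarray] = {}
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            vec = X[v]
        else:
            vec = L[v] * O[v]
        probs[v] = vec / vec.sum()
    return StatePosterior(regions, probs, atol=1e-9, renormalize=True)


# --------------------------------------------------------------------------
# Exhaustive-enumeration reference (for validation only)
# --------------------------------------------------------------------------


def _enumeration_joint(tree, X, model, P):
    internals = list(tree.internal_nodes)
    k = model.k
    # integrate tips analytically: message from tip c to its parent state
    total = 0.0
    marg = {v: np.zeros(k) for v in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        state = dict(zip(internals, assign))
        w = model.root_prior[state[tree.root]]
        for v in internals:
            for c in tree.children(v):
                if tree.is_tip(c):
                    w *= float(P[c][state[v]] @ X[c])
                else:
                    w *= float(P[c][state[v], state[c]])
        total += w
        for v in internals:
            marg[v][state[v]] += w
    return total, marg


def enumeration_log_likelihood(tree: TimeTree, tip_states, model: CTMCModel,
                               regions: RegionSet | None = None) -> float:
    """Brute-force likelihood by summing over all internal-state assignments.

    O(K^internal) — a reference for small trees, never the production path.
    Shares only :func:`transition_probabilities` with the pruning code.
    """
    if regions is None:
        regions = DEFAULT_REGIONS if model.k == 4 else RegionSet(
            tuple(str(i) for i in range(model.k)))
    X = _tip_state_matrix(tree, tip_states, regions)
    P = _branch_matrices(tree, model)
    total, _ = _enumeration_joint(tree, X, model, P)
    return float(np.log(total))


def enumeration_marginals(tree: TimeTree, tip_states, model: CTMCModel,
                          regions: RegionSet | None = None) -> dict[int, np.ndarray]:
    """Brute-force marginals at internal nodes (Bayes rule on the enumerated joint)."""
    if regions is None:
        regions = DEFAULT_REGIONS if model.k == 4 else RegionSet(
            tuple(str(i) for i in range(model.k)))
    X = _tip_state_matrix(tree, tip_states, regions)
    P = _branch_matrices(tree, model)
    total, marg = _enumeration_joint(tree, X, model, P)
    return {v: m / total for v, m in marg.items()}


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------


class AncestralStateModel:
    """ML dispersal model for tip regions on a fixed ultrametric time tree.

    Parameters
    ----------
    tree
        The time-calibrated tree (branch durations in My).
    tip_states
        Mapping tip label -> region label (or probability vector; '?' for
        missing).
    regions
        Region axis; defaults to the I–IV coding.
    structure
        'equal_rates' (default; single symmetric rate, the standard
        Mk/Lewis model), 'sym' (free symmetric) or 'ard' (all rates
        differ).
    root_prior
        Optional fixed root prior π; default is the stationary
        distribution of the fitted Q (uniform for symmetric structures).
    """

    def __init__(self, tree: TimeTree, tip_states, regions: RegionSet = DEFAULT_REGIONS,
                 structure: str = "equal_rates", root_prior=None) -> None:
        if structure not in _STRUCTURES:
            raise ValueError(f"structure must be one of {_STRUCTURES}")
        self.tree = tree
        self.tip_states = dict(tip_states)
        self.regions = regions
        self.structure = structure
        self.root_prior = None if root_prior is None else np.asarray(root_prior, float)
        # validate tips up front so errors name the tip, not the optimizer
        _tip_state_matrix(tree, self.tip_states, regions)
        tree.ages()  # raises if not ultrametric

    @classmethod
    def from_table(cls, tree: TimeTree, path, regions: RegionSet = DEFAULT_REGIONS,
                   **kwargs) -> "AncestralStateModel":
        """Build from a two-column TSV (tip label, region) or tip-probability TSV."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        if set(regions.labels) <= set(df.columns):
            tip_col = df.columns[0]
            states = {
                str(row[tip_col]): np.asarray([row[r] for r in regions.labels], float)
                for _, row in df.iterrows()
            }
        else:
            tip_col, reg_col = df.columns[:2]
            states = {str(row[tip_col]): str(row[reg_col]) for _, row in df.iterrows()}
        return cls(tree, states, regions, **kwargs)

    def _ctmc(self, params: np.ndarray) -> CTMCModel:
        k = self.regions.k
        if self.structure == "equal_rates":
            m = CTMCModel.equal_rates(float(params[0]), k)
        else:
            Q = np.zeros((k, k))
            if self.structure == "sym":
                iu = np.triu_indices(k, 1)
                Q[iu] = params
                Q = Q + Q.T
            else:
                mask = ~np.eye(k, dtype=bool)
                Q[mask] = params
            m = CTMCModel.from_rates(Q, self.structure)
        if self.root_prior is not None:
            m = CTMCModel(m.rate_matrix, self.root_prior, m.structure)
        return m

    @property
    def n_params(self) -> int:
        k = self.regions.k
        return {"equal_rates": 1, "sym": k * (k - 1) // 2, "ard": k * (k - 1)}[
            self.structure
        ]

    def loglike(self, params) -> float:
        params = np.atleast_1d(np.asarray(params, dtype=float))
        return tree_log_likelihood(self.tree, self.tip_states, self._ctmc(params),
                                   self.regions)

    def _default_q_max(self) -> float:
        # large enough that P(t) is at its ergodic limit on typical branches,
        # so the likelihood is flat at the boundary for informative data
        bl = np.array([self.tree.branch_length(v)
                       for v in range(self.tree.n_nodes) if v != self.tree.root])
        mean_bl = float(bl[bl > 0].mean()) if np.any(bl > 0) else 1.0
        return 100.0 / (self.regions.k * mean_bl)

    def fit(self, q_max: float | None = None, q_min: float = 1e-8,
            xatol: float = 1e-8, n_starts: int = 5, seed: int = 0
            ) -> "AncestralStateResults":
        """Maximize the pruning likelihood over the rate parameter(s).

        Equal-rates uses deterministic 1-D bounded minimization on
        [q_min, q_max] (tolerance `xatol` on q); free structures use
        L-BFGS-B on log-rates with `n_starts` fixed-seed restarts.
        Monomorphic tip data leave the rate unidentifiable: a
        RuntimeWarning is issued and the lower bound returned with
        ``identifiable=False``.
        """
        observed = {
            str(v) for v in self.tip_states.values() if isinstance(v, str)
            and v.strip() not in _AMBIGUOUS
        }
        identifiable = len(observed) >= 2 or not all(
            isinstance(v, str) for v in self.tip_states.values()
        )
        if q_max is None:
            q_max = self._default_q_max()
        if not identifiable:
            warnings.warn(
                "rate not identifiable (all tips in one region); "
                "lower bound returned", RuntimeWarning, stacklevel=2)
            ctmc = self._ctmc(np.full(self.n_params, q_min))
            return AncestralStateResults(
                self, ctmc, llf=self.loglike(np.full(self.n_params, q_min)),
                converged=False, identifiable=False, n_evals=1,
                message="rate not identifiable, lower bound returned")

        if self.structure == "equal_rates":
            opt = scipy.optimize.minimize_scalar(
                lambda q: -self.loglike([q]), bounds=(q_min, q_max),
                method="bounded", options={"xatol": xatol})
            params = np.array([opt.x])
            at_boundary = opt.x > q_max - 10 * max(xatol, q_max * 1e-6)
            return AncestralStateResults(
                self, self._ctmc(params), llf=-float(opt.fun),
                converged=bool(opt.success) and not at_boundary,
                identifiable=True, n_evals=int(opt.nfev),
                message="boundary maximum" if at_boundary else str(opt.message))

        rng = np.random.default_rng(seed)
        best = None
        nfev = 0
        for _ in range(n_starts):
            x0 = np.log(10 ** rng.uniform(-2, 0, self.n_params) * q_max * 0.01)
            opt = scipy.optimize.minimize(
                lambda lx: -self.loglike(np.exp(lx)), x0, method="L-BFGS-B",
                bounds=[(np.log(q_min), np.log(q_max))] * self.n_params)
            nfev += int(opt.nfev)
            if best is None or opt.fun < best.fun:
                best = opt
        params = np.exp(best.x)
        return AncestralStateResults(
            self, self._ctmc(params), llf=-float(best.fun),
            converged=bool(best.success), identifiable=True, n_evals=nfev,
            message=str(best.message))


@dataclass
class AncestralStateResults:
    """Fit results: ML rate(s), log-likelihood, and node-state marginals."""

    model: AncestralStateModel
    ctmc: CTMCModel
    llf: float
    converged: bool
    identifiable: bool
    n_evals: int
    message: str = ""
    _posterior: StatePosterior | None = field(default=None, repr=False)

    @property
    def rate(self) -> float:
        """The single dispersal rate (equal-rates structure only)."""
        return self.ctmc.equal_rate

    @property
    def params(self) -> np.ndarray:
        Q = self.ctmc.rate_matrix
        k = self.ctmc.k
        if self.ctmc.structure == "equal_rates":
            return np.array([Q[0, 1]])
        if self.ctmc.structure == "sym":
            return Q[np.triu_indices(k, 1)]
        return Q[~np.eye(k, dtype=bool)]

    def state_posterior(self) -> StatePosterior:
        """Marginal region probabilities for every node (cached)."""
        if self._posterior is None:
            self._posterior = marginal_node_probabilities(
                self.model.tree, self.model.tip_states, self.ctmc,
                self.model.regions)
        return self._posterior

    def summary(self) -> str:
        m = self.model
        lines = [
            "Ancestral State Reconstruction Results",
            "=" * 54,
            f"{'Tree tips:':<28}{m.tree.n_tips}",
            f"{'Internal nodes:':<28}{len(m.tree.internal_nodes)}",
            f"{'Root age (My):':<28}{m.tree.root_age:.4g}",
            f"{'Regions:':<28}{', '.join(m.regions.labels)}",
            f"{'Rate structure:':<28}{self.ctmc.structure}",
            f"{'Log-likelihood:':<28}{self.llf:.6f}",
            f"{'Converged:':<28}{self.converged}",
            f"{'Identifiable:':<28}{self.identifiable}",
            f"{'Function evaluations:':<28}{self.n_evals}",
            "-" * 54,
        ]
        if self.ctmc.structure == "equal_rates":
            lines.append(f"{'Dispersal rate q (/My):':<28}{self.rate:.6g}")
        else:
            lines.append("Rate matrix Q (/My):")
            for i, row in enumerate(self.ctmc.rate_matrix):
                lines.append(
                    f"  {m.regions.labels[i]:<4}"
                    + " ".join(f"{x:>10.4g}" for x in row))
        lines.append(
            f"{'Root prior:':<28}"
            + " ".join(f"{x:.3g}" for x in self.ctmc.root_prior))
        return "\n".join(lines)


def fit_rate(tree: TimeTree, tip_states, structure: str = "equal_rates",
             regions: RegionSet = DEFAULT_REGIONS, **fit_kwargs
             ) -> AncestralStateResults:
    """Convenience wrapper: build an :class:`AncestralStateModel` and fit it."""
    return AncestralStateModel(tree, tip_states, regions, structure).fit(**fit_kwargs)
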