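"""Exponential random graph models for attribute homophily.

The model places probability

    P(Y = y | X) = exp(sum_a theta_a g_a(y, X)) / kappa(theta)

on simple undirected graphs y, with sufficient statistics g_a drawn from
the term set {edges, nodefactor(attr), nodematch(attr)}:

* ``edges`` — the edge count (density intercept);
* ``nodefactor(attr, base)`` — number of edge endpoints whose attribute
  differs from the base level (degree main effect of the attribute);
* ``nodematch(attr)`` — number of edges joining same-attribute endpoints
  (uniform homophily).

All three terms are *dyad independent*: toggling one dyad changes each
statistic by an amount depending only on the two endpoints' attributes.
The likelihood therefore factorizes into independent Bernoulli dyads and
the exact MLE is a logistic fit over dyads, computed here by Newton's
method on the collapsed dyad-pattern design (one row per distinct
change-statistic vector), which is exact and O(#patterns) per iteration
regardless of cohort size.  MCMC-MLE (Geyer–Thompson importance sampling
over networks drawn by a tie-flip Metropolis sampler) is also provided:
for dyad-independent terms it must agree with the exact fit, which the
test suite uses as its oracle, and it is the route that generalizes to
dyad-dependent terms.

Model selection follows the zero-model / node-attribute-model comparison:
the edges-only control against the model adding burnout terms, by AIC and
BIC, with BIC's sample size the dyad count D = N(N-1)/2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.stats import norm

__all__ = [
    "ErgmTerm", "ErgmSpec", "ErgmControl", "ErgmFit", "ErgmError",
    "ErgmDegeneracyError", "zero_spec", "burnout_spec",
    "change_statistics", "sufficient_statistics", "dyad_pattern_design",
    "fit_exact", "simulate_network", "mh_sampler", "fit_mcmcmle",
    "compare_models", "predicted_edge_probability",
]


class ErgmError(ValueError):
    pass


class ErgmDegeneracyError(RuntimeError):
    """Raised when MCMC samples cannot support the observed statistics."""


@dataclass(frozen=True)
class ErgmTerm:
    name: str
    attribute: str | None = None
    base: str | None = None

    def __post_init__(self) -> None:
        if self.name not in ("edges", "nodefactor", "nodematch"):
            raise ErgmError(f"unknown term {self.name!r}")
        if self.name != "edges" and self.attribute is None:
            raise ErgmError(f"term {self.name!r} needs an attribute")

    @property
    def label(self) -> str:
        if self.name == "edges":
            return "edges"
        if self.name == "nodefactor":
            return f"{self.attribute}"
        return f"nodematch.{self.attribute}"


@dataclass(frozen=True)
class ErgmSpec:
    terms: tuple[ErgmTerm, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ErgmError("spec needs at least one term")
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(set(self.terms)) != len(self.terms):
            raise ErgmError("duplicate terms in spec")

    @property
    def k(self) -> int:
        return len(self.terms)

    @property
    def attributes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.terms:
            if t.attribute and t.attribute not in seen:
                seen.append(t.attribute)
        return tuple(seen)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)


def zero_spec() -> ErgmSpec:
    """The edges-only control ('zero') model."""
    return ErgmSpec((ErgmTerm("edges"),))


def burnout_spec(attribute: str = "burnout", base: str = "low") -> ErgmSpec:
    """The node-attribute model: edges + nodefactor + nodematch."""
    return ErgmSpec((
        ErgmTerm("edges"),
        ErgmTerm("nodefactor", attribute, base),
        ErgmTerm("nodematch", attribute),
    ))


def change_statistics(attrs_i: dict, attrs_j: dict, spec: ErgmSpec
                      ) -> np.ndarray:
    """Change-statistic vector for toggling the dyad (i, j).

    For dyad-independent terms this depends only on the endpoints'
    attribute values: edges -> 1; nodefactor -> endpoints off the base
    level; nodematch -> attribute agreement indicator.
    """
    delta = np.empty(spec.k)
    for a, term in enumerate(spec.terms):
        if term.name == "edges":
            delta[a] = 1.0
        elif term.name == "nodefactor":
            delta[a] = float(attrs_i[term.attribute] != term.base) + float(
                attrs_j[term.attribute] != term.base)
        else:  # nodematch
            delta[a] = float(
                attrs_i[term.attribute] == attrs_j[term.attribute])
    return delta


def _node_attr_arrays(g: nx.Graph, spec: ErgmSpec
                      ) -> tuple[list, dict[str, np.ndarray]]:
    nodes = list(g.nodes())
    arrays: dict[str, np.ndarray] = {}
    for attr in spec.attributes:
        vals = []
        for n in nodes:
            if attr not in g.nodes[n]:
                raise ErgmError(f"node {n!r} lacks attribute {attr!r}")
            vals.append(g.nodes[n][attr])
        arrays[attr] = np.asarray(vals, dtype=object)
    return nodes, arrays


def sufficient_statistics(g: nx.Graph, spec: ErgmSpec) -> np.ndarray:
    """g_a(y, X): observed network statistics, summed over present edges."""
    _node_attr_arrays(g, spec)  # validates attributes
    stats = np.zeros(spec.k)
    for u, v in g.edges():
        stats += change_statistics(g.nodes[u], g.nodes[v], spec)
    return stats


@dataclass
class DyadPatternDesign:
    """Dyads collapsed by their change-statistic pattern.

    ``deltas`` is P x k (one distinct change-statistic vector per row);
    ``n_dyads`` and ``n_edges`` count dyads and observed edges per
    pattern.  Pattern counts always sum to D = N(N-1)/2.
    """

    deltas: np.ndarray
    n_dyads: np.ndarray
    n_edges: np.ndarray
    class_labels: list[tuple]
    n_nodes: int

    @property
    def dyad_count(self) -> int:
        return int(self.n_dyads.sum())


def _node_classes(nodes, arrays: dict[str, np.ndarray], spec: ErgmSpec):
    """Group nodes by their tuple of attribute values."""
    if not spec.attributes:
        return np.zeros(len(nodes), dtype=int), [()]
    keys = [tuple(arrays[a][i] for a in spec.attributes)
            for i in range(len(nodes))]
    uniq = sorted(set(keys))
    index = {k: i for i, k in enumerate(uniq)}
    return np.asarray([index[k] for k in keys]), uniq


def dyad_pattern_design(g: nx.Graph, spec: ErgmSpec) -> DyadPatternDesign:
    """Collapse all N(N-1)/2 dyads into distinct attribute-pair patterns."""
    nodes, arrays = _node_attr_arrays(g, spec)
    n = len(nodes)
    if n < 2:
        raise ErgmError("network needs at least two nodes")
    class_idx, classes = _node_classes(nodes, arrays, spec)
    counts = np.bincount(class_idx, minlength=len(classes))

    pairs: list[tuple[int, int]] = []
    for c1 in range(len(classes)):
        for c2 in range(c1, len(classes)):
            pairs.append((c1, c2))
    pair_index = {p: i for i, p in enumerate(pairs)}

    def _delta(c1: int, c2: int) -> np.ndarray:
        ai = {a: classes[c1][k] for k, a in enumerate(spec.attributes)}
        aj = {a: classes[c2][k] for k, a in enumerate(spec.attributes)}
        return change_statistics(ai, aj, spec)

    deltas = np.vstack([_delta(c1, c2) for c1, c2 in pairs])
    n_dyads = np.zeros(len(pairs))
    for c1, c2 in pairs:
        if c1 == c2:
            n_dyads[pair_index[(c1, c2)]] = counts[c1] * (counts[c1] - 1) / 2
        else:
            n_dyads[pair_index[(c1, c2)]] = counts[c1] * counts[c2]

    node_pos = {node: i for i, node in enumerate(nodes)}
    n_edges = np.zeros(len(pairs))
    for u, v in g.edges():
        cu, cv = class_idx[node_pos[u]], class_idx[node_pos[v]]
        n_edges[pair_index[(min(cu, cv), max(cu, cv))]] += 1

    keep = n_dyads > 0
    labels = [(classes[c1], classes[c2]) for (c1, c2), k in
              zip(pairs, keep) if k]
    return DyadPatternDesign(deltas[keep], n_dyads[keep], n_edges[keep],
                             labels, n)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    return np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))


def _collapsed_loglik(theta, design: DyadPatternDesign) -> float:
    eta = design.deltas @ theta
    return float(design.n_edges @ eta - design.n_dyads @ _log1pexp(eta))


def _network_fingerprint(design: DyadPatternDesign) -> tuple:
    return (design.n_nodes, int(design.n_edges.sum()),
            tuple(sorted((str(lbl), int(nd), int(ne)) for lbl, nd, ne in
                         zip(design.class_labels, design.n_dyads,
                             design.n_edges))))


@dataclass
class ErgmFit:
    """Fitted ERGM with Wald inference and information criteria.

    ``log_normalizer`` is log kappa(theta_hat), computable exactly for
    dyad-independent specs.  ``aic = 2k - 2*loglik`` and
    ``bic = k*ln(D) - 2*loglik`` with D the dyad count.
    """

    spec: ErgmSpec
    coefficients: np.ndarray
    standard_errors: np.ndarray
    loglik: float
    log_normalizer: float
    dyad_count: int
    n_nodes: int
    observed_stats: np.ndarray
    method: str
    converged: bool = True
    message: str = ""
    fingerprint: tuple = field(default=(), repr=False)

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def z_values(self) -> np.ndarray:
        return self.coefficients / self.standard_errors

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z_values))

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.dyad_count) - 2.0 * self.loglik

    def coefficient(self, label: str) -> float:
        return float(self.coefficients[list(self.spec.labels).index(label)])

    def summary_table(self) -> str:
        """Coefficient table: estimate (SE), Z, p, with AIC/BIC footer."""
        lines = ["Configurations\tEstimated value (Std. Error)\t"
                 "Z-value\tp-Value"]
        for label, coef, se, z, p in zip(
                self.spec.labels, self.coefficients, self.standard_errors,
                self.z_values, self.p_values):
            p_txt = "<1e-04" if p < 1e-4 else f"{p:.4f}"
            lines.append(f"{label}\t{coef:.2f} ({se:.2f})\t{z:.2f}\t{p_txt}")
        lines.append(f"AIC: {self.aic:,.0f}\tBIC: {self.bic:,.0f}")
        if not self.converged:
            lines.append(f"WARNING: not converged: {self.message}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "terms": list(self.spec.labels),
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "z_values": self.z_values.tolist(),
            "p_values": self.p_values.tolist(),
            "loglik": self.loglik,
            "log_normalizer": self.log_normalizer,
            "aic": self.aic,
            "bic": self.bic,
            "dyad_count": self.dyad_count,
            "n_nodes": self.n_nodes,
            "observed_stats": self.observed_stats.tolist(),
            "method": self.method,
            "converged": self.converged,
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _graph_fingerprint(g: nx.Graph) -> tuple:
    """Spec-independent identity of a network: nodes, size and edge hash."""
    edges = sorted(tuple(sorted(map(str, e))) for e in g.edges())
    digest = hash((tuple(sorted(map(str, g.nodes()))), tuple(edges)))
    return (g.number_of_nodes(), g.number_of_edges(), digest)


def _fit_collapsed(design: DyadPatternDesign, spec: ErgmSpec,
                   method: str, fingerprint: tuple = ()) -> ErgmFit:
    """Newton-Raphson logistic MLE on the collapsed pattern design."""
    degenerate = [
        (lbl, int(ne), int(nd))
        for lbl, ne, nd in zip(design.class_labels, design.n_edges,
                               design.n_dyads)
        if ne == 0 or ne == nd
    ]
    theta = np.zeros(spec.k)
    converged = False
    message = ""
    ll = _collapsed_loglik(theta, design)
    for _ in range(100):
        eta = design.deltas @ theta
        mu = design.n_dyads * _sigmoid(eta)
        grad = design.deltas.T @ (design.n_edges - mu)
        w = design.n_dyads * _sigmoid(eta) * _sigmoid(-eta)
        fisher = design.deltas.T @ (design.deltas * w[:, None])
        try:
            step = np.linalg.solve(fisher, grad)
        except np.linalg.LinAlgError:
            message = "singular Fisher information (collinear terms)"
            break
        # step-halving line search
        for _ in range(40):
            cand = theta + step
            ll_cand = _collapsed_loglik(cand, design)
            if ll_cand >= ll - 1e-12:
                break
            step = 0.5 * step
        theta, ll = cand, ll_cand
        if np.max(np.abs(grad)) < 1e-10 and np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    if np.max(np.abs(theta)) > 25:
        converged = False
        message = ("separation: pattern(s) with all or no edges drive "
                   f"coefficients to infinity: {degenerate}")
    elif not converged and not message:
        message = "Newton iteration did not converge"

    eta = design.deltas @ theta
    w = design.n_dyads * _sigmoid(eta) * _sigmoid(-eta)
    fisher = design.deltas.T @ (design.deltas * w[:, None])
    try:
        cov = np.linalg.inv(fisher)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(spec.k, np.nan)
    log_norm = float(design.n_dyads @ _log1pexp(eta))
    observed = design.deltas.T @ design.n_edges
    return ErgmFit(
        spec=spec, coefficients=theta, standard_errors=se, loglik=ll,
        log_normalizer=log_norm, dyad_count=design.dyad_count,
        n_nodes=design.n_nodes, observed_stats=observed, method=method,
        converged=converged, message=message, fingerprint=fingerprint)


def fit_exact(g: nx.Graph, spec: ErgmSpec) -> ErgmFit:
    """Exact MLE for dyad-independent specs.

    The Bernoulli-dyad log-likelihood
    ``sum_dyads [y_ij theta.delta_ij - log(1 + exp(theta.delta_ij))]``
    is maximized by Newton's method on the collapsed pattern design;
    standard errors come from the inverse observed Fisher information.
    Separation (a pattern with all or none of its dyads tied) is reported
    via ``converged=False`` with a diagnostic message.
    """
    design = dyad_pattern_design(g, spec)
    return _fit_collapsed(design, spec, "exact_dyad",
                          _graph_fingerprint(g))


def _status_design(attrs, spec: ErgmSpec):
    """Pattern design skeleton (no edges) from a node-attribute mapping."""
    if hasattr(attrs, "items"):
        nodes = list(attrs.keys())
        values = {a: np.asarray([attrs[n] for n in nodes], dtype=object)
                  for a in spec.attributes}
        if spec.attributes and hasattr(next(iter(attrs.values())), "keys"):
            values = {a: np.asarray([attrs[n][a] for n in nodes],
                                    dtype=object) for a in spec.attributes}
    else:
        raise ErgmError("attrs must map node id -> status (or dict)")
    g = nx.Graph()
    for i, n in enumerate(nodes):
        g.add_node(n, **{a: values[a][i] for a in spec.attributes})
    return g, nodes, values


def simulate_network(theta, attrs, spec: ErgmSpec, seed: int = 0
                     ) -> nx.Graph:
    """Draw one network from a dyad-independent ERGM.

    Each dyad is an independent Bernoulli(logistic(theta . delta_ij))
    coin; ``attrs`` maps node id to attribute value (or to a dict of
    attribute values for multi-attribute specs).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.k,):
        raise ErgmError("theta length must match the number of terms")
    single = spec.attributes[:1]
    if hasattr(attrs, "items") and spec.attributes and not hasattr(
            next(iter(attrs.values())), "keys"):
        attrs = {n: {single[0]: v} for n, v in attrs.items()}
    g, nodes, values = _status_design(attrs, spec)
    n = len(nodes)
    rng = np.random.default_rng(seed)

    class_idx, classes = _node_classes(nodes, values, spec)
    by_class = [np.flatnonzero(class_idx == c) for c in range(len(classes))]
    node_arr = np.asarray(nodes, dtype=object)
    for c1 in range(len(classes)):
        for c2 in range(c1, len(classes)):
            ai = {a: classes[c1][k] for k, a in enumerate(spec.attributes)}
            aj = {a: classes[c2][k] for k, a in enumerate(spec.attributes)}
            p = _sigmoid(np.asarray([change_statistics(ai, aj, spec)
                                     @ theta]))[0]
            i_idx, j_idx = by_class[c1], by_class[c2]
            if c1 == c2:
                if len(i_idx) < 2:
                    continue
                draws = rng.random((len(i_idx), len(i_idx)))
                iu, ju = np.triu_indices(len(i_idx), k=1)
                hit = draws[iu, ju] < p
                g.add_edges_from(
                    zip(node_arr[i_idx[iu[hit]]], node_arr[i_idx[ju[hit]]]))
            else:
                draws = rng.random((len(i_idx), len(j_idx)))
                ii, jj = np.nonzero(draws < p)
                g.add_edges_from(
                    zip(node_arr[i_idx[ii]], node_arr[j_idx[jj]]))
    return g


@dataclass
class ErgmControl:
    """MCMC controls.  ``burn_in`` defaults to 10*D toggles and
    ``interval`` to D, with D the dyad count; ``sampler`` is ``"blocked"``
    (exact-distribution vectorized tie-flip chain) or ``"sequential"``
    (literal one-toggle-at-a-time Metropolis)."""

    seed: int = 0
    burn_in: int | None = None
    interval: int | None = None
    n_samples: int = 1000
    tol: float = 1e-4
    max_iter: int = 20
    sampler: str = "blocked"


class _DyadState:
    """Per-dyad state grouped by change-statistic pattern."""

    def __init__(self, g: nx.Graph, spec: ErgmSpec):
        design = dyad_pattern_design(g, spec)
        nodes, arrays = _node_attr_arrays(g, spec)
        class_idx, classes = _node_classes(nodes, arrays, spec)
        # enumerate dyads pattern-by-pattern
        pat_of_pair = {}
        for p, (l1, l2) in enumerate(design.class_labels):
            pat_of_pair[(l1, l2)] = p
            pat_of_pair[(l2, l1)] = p
        key = [classes[c] for c in class_idx]
        n = len(nodes)
        iu, ju = np.triu_indices(n, k=1)
        self.pattern = np.asarray(
            [pat_of_pair[(key[i], key[j])] for i, j in zip(iu, ju)],
            dtype=int)
        adj = nx.to_numpy_array(g, nodelist=nodes, dtype=bool)
        self.state = adj[iu, ju].copy()
        self.design = design
        self.deltas = design.deltas
        self.D = self.state.size

    def stats(self) -> np.ndarray:
        counts = np.bincount(self.pattern[self.state],
                             minlength=len(self.design.n_dyads))
        return self.deltas.T @ counts


def _run_sequential(state: _DyadState, scores: np.ndarray, n_toggles: int,
                    rng) -> None:
    """Literal tie-flip Metropolis: one uniformly chosen dyad per step."""
    idx = rng.integers(0, state.D, size=n_toggles)
    u = rng.random(n_toggles)
    s = state.state
    pat = state.pattern
    for t in range(n_toggles):
        d = idx[t]
        sc = scores[pat[d]]
        if s[d]:
            # removing the tie changes the statistic by -delta
            if u[t] < min(1.0, math.exp(-sc)):
                s[d] = False
        else:
            if u[t] < min(1.0, math.exp(sc)):
                s[d] = True


def _run_blocked(state: _DyadState, scores: np.ndarray, n_toggles: int,
                 rng) -> None:
    """Advance the chain by ``n_toggles`` proposals in one vectorized pass.

    Under dyad independence each dyad evolves as its own two-state chain
    with per-proposal transition probabilities p01 = min(1, e^s) and
    p10 = min(1, e^-s); how many of the T uniform proposals each dyad
    receives is Multinomial(T, 1/D).  Conditional on its proposal count k,
    a dyad's end state is Bernoulli(pi + (start - pi) * lambda^k) with
    lambda = 1 - p01 - p10 and pi = p01/(p01 + p10).  This reproduces the
    sequential sampler's distribution exactly while running in O(D).
    """
    k = rng.multinomial(n_toggles, np.full(state.D, 1.0 / state.D))
    p01 = np.minimum(1.0, np.exp(scores))[state.pattern]
    p10 = np.minimum(1.0, np.exp(-scores))[state.pattern]
    lam = 1.0 - p01 - p10
    pi = p01 / (p01 + p10)
    start = state.state.astype(float)
    with np.errstate(invalid="ignore"):
        prob = pi + (start - pi) * np.power(lam, k)
    touched = k > 0
    draws = rng.random(state.D)
    new = np.where(touched, draws < prob, state.state)
    state.state = new.astype(bool)


def mh_sampler(g0: nx.Graph, theta, spec: ErgmSpec,
               control: ErgmControl | None = None) -> np.ndarray:
    """Sample sufficient-statistic vectors from the ERGM at ``theta``.

    Tie-flip Metropolis: propose toggling a uniformly random dyad and
    accept with min(1, exp(theta . delta_change)).  After ``burn_in``
    toggles, one statistic vector is recorded every ``interval`` toggles,
    ``n_samples`` times.  Returns an (n_samples, k) array.
    """
    if control is None:
        control = ErgmControl()
    theta = np.asarray(theta, dtype=float)
    state = _DyadState(g0, spec)
    burn_in = control.burn_in if control.burn_in is not None else 10 * state.D
    interval = control.interval if control.interval is not None else state.D
    rng = np.random.default_rng(control.seed)
    scores = state.deltas @ theta
    runner = (_run_sequential if control.sampler == "sequential"
              else _run_blocked)
    runner(state, scores, burn_in, rng)
    out = np.empty((control.n_samples, spec.k))
    for s in range(control.n_samples):
        runner(state, scores, interval, rng)
        out[s] = state.stats()
    return out


def fit_mcmcmle(g: nx.Graph, spec: ErgmSpec,
                control: ErgmControl | None = None) -> ErgmFit:
    """Geyer-Thompson MCMC maximum likelihood.

    Initialized at the exact dyad-independent fit (where maximum
    pseudolikelihood coincides with the MLE); each iteration samples
    networks at the current theta and maximizes the importance-sampled
    log-likelihood-ratio surrogate

        l(theta) - l(theta_k) ~ (theta - theta_k) . g_obs
                                - log mean_s exp((theta - theta_k) . g_s)

    until the sup-norm update falls below ``tol`` or ``max_iter`` is hit.
    Standard errors come from the inverse importance-weighted covariance
    of the sampled statistics at the final theta.  If the sampled
    statistics cannot bracket the observation (degeneracy) an
    :class:`ErgmDegeneracyError` is raised.
    """
    from scipy.optimize import minimize

    if control is None:
        control = ErgmControl()
    init = fit_exact(g, spec)
    g_obs = init.observed_stats
    theta = init.coefficients.copy()
    if control.max_iter == 0:
        init.method = "mcmc_mle"
        init.message = "0 iterations: returned exact-fit initializer"
        return init

    design = dyad_pattern_design(g, spec)
    samples = None
    converged = False
    for it in range(control.max_iter):
        iter_control = ErgmControl(
            seed=(control.seed * 1000003 + it) % (2**31),
            burn_in=control.burn_in, interval=control.interval,
            n_samples=control.n_samples, sampler=control.sampler)
        samples = mh_sampler(g, theta, spec, iter_control)
        lo, hi = samples.min(axis=0), samples.max(axis=0)
        if np.any(g_obs < lo - 1e-9) or np.any(g_obs > hi + 1e-9):
            raise ErgmDegeneracyError(
                f"observed statistics {g_obs} outside sampled range "
                f"[{lo}, {hi}] at iteration {it}: model degenerate or "
                "sample too small")
        centered = samples - samples.mean(axis=0)

        def neg_llr(d, centered=centered, mean=samples.mean(axis=0)):
            expo = centered @ d
            m = expo.max()
            lse = m + np.log(np.mean(np.exp(expo - m)))
            return -(d @ (g_obs - mean) - lse)

        def neg_grad(d, centered=centered, mean=samples.mean(axis=0)):
            expo = centered @ d
            w = np.exp(expo - expo.max())
            w /= w.sum()
            return -(g_obs - mean - centered.T @ w)

        res = minimize(neg_llr, np.zeros(spec.k), jac=neg_grad,
                       method="BFGS")
        step = res.x
        # importance weights at the accepted step; collapsed weights mean
        # the surrogate was extrapolating far beyond the sample
        expo = centered @ step
        w = np.exp(expo - expo.max())
        w /= w.sum()
        if 1.0 / np.sum(w**2) < 30:
            raise ErgmDegeneracyError(
                f"effective sample size {1.0 / np.sum(w**2):.1f} below "
                f"floor at iteration {it}; importance weights collapsed")
        # dampen very large steps: the surrogate is only trustworthy
        # near the sampling point
        norm_inf = np.max(np.abs(step))
        if norm_inf > 1.0:
            step = step / norm_inf
        theta = theta + step
        if norm_inf < control.tol:
            converged = True
            break

    # Fisher information at theta_hat is Cov_theta(g): estimate it from a
    # fresh sample drawn at the final coefficients
    final_control = ErgmControl(
        seed=(control.seed * 1000003 + control.max_iter) % (2**31),
        burn_in=control.burn_in, interval=control.interval,
        n_samples=control.n_samples, sampler=control.sampler)
    final_samples = mh_sampler(g, theta, spec, final_control)
    info = np.cov(final_samples.T, ddof=1)
    info = np.atleast_2d(info)
    try:
        se = np.sqrt(np.clip(np.diag(np.linalg.inv(info)), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(spec.k, np.nan)

    eta = design.deltas @ theta
    ll = _collapsed_loglik(theta, design)
    log_norm = float(design.n_dyads @ _log1pexp(eta))
    return ErgmFit(
        spec=spec, coefficients=theta, standard_errors=se, loglik=ll,
        log_normalizer=log_norm, dyad_count=design.dyad_count,
        n_nodes=design.n_nodes, observed_stats=g_obs, method="mcmc_mle",
        converged=converged,
        message="" if converged else
        f"stopped at max_iter={control.max_iter}",
        fingerprint=init.fingerprint)


@dataclass(frozen=True)
class ModelComparison:
    aic_zero: float
    aic_attr: float
    bic_zero: float
    bic_attr: float
    selected: str
    criteria_disagree: bool
    tie: bool

    def to_dict(self) -> dict:
        return {
            "aic": {"zero": self.aic_zero, "node_attribute": self.aic_attr},
            "bic": {"zero": self.bic_zero, "node_attribute": self.bic_attr},
            "selected": self.selected,
            "criteria_disagree": self.criteria_disagree,
            "tie": self.tie,
        }


def compare_models(fit_zero: ErgmFit, fit_attr: ErgmFit) -> ModelComparison:
    """Zero-model vs node-attribute-model selection by AIC and BIC."""
    if fit_zero.fingerprint != fit_attr.fingerprint:
        raise ErgmError("fits come from different networks")
    if not set(fit_zero.spec.terms) <= set(fit_attr.spec.terms):
        raise ErgmError("zero model terms must nest in the attribute model")
    by_aic = "zero" if fit_zero.aic < fit_attr.aic else "node_attribute"
    by_bic = "zero" if fit_zero.bic < fit_attr.bic else "node_attribute"
    tie = (fit_zero.aic == fit_attr.aic) and (fit_zero.bic == fit_attr.bic)
    return ModelComparison(
        aic_zero=fit_zero.aic, aic_attr=fit_attr.aic,
        bic_zero=fit_zero.bic, bic_attr=fit_attr.bic,
        selected=by_bic, criteria_disagree=by_aic != by_bic, tie=tie)


def predicted_edge_probability(fit: ErgmFit, status_i: str,
                               status_j: str) -> float:
    """Tie probability for a dyad with the given attribute values."""
    attr = fit.spec.attributes
    if not attr:
        delta = change_statistics({}, {}, fit.spec)
    else:
        delta = change_statistics({attr[0]: status_i},
                                  {attr[0]: status_j}, fit.spec)
    return float(_sigmoid(np.asarray([delta @ fit.coefficients]))[0])
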