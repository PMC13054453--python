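"""Co-reported symptom networks per drug class.

Within the reports of one pharmacological class, the Preferred Terms that
are disproportionately co-reported with the index condition are selected
by an event-event IC analysis (same statistic as the drug screen, with the
PT playing the drug's part).  The selected terms form a binary case-by-term
matrix from which two association networks are estimated:

* an **Ising model**, fitted by node-wise L1-regularised logistic
  regression with per-node penalty chosen by the extended BIC and the
  couplings symmetrised by the AND rule (edge kept only when selected in
  both directions, weight = mean of the two coefficients);
* a **PPMI network**, positive pointwise mutual information between term
  pairs with a +0.5 smoothing count on the joint.

Communities are found by walktrap on positive edge weights, and partitions
from the two methods are compared by the adjusted Rand index (plus an edge
Jaccard between the two graphs), since the methods need not agree.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score

from . import store
from .disproportionality import AnalysisOptions, ic_lower_bound, ic_point
from .store import IcsrDatabase

logger = logging.getLogger(__name__)

__all__ = [
    "CaseTermMatrix",
    "EventNetwork",
    "select_terms",
    "build_matrix",
    "fit_ising",
    "compute_ppmi",
    "detect_communities",
    "compare_partitions",
    "edge_jaccard",
    "simulate_ising",
    "two_cluster_ising",
]

MIN_ROWS_ISING = 20
MIN_COLS_ISING = 3


@dataclass
class CaseTermMatrix:
    """Binary cases x Preferred-Terms matrix for one drug class."""

    data: np.ndarray  # (n_cases, n_terms) in {0, 1}
    pt_codes: list
    report_ids: list

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.pt_codes):
            raise ValueError("matrix shape inconsistent with pt_codes")


@dataclass
class EventNetwork:
    """Symmetric weighted network over Preferred Terms."""

    nodes: list
    weights: np.ndarray  # symmetric, zero diagonal
    method: str  # "ising" | "ppmi"
    partition: dict | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape mismatch")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        np.fill_diagonal(w, 0.0)
        if self.method == "ppmi" and (w < 0).any():
            raise ValueError("PPMI weights must be non-negative")
        self.weights = w

    def edges(self, positive_only: bool = False) -> list:
        """(node_a, node_b, weight) for the upper triangle of non-zero
        (optionally positive) weights."""
        out = []
        for i, j in itertools.combinations(range(len(self.nodes)), 2):
            w = self.weights[i, j]
            if w != 0 and (w > 0 or not positive_only):
                out.append((self.nodes[i], self.nodes[j], float(w)))
        return out


# ---------------------------------------------------------------------------
# term selection and matrix construction

def class_report_ids(db: IcsrDatabase, class_tag: str) -> set:
    """Reports carrying >=1 suspect/interacting drug tagged ``class_tag``."""
    drugs = db.drug_classes(class_tag)
    links = db.report_drugs
    mask = links["drug_id"].isin(drugs) & links["role"].isin(store.ANALYSIS_ROLES)
    return set(links.loc[mask, "report_id"])


def select_terms(
    db: IcsrDatabase,
    class_tag: str,
    rp_case_ids,
    exclude_pts=(),
    options: AnalysisOptions | None = None,
) -> list:
    """PTs disproportionately co-reported with the index condition within
    one drug class.

    Among the class's reports, each PT gets a 2x2 of (PT present) x
    (report is an index case); PTs with IC_LB > 0 are kept.  The index
    condition's own PT(s) are excluded via ``exclude_pts``.
    """
    opts = options or AnalysisOptions()
    drugs = db.drug_classes(class_tag)
    if not drugs:
        raise KeyError(f"class tag resolves to no drug: {class_tag!r}")
    class_ids = class_report_ids(db, class_tag)
    case_ids = set(rp_case_ids) & class_ids
    if not case_ids:
        logger.warning("class %s has zero index cases", class_tag)
        return []

    Y, rid_index, pt_index = store.event_indicator(db)
    in_class = rid_index.isin(class_ids)
    is_case = rid_index.isin(case_ids)
    N = int(in_class.sum())
    n_case = int(is_case.sum())
    n_pt = np.asarray(Y[in_class].sum(axis=0)).ravel()
    O = np.asarray(Y[is_case].sum(axis=0)).ravel()
    E = n_pt * n_case / N
    lb = ic_lower_bound(O, E, level=opts.level, method=opts.lb_method)
    keep = (lb > 0) & ~pt_index.isin(set(exclude_pts)) & (n_pt > 0)
    return sorted(pt_index[keep])


def build_matrix(db: IcsrDatabase, class_tag: str, rp_case_ids, pt_codes) -> CaseTermMatrix:
    """Binary matrix of the class's index cases by the selected PTs; zero-
    variance columns are dropped with a warning."""
    pt_codes = list(pt_codes)
    if not pt_codes:
        raise ValueError("pt_codes is empty")
    case_ids = sorted(set(rp_case_ids) & class_report_ids(db, class_tag))
    Y, rid_index, pt_index = store.event_indicator(db)
    rows = rid_index.get_indexer(case_ids)
    cols = pt_index.get_indexer(pt_codes)
    if (cols < 0).any():
        missing = [p for p, c in zip(pt_codes, cols) if c < 0]
        raise KeyError(f"unknown PT codes: {missing}")
    data = np.asarray(Y[rows][:, cols].todense(), dtype=np.int8)
    variable = data.std(axis=0) > 0
    if not variable.all():
        dropped = [p for p, v in zip(pt_codes, variable) if not v]
        logger.warning("dropping %d zero-variance columns: %s", len(dropped), dropped)
    data = data[:, variable]
    kept = [p for p, v in zip(pt_codes, variable) if v]
    return CaseTermMatrix(data=data, pt_codes=kept, report_ids=list(case_ids))


# ---------------------------------------------------------------------------
# Ising estimation

def _ebic_logistic_path(X, y, gamma: float, n_lambdas: int = 30):
    """L1 logistic path over a lambda grid; returns the coefficient vector
    minimising the extended BIC ``-2 loglik + k log n + 2 gamma k log p``."""
    n, p = X.shape
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        return np.zeros(p)
    lam_max = np.abs(X.T @ (y - ybar)).max() / n
    if lam_max <= 0:
        return np.zeros(p)
    lambdas = np.geomspace(lam_max, lam_max * 0.01, n_lambdas)
    best = (np.inf, np.zeros(p))
    for lam in lambdas:
        # large intercept_scaling leaves the intercept effectively
        # unpenalised (liblinear would otherwise shrink it, which
        # distorts edge selection)
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
            intercept_scaling=100.0, max_iter=500, tol=1e-5, random_state=0,
        )
        clf.fit(X, y)
        coef = clf.coef_.ravel()
        eta = X @ coef + clf.intercept_[0]
        loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        k = int(np.count_nonzero(coef))
        ebic = -2.0 * loglik + k * np.log(n) + 2.0 * gamma * k * np.log(max(p, 2))
        if ebic < best[0] - 1e-9:
            best = (ebic, coef.copy())
    return best[1]


def _drop_collinear(data: np.ndarray, pt_codes: list):
    """Drop later columns perfectly collinear (equal or complementary)
    with an earlier one."""
    keep, dropped = [], []
    for j in range(data.shape[1]):
        col = data[:, j]
        dup = any(
            np.array_equal(col, data[:, k]) or np.array_equal(col, 1 - data[:, k])
            for k in keep
        )
        (dropped if dup else keep).append(j)
    if dropped:
        logger.warning(
            "fit_ising: dropped perfectly collinear columns: %s",
            [pt_codes[j] for j in dropped],
        )
    return data[:, keep], [pt_codes[j] for j in keep]


def fit_ising(matrix: CaseTermMatrix, ebic_gamma: float = 0.25, rule: str = "and") -> EventNetwork:
    """Node-wise L1 logistic Ising estimate with EBIC penalty selection.

    Refuses matrices with fewer than 20 rows or 3 columns, where the
    estimate is unstable.  ``rule`` is ``"and"`` (default: edge kept only
    when selected in both directions) or ``"or"``.
    """
    data = np.asarray(matrix.data, dtype=float)
    if data.shape[0] < MIN_ROWS_ISING or data.shape[1] < MIN_COLS_ISING:
        raise ValueError(
            f"matrix too small for a stable Ising fit: {data.shape} "
            f"(need >= {MIN_ROWS_ISING} rows and >= {MIN_COLS_ISING} columns)"
        )
    data, nodes = _drop_collinear(data.astype(np.int8), list(matrix.pt_codes))
    data = data.astype(float)
    p = data.shape[1]
    if p < MIN_COLS_ISING:
        raise ValueError("too few columns left after collinearity filtering")

    B = np.zeros((p, p))
    for j in range(p):
        others = np.delete(np.arange(p), j)
        coef = _ebic_logistic_path(data[:, others], data[:, j], gamma=ebic_gamma)
        B[j, others] = coef

    sel = B != 0
    if rule == "and":
        keep = sel & sel.T
    elif rule == "or":
        keep = sel | sel.T
    else:
        raise ValueError(f"unknown symmetrisation rule: {rule!r}")
    W = np.where(keep, (B + B.T) / 2.0, 0.0)
    W = (W + W.T) / 2.0
    return EventNetwork(nodes=nodes, weights=W, method="ising")


# ---------------------------------------------------------------------------
# PPMI

def compute_ppmi(matrix: CaseTermMatrix) -> EventNetwork:
    """Positive pointwise mutual information between term pairs.

    ``pmi(a,b) = log2( p(a,b) / (p(a) p(b)) )`` with marginal probabilities
    as column means and the joint count smoothed by +0.5 (so a zero joint
    count stays finite; it clips to 0 anyway).  PPMI = max(pmi, 0).
    """
    data = np.asarray(matrix.data, dtype=float)
    n, p = data.shape
    if p < 2:
        raise ValueError("need at least two columns")
    marg = data.mean(axis=0)
    joint = (data.T @ data + 0.5) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log2(joint / np.outer(marg, marg))
    pmi[~np.isfinite(pmi)] = 0.0
    ppmi = np.maximum(pmi, 0.0)
    np.fill_diagonal(ppmi, 0.0)
    ppmi = (ppmi + ppmi.T) / 2.0
    assert (ppmi >= 0).all() and np.allclose(ppmi, ppmi.T)
    return EventNetwork(nodes=list(matrix.pt_codes), weights=ppmi, method="ppmi")


# ---------------------------------------------------------------------------
# communities and partition comparison

def detect_communities(network: EventNetwork, method: str = "walktrap",
                       seed: int = 0, steps: int = 4) -> dict:
    """Community partition on positive edge weights.

    Walktrap by default (deterministic); ``louvain`` (multilevel) is
    available and uses the seed.  An edgeless network yields singleton
    communities with a warning.
    """
    nodes = list(network.nodes)
    edges = network.edges(positive_only=True)
    if not edges:
        logger.warning("edgeless network: every node is its own community")
        return {v: i for i, v in enumerate(nodes)}
    g = ig.Graph()
    g.add_vertices(nodes)
    g.add_edges([(a, b) for a, b, _ in edges])
    weights = [w for _, _, w in edges]
    if method == "walktrap":
        clustering = g.community_walktrap(weights=weights, steps=steps).as_clustering()
    elif method == "louvain":
        ig.set_random_number_generator(np.random.default_rng(seed))
        clustering = g.community_multilevel(weights=weights)
        ig.set_random_number_generator(None)
    else:
        raise ValueError(f"unknown community method: {method!r}")
    return {v["name"]: m for v, m in zip(g.vs, clustering.membership)}


def compare_partitions(p_a: dict, p_b: dict) -> float:
    """Adjusted Rand index between two partitions of the same node set."""
    if set(p_a) != set(p_b):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(p_a)
    return float(adjusted_rand_score([p_a[v] for v in nodes], [p_b[v] for v in nodes]))


def edge_jaccard(net_a: EventNetwork, net_b: EventNetwork) -> float:
    """Jaccard overlap of the (positive) edge sets of two networks."""
    ea = {frozenset((a, b)) for a, b, _ in net_a.edges(positive_only=True)}
    eb = {frozenset((a, b)) for a, b, _ in net_b.edges(positive_only=True)}
    if not ea and not eb:
        return 1.0
    return len(ea & eb) / len(ea | eb)


# ---------------------------------------------------------------------------
# Ising simulation (exact, for validation)

def two_cluster_ising(nodes_per_cluster: int = 5, coupling: float = 1.0,
                      field_strength: float = -2.0):
    """Planted two-cluster Ising model on {0,1} variables: full within-
    cluster coupling, none between.  Returns (h, J, labels)."""
    p = 2 * nodes_per_cluster
    h = np.full(p, field_strength)
    J = np.zeros((p, p))
    labels = np.repeat([0, 1], nodes_per_cluster)
    for i, j in itertools.combinations(range(p), 2):
        if labels[i] == labels[j]:
            J[i, j] = J[j, i] = coupling
    return h, J, labels


def simulate_ising(h: np.ndarray, J: np.ndarray, n: int, rng) -> np.ndarray:
    """Exact sampling from ``P(x) propto exp(h.x + x'Jx/2)``, x in {0,1}^p,
    by full state enumeration (p <= 20)."""
    p = len(h)
    if p > 20:
        raise ValueError("exact enumeration limited to 20 nodes")
    states = ((np.arange(2 ** p)[:, None] >> np.arange(p)[None, :]) & 1).astype(float)
    energy = states @ h + 0.5 * np.einsum("si,ij,sj->s", states, J, states)
    logp = energy - energy.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    idx = rng.choice(len(states), size=n, p=prob)
    return states[idx].astype(np.int8)
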