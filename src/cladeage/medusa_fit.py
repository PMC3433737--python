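"""Stepwise AICc selection of diversification rate shifts (MEDUSA-style).

Fits a mixture of constant-rate birth-death processes to a backbone timetree
whose tips carry species richness.  The likelihood of a painting of the tree
into rate classes is assembled from birth-death transition probabilities:

- each *internal* edge of duration tau contributes P(1 -> 1 over tau), the
  probability that a single lineage leaves exactly one descendant lineage,
- each *tip* contributes the survival-conditioned probability of its
  richness over its pendant (stem) branch,
- a rate shift placed at a node repaints that node's stem edge and its
  whole subtree (until overridden by a nested shift).

Shifts are added greedily: each round scores every candidate node, accepts
the best one only if the AICc improves by more than a sample-size-dependent
threshold A*(N-B)^C + D, refits the affected rate classes by maximum
likelihood (extinction exceeding speciation is allowed), and repeats.
Parameter count follows np = 3*shifts + 2 (two rates per class plus one
location per shift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from cladeage.birthdeath_core import (BDParams, _log_geom_terms_vec,
                                      conditioned_logpmf_terms)
from cladeage.clade_data import CladeDataset, TimeTree

__all__ = [
    "ThresholdParams",
    "RateClass",
    "MedusaResult",
    "aicc_threshold",
    "model_likelihood",
    "stepwise_fit",
    "shift_rate_mle",
]


@dataclass(frozen=True)
class ThresholdParams:
    """Coefficients of the AICc-improvement stopping threshold."""

    A: float = -35.94105
    B: float = 6.73726
    C: float = -0.10062
    D: float = 27.51668


DEFAULT_THRESHOLD = ThresholdParams()


def aicc_threshold(N: float, params: ThresholdParams = DEFAULT_THRESHOLD
                   ) -> float:
    """Required AICc improvement for accepting one more shift, A*(N-B)^C + D."""
    if N <= params.B:
        raise ValueError(f"taxon count N={N} must exceed B={params.B}")
    return params.A * (N - params.B) ** params.C + params.D


@dataclass(frozen=True)
class RateClass:
    params: BDParams
    label: int


def _aicc(loglik: float, k: int, N: int) -> float:
    if N - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2 * k + 2.0 * k * (k + 1) / (N - k - 1)


class _TreeArrays:
    """Postorder-indexed arrays of the backbone tree for fast painting."""

    def __init__(self, dataset: CladeDataset):
        tree = dataset.tree.dendropy_tree
        richness = dict(zip(dataset.names, dataset.richness_array()))
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        n = len(self.nodes)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.edge_len = np.zeros(n)
        self.is_leaf = np.zeros(n, dtype=bool)
        self.tip_n = np.zeros(n, dtype=np.int64)
        self.tip_names = [None] * n
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, nd in enumerate(self.nodes):
            self.edge_len[i] = nd.edge.length or 0.0
            if nd.parent_node is not None:
                p = self.index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
            if nd.is_leaf():
                self.is_leaf[i] = True
                self.tip_n[i] = richness[nd.taxon.label]
                self.tip_names[i] = nd.taxon.label
        self.root = n - 1
        self.n_tips = int(self.is_leaf.sum())

    def paint(self, shifts: Sequence[int]) -> np.ndarray:
        """Class id per node edge; shift k (in order) paints class k+1."""
        classes = np.zeros(len(self.nodes), dtype=np.int64)
        shift_class = {node: k + 1 for k, node in enumerate(shifts)}
        # preorder = reversed postorder
        for i in reversed(range(len(self.nodes))):
            if i in shift_class:
                classes[i] = shift_class[i]
            elif self.parent[i] >= 0:
                classes[i] = classes[self.parent[i]]
        return classes

    def subtree(self, node: int) -> list[int]:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def tips_under(self, node: int) -> list[str]:
        return [self.tip_names[i] for i in self.subtree(node)
                if self.is_leaf[i]]


def _class_loglik(lam: float, mu: float, int_dur: np.ndarray,
                  tip_n: np.ndarray, tip_t: np.ndarray) -> float:
    """Log-likelihood of one rate class over its edges and tips."""
    total = 0.0
    if int_dur.size:
        # zero-duration edges contribute log P(1->1 over 0) = 0 identically
        int_dur = int_dur[int_dur > 0]
    if int_dur.size:
        log1m_a, _, log1m_b = _log_geom_terms_vec(lam, mu, int_dur)
        total += float(np.sum(log1m_a + log1m_b))  # P(1 -> 1)
    if tip_n.size:
        total += float(np.sum(conditioned_logpmf_terms(lam, mu, tip_n, tip_t)))
    return total


_RATE_LO, _RATE_HI = -14.0, 6.0


def _fit_class(int_dur: np.ndarray, tip_n: np.ndarray, tip_t: np.ndarray,
               start: Optional[BDParams] = None, quick: bool = False
               ) -> tuple[BDParams, float]:
    """ML (lambda, mu) for one class; optimised on the log scale so mu > lambda
    is reachable smoothly.  ``quick`` uses a single warm start with a loose
    iteration cap (candidate screening)."""

    def nll(x):
        if np.any(x < _RATE_LO) or np.any(x > _RATE_HI):
            return np.inf
        ll = _class_loglik(math.exp(x[0]), math.exp(x[1]), int_dur, tip_n,
                           tip_t)
        return -ll if math.isfinite(ll) else np.inf

    if start is None:
        tbar = float(np.mean(tip_t)) if tip_t.size else float(
            np.mean(int_dur)) if int_dur.size else 1.0
        nbar = float(np.mean(tip_n)) if tip_n.size else 2.0
        r0 = max(math.log(max(nbar, 1.05)) / max(tbar, 1e-3), 1e-3)
        start = BDParams(r0 / 0.5, r0)
    x0 = np.array([math.log(max(start.lam, 1e-6)),
                   math.log(max(start.mu, 1e-6))])
    if quick:
        # candidate screening: 1-D in the speciation rate at the warm
        # start's relative extinction; full 2-D refit happens on acceptance
        eps = start.epsilon if (start.lam > 0
                                and math.isfinite(start.epsilon)) else 0.0
        eps = min(eps, 10.0)

        def nll1(log_lam):
            lam = math.exp(log_lam)
            ll = _class_loglik(lam, eps * lam, int_dur, tip_n, tip_t)
            return -ll if math.isfinite(ll) else np.inf

        res = optimize.minimize_scalar(nll1, bounds=(_RATE_LO, _RATE_HI),
                                       method="bounded",
                                       options={"xatol": 1e-3, "maxiter": 60})
        lam = math.exp(res.x)
        return BDParams(lam, eps * lam), -float(res.fun)

    starts = (x0, x0 + np.array([0.5, -2.0]))
    maxiter = 400
    best = None
    with np.errstate(invalid="ignore"):  # simplex may contain inf penalties
        for x_init in starts:
            res = optimize.minimize(nll, x_init, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-8,
                                             "maxiter": maxiter})
            if best is None or res.fun < best.fun:
                best = res
    params = BDParams(math.exp(best.x[0]), math.exp(best.x[1]))
    return params, -float(best.fun)


def _gather(arrays: _TreeArrays, classes: np.ndarray, cls: int):
    sel = (classes == cls)
    sel[arrays.root] = False  # the root has no edge
    internal = sel & ~arrays.is_leaf
    tips = sel & arrays.is_leaf
    return (arrays.edge_len[internal], arrays.tip_n[tips],
            arrays.edge_len[tips])


def model_likelihood(dataset: CladeDataset, shifts: Sequence[int],
                     rate_classes: Sequence[BDParams]) -> float:
    """Log-likelihood of a fixed painting.

    ``shifts`` are postorder node indices (see :class:`MedusaResult`);
    ``rate_classes[0]`` governs the root (base) class and
    ``rate_classes[k]`` the k-th shift.  Placing a shift at the root would
    duplicate the base class and is an error.
    """
    arrays = _TreeArrays(dataset)
    if len(rate_classes) != len(shifts) + 1:
        raise ValueError("need one rate class per shift plus the base class")
    if arrays.root in shifts:
        raise ValueError("a shift at the root duplicates the base class")
    classes = arrays.paint(list(shifts))
    total = 0.0
    for cls, params in enumerate(rate_classes):
        int_dur, tip_n, tip_t = _gather(arrays, classes, cls)
        total += _class_loglik(params.lam, params.mu, int_dur, tip_n, tip_t)
    return total


@dataclass
class MedusaResult:
    """Outcome of the stepwise shift selection."""

    shifts: list            # postorder node indices, in acceptance order
    shift_tip_sets: list    # tip-name frozensets under each shift
    rate_classes: list      # BDParams; [0] is the base class
    loglik: float
    aicc_single: float
    aicc_best: float
    n_shifts: int
    np: int
    N: int                  # AICc sample size used
    threshold: float
    trajectory: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "shifts": list(self.shifts),
            "shift_tip_sets": [sorted(s) for s in self.shift_tip_sets],
            "rate_classes": [p.to_dict() for p in self.rate_classes],
            "loglik": self.loglik,
            "aicc_single": self.aicc_single,
            "aicc_best": self.aicc_best,
            "n_shifts": self.n_shifts,
            "np": self.np,
            "N": self.N,
            "threshold": self.threshold,
            "trajectory": self.trajectory,
        }


def stepwise_fit(dataset: CladeDataset,
                 threshold: ThresholdParams = DEFAULT_THRESHOLD,
                 max_shifts: Optional[int] = None,
                 aicc_n: Optional[int] = None,
                 include_backbone: bool = True) -> MedusaResult:
    """Greedy forward selection of diversification rate shifts.

    Each round scores every node (internal or tip, except the root) as a
    candidate shift: the candidate's new class is fitted by ML while the
    donor class it takes edges from keeps its parameters; the single best
    candidate is then fully refitted (new class and donor) and accepted if
    the AICc improves by at least ``aicc_threshold(N)``.  Ties on AICc break
    to the lowest postorder node index, making reruns deterministic.

    ``aicc_n`` sets the AICc sample size N (defaults to the number of
    tips).  ``include_backbone=False`` drops the internal-edge P(1 -> 1)
    terms, reducing the single-class model to the plain constant-rate fit
    on (richness, stem age) pairs.
    """
    arrays = _TreeArrays(dataset)
    if not include_backbone:
        arrays.edge_len = arrays.edge_len.copy()
        # zero-duration internal edges contribute log P(1->1 over 0) = 0
        arrays.edge_len[~arrays.is_leaf] = 0.0
    N = aicc_n if aicc_n is not None else arrays.n_tips
    thresh = aicc_threshold(N, threshold)
    if max_shifts is None:
        max_shifts = max(0, (N - 4) // 3)  # keep N - k - 1 > 0 in the AICc

    classes = arrays.paint([])
    base_params, base_ll = _fit_class(*_gather(arrays, classes, 0))
    class_params = [base_params]
    class_ll = [base_ll]
    shifts: list[int] = []
    loglik = base_ll
    k = 2  # parameters so far
    aicc_single = _aicc(loglik, k, N)
    aicc_best = aicc_single
    trajectory = [{"step": 0, "shift": None, "loglik": loglik,
                   "aicc": aicc_single, "np": k}]

    candidates = [i for i in range(len(arrays.nodes)) if i != arrays.root]
    n_refit = 8  # screened candidates promoted to a full refit per round
    while len(shifts) < max_shifts:
        classes = arrays.paint(shifts)
        screened = []  # (delta_ll, node, new_params, donor_cls)
        for node in candidates:
            if node in shifts:
                continue
            donor = int(classes[node])
            sub = [v for v in arrays.subtree(node)
                   if classes[v] == donor]
            sub_mask = np.zeros(len(arrays.nodes), dtype=bool)
            sub_mask[sub] = True
            internal = sub_mask & ~arrays.is_leaf
            tips = sub_mask & arrays.is_leaf
            if not internal.any() and not tips.any():
                continue
            try:
                new_params, new_ll = _fit_class(
                    arrays.edge_len[internal], arrays.tip_n[tips],
                    arrays.edge_len[tips], start=class_params[donor],
                    quick=True)
            except Exception:
                continue  # skip candidates whose optimisation fails
            # screening: quick refit of the donor on its remaining edges too,
            # so candidates that free the donor from a compromise fit are
            # ranked fairly
            donor_sel = (classes == donor) & ~sub_mask
            donor_sel[arrays.root] = False
            d_int = donor_sel & ~arrays.is_leaf
            d_tip = donor_sel & arrays.is_leaf
            if donor_sel.any():
                _, donor_ll = _fit_class(arrays.edge_len[d_int],
                                         arrays.tip_n[d_tip],
                                         arrays.edge_len[d_tip],
                                         start=class_params[donor],
                                         quick=True)
            else:
                donor_ll = 0.0
            delta = (new_ll + donor_ll) - class_ll[donor]
            screened.append((delta, node, new_params, donor))
        if not screened:
            break
        # promote the best-screened candidates to a full refit of both
        # affected classes; choose by the refitted likelihood, ties to the
        # lowest postorder index
        screened.sort(key=lambda item: (-item[0], item[1]))
        best = None  # (trial_loglik, node, new_params, donor, donor_params,
        #               new_ll, donor_ll)
        for _, node, warm, donor in screened[:n_refit]:
            trial_shifts = shifts + [node]
            trial_classes = arrays.paint(trial_shifts)
            new_cls = len(trial_shifts)
            try:
                new_params, new_ll = _fit_class(
                    *_gather(arrays, trial_classes, new_cls), start=warm)
                donor_params, donor_ll = _fit_class(
                    *_gather(arrays, trial_classes, donor),
                    start=class_params[donor])
            except Exception:
                continue
            trial_loglik = (loglik - class_ll[donor]) + donor_ll + new_ll
            if (best is None or trial_loglik > best[0] + 1e-9
                    or (abs(trial_loglik - best[0]) <= 1e-9
                        and node < best[1])):
                best = (trial_loglik, node, new_params, donor, donor_params,
                        new_ll, donor_ll)
        if best is None:
            break
        (trial_loglik, node, new_params, donor, donor_params, new_ll,
         donor_ll) = best
        trial_shifts = shifts + [node]
        k_new = 3 * len(trial_shifts) + 2
        aicc_new = _aicc(trial_loglik, k_new, N)
        if aicc_best - aicc_new < thresh:
            break
        shifts = trial_shifts
        class_params = class_params + [new_params]
        class_params[donor] = donor_params
        class_ll = class_ll + [new_ll]
        class_ll[donor] = donor_ll
        loglik = trial_loglik
        aicc_best = aicc_new
        trajectory.append({"step": len(shifts), "shift": node,
                           "loglik": loglik, "aicc": aicc_best,
                           "np": k_new})

    return MedusaResult(
        shifts=shifts,
        shift_tip_sets=[frozenset(arrays.tips_under(s)) for s in shifts],
        rate_classes=class_params,
        loglik=loglik,
        aicc_single=aicc_single,
        aicc_best=aicc_best,
        n_shifts=len(shifts),
        np=3 * len(shifts) + 2,
        N=N,
        threshold=thresh,
        trajectory=trajectory)


def shift_rate_mle(tree: TimeTree, n_shifts: int) -> float:
    """Poisson ML shift rate: events per My of internal branch length."""
    if n_shifts < 0:
        raise ValueError("n_shifts must be >= 0")
    total = 0.0
    dtree = tree.dendropy_tree
    for node in dtree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        total += node.edge.length or 0.0
    if total <= 0:
        raise ValueError("tree has no internal branch length")
    return n_shifts / total
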