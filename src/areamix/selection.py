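"""Greedy stepwise selection of clustering variables by BIC evidence.

Not every measured variable carries information about the latent group
structure; irrelevant variables inflate the parameter count and can degrade
the clustering. The search here is the Raftery–Dean style greedy algorithm:
at each step a candidate variable is judged by comparing, via BIC, a model in
which it participates in the clustering against one in which it is merely a
linear regression on the already-selected variables. The evidence score is

    E(v | S) = BIC_clust(S ∪ {v}) − [BIC_clust(S) + BIC_reg(v | S)]

where BIC_clust(S) is the best clustering BIC over the (K, covariance-family)
grid on variable set S (defined as 0 for the empty set), and BIC_reg is the
Gaussian linear-regression BIC (intercept-only — i.e. a single-Gaussian
marginal — when S is empty). Positive evidence favors treating v as a
clustering variable.

The search: (1) pick the variable with the most evidence; (2) add the best
second variable; then alternate proposing the best addition (3) and the
weakest current variable for removal (4), accepting either only when the
evidence crosses the threshold, and stop after two consecutive rejected
proposals (5).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMatrix, as_feature_matrix
from .mixture import COVARIANCE_TYPES, ClusteringSolution, select_model

#: Evidence must exceed this (BIC scale) for an addition to be accepted and a
#: current variable to be retained.
DEFAULT_THRESHOLD = 0.0


@dataclass
class SelectionStep:
    """One decision in the greedy trace."""

    action: str  # {add,drop}-{proposed,accepted,rejected}
    variable: str
    evidence: float
    current_set: list[str]


@dataclass
class VariableSelectionResult:
    """Selected variables, the full decision trace, and the final clustering."""

    selected: list[str]
    trace: list[SelectionStep]
    final_solution: ClusteringSolution
    warning: str | None = None

    def summary(self) -> str:
        lines = ["Greedy clustering-variable selection", "=" * 60]
        if self.warning:
            lines.append(f"WARNING: {self.warning}")
        lines.append(f"selected ({len(self.selected)}): {', '.join(self.selected)}")
        lines += ["", f"{'action':>14s}  {'variable':>20s}  {'evidence':>10s}"]
        for s in self.trace:
            lines.append(f"{s.action:>14s}  {s.variable:>20s}  {s.evidence:10.2f}")
        lines += ["", "Final clustering on the selected variables:",
                  self.final_solution.summary()]
        return "\n".join(lines)


def replay_trace(trace: list[SelectionStep]) -> list[str]:
    """Re-execute the accepted decisions of a trace from the empty set."""
    current: list[str] = []
    for step in trace:
        if step.action == "add-accepted":
            current.append(step.variable)
        elif step.action == "drop-accepted":
            current.remove(step.variable)
    return current


def gaussian_regression_bic(y: np.ndarray, X: np.ndarray | None):
    """BIC (2ℓ̂ − p log N) of a Gaussian linear regression of y on X.

    With X empty/None this is the intercept-only model, i.e. the
    single-Gaussian marginal BIC of y. The error variance uses the ML
    estimate RSS/N. Returns (bic, collinear_flag); the flag marks a
    numerically perfect fit (candidate collinear with the regressors).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None or X.size == 0:
        design = np.ones((n, 1))
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = np.column_stack([np.ones(n), X])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    collinear = False
    scale = max(float(y @ y), 1.0)
    if rss <= 1e-12 * scale:
        collinear = True
        rss = 1e-12 * scale  # variance floor keeps the BIC finite
    sigma2 = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    p = design.shape[1] + 1  # coefficients + error variance
    return 2.0 * loglik - p * np.log(n), collinear


class _EvidenceEngine:
    """Caches best clustering BICs per variable set across greedy steps."""

    def __init__(self, fm: FeatureMatrix, k_range, covariance_types, seed,
                 n_starts, max_iter):
        self.fm = fm
        self.k_range = list(k_range)
        self.covariance_types = tuple(covariance_types)
        self.n_starts = n_starts
        self.max_iter = max_iter
        if isinstance(seed, np.random.SeedSequence):
            self._seed_root = seed
        else:
            self._seed_root = np.random.SeedSequence(seed)
        self._cache: dict[frozenset, ClusteringSolution] = {}

    def cluster_solution(self, varset, clustering_only=False) -> ClusteringSolution:
        """Best mixture on a variable set.

        With `clustering_only` the grid is restricted to K >= 2: this is the
        inclusion side of the evidence comparison, where the model must
        actually cluster the candidate (the K=1 cell belongs to the
        "no clustering" alternative).
        """
        k_range = ([k for k in self.k_range if k >= 2] if clustering_only
                   else self.k_range)
        if not k_range:
            raise ValueError("k_range must contain a K >= 2 for the "
                             "clustering side of the evidence comparison")
        key = (frozenset(varset), clustering_only)
        if key not in self._cache:
            # stable per-set seed: same set -> same fit regardless of path
            digest = hashlib.sha256("|".join(sorted(varset)).encode()).hexdigest()
            sub = np.random.SeedSequence(
                entropy=self._seed_root.entropy,
                spawn_key=tuple(self._seed_root.spawn_key)
                + (int(digest[:8], 16), int(clustering_only)))
            self._cache[key] = select_model(
                self.fm.subset(sorted(varset)), k_range=k_range,
                covariance_types=self.covariance_types, seed=sub,
                n_starts=self.n_starts, max_iter=self.max_iter)
        return self._cache[key]

    def cluster_bic(self, varset, clustering_only=False) -> float:
        if not varset:
            return 0.0
        return self.cluster_solution(varset, clustering_only).model.bic

    def evidence(self, included, candidate):
        """Clustering-vs-regression BIC evidence for `candidate` given `included`.

        BIC(mixture with K>=2 on included+candidate) minus
        [BIC(best mixture on included) + BIC(regression of candidate on
        included)]. Positive values mean the candidate carries clustering
        information beyond what the included set explains linearly.
        """
        names = self.fm.variable_names
        y = self.fm.values[:, names.index(candidate)]
        X = (self.fm.values[:, [names.index(v) for v in included]]
             if included else None)
        reg_bic, collinear = gaussian_regression_bic(y, X)
        with_c = self.cluster_bic(set(included) | {candidate},
                                  clustering_only=True)
        without = self.cluster_bic(set(included))
        ev = with_c - (without + reg_bic)
        if collinear:
            warnings.warn(
                f"candidate {candidate!r} is collinear with the included set",
                stacklevel=3)
        return ev


def inclusion_evidence(data, included: list[str], candidate: str,
                       k_range=range(1, 10),
                       covariance_types=COVARIANCE_TYPES, seed=None,
                       n_starts: int = 2, max_iter: int = 500) -> float:
    """BIC evidence that `candidate` carries clustering information.

    Positive values favor adding the candidate to the clustering set; see the
    module docstring for the exact comparison.
    """
    fm = as_feature_matrix(data)
    if candidate in included:
        raise ValueError(f"candidate {candidate!r} already included")
    for v in list(included) + [candidate]:
        if v not in fm.variable_names:
            raise ValueError(f"unknown variable: {v!r}")
    engine = _EvidenceEngine(fm, k_range, covariance_types, seed, n_starts,
                             max_iter)
    return engine.evidence(list(included), candidate)


def greedy_select(data, k_range=range(1, 10),
                  covariance_types=COVARIANCE_TYPES, seed=None,
                  threshold: float = DEFAULT_THRESHOLD, n_starts: int = 2,
                  max_iter: int = 500) -> VariableSelectionResult:
    """Run the greedy add/drop search over all variables of `data`.

    Stops after two consecutive rejected proposals (or when the step budget
    2·D + 20 is exhausted). On null data where no variable shows positive
    first-step evidence, returns the single best variable with a warning
    rather than an empty set. Ties in evidence break alphabetically.
    """
    fm = as_feature_matrix(data)
    if not fm.standardized:
        warnings.warn("variable selection on non-standardized data", stacklevel=2)
    names = sorted(fm.variable_names)  # alphabetical tie-break order
    if len(names) < 2:
        raise ValueError("need at least 2 candidate variables")
    engine = _EvidenceEngine(fm, k_range, covariance_types, seed, n_starts,
                             max_iter)
    trace: list[SelectionStep] = []
    selected: list[str] = []
    warning = None

    def best_candidate(pool, included):
        evs = {v: engine.evidence(included, v) for v in pool}
        best = max(sorted(evs), key=lambda v: evs[v])
        return best, evs[best]

    # Step 1: strongest single clustering variable.
    v1, ev1 = best_candidate(names, [])
    trace.append(SelectionStep("add-proposed", v1, ev1, list(selected)))
    if ev1 <= threshold:
        warning = ("no variable shows positive clustering evidence; "
                   "returning the best single variable")
        selected = [v1]
        trace.append(SelectionStep("add-accepted", v1, ev1, list(selected)))
        sol = engine.cluster_solution(selected)
        return VariableSelectionResult(selected, trace, sol, warning)
    selected = [v1]
    trace.append(SelectionStep("add-accepted", v1, ev1, list(selected)))

    # Step 2: best second variable, added unconditionally.
    v2, ev2 = best_candidate([v for v in names if v not in selected], selected)
    trace.append(SelectionStep("add-proposed", v2, ev2, list(selected)))
    selected.append(v2)
    trace.append(SelectionStep("add-accepted", v2, ev2, list(selected)))

    # Steps 3-5: alternate additions and removals until two straight rejections.
    consecutive_rejections = 0
    budget = 2 * len(names) + 20
    mode = "add"
    while consecutive_rejections < 2 and budget > 0:
        budget -= 1
        if mode == "add":
            pool = [v for v in names if v not in selected]
            if not pool:
                consecutive_rejections += 1
            else:
                v, ev = best_candidate(pool, selected)
                trace.append(SelectionStep("add-proposed", v, ev, list(selected)))
                if ev > threshold:
                    selected.append(v)
                    trace.append(SelectionStep("add-accepted", v, ev, list(selected)))
                    consecutive_rejections = 0
                else:
                    trace.append(SelectionStep("add-rejected", v, ev, list(selected)))
                    consecutive_rejections += 1
            mode = "drop"
        else:
            if len(selected) <= 1:
                consecutive_rejections += 1
            else:
                evs = {v: engine.evidence([u for u in selected if u != v], v)
                       for v in selected}
                v = min(sorted(evs), key=lambda u: evs[u])
                ev = evs[v]
                trace.append(SelectionStep("drop-proposed", v, ev, list(selected)))
                if ev <= threshold:  # exclusion favored
                    selected.remove(v)
                    trace.append(SelectionStep("drop-accepted", v, ev, list(selected)))
                    consecutive_rejections = 0
                else:
                    trace.append(SelectionStep("drop-rejected", v, ev, list(selected)))
                    consecutive_rejections += 1
            mode = "add"

    sol = engine.cluster_solution(selected)
    # keep the user-facing order stable: order of first acceptance
    ordered = [s.variable for s in trace
               if s.action == "add-accepted" and s.variable in selected]
    ordered = list(dict.fromkeys(ordered))
    return VariableSelectionResult(ordered, trace, sol, warning)
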