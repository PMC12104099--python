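"""Variable-length Markov chains: context-tree fitting and imputation.

A VLMC conditions the next state on a *variable* amount of history: the
context tree stores, for every history suffix up to ``max_depth``, the
empirical next-state counts; pruning merges a context into its suffix
when their conditional distributions are close enough.  Two pruning
criteria are supported — the context algorithm (deviance against a
chi-squared quantile) and a Learn-PSA-style probability-ratio rule —
with the threshold chosen by AIC over a candidate list.

Missing-data gaps split sequences into observed subsequences; the model
is fitted on those, and gaps are then filled left to right, each cell
drawn from the tree distribution of the longest context matching the
(observed plus already imputed) prefix.  The very first cell of an
initial gap has no prefix and is drawn from the panel-wide state
distribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .mict import MultipleImputation
from .panel import MISSING, SequencePanel

#: published candidate thresholds
CONTEXT_QUANTILES = (0.1, 0.05, 0.04, 0.03, 0.02, 0.01, 0.001)
PSA_RATIOS = (1.0, 1.05, 1.1, 1.2, 1.5)


class ContextTree:
    """Counts of next states keyed by context.

    A context is a tuple of state codes read backwards from the present:
    ``(x_{t-1}, x_{t-2}, ...)``; the root is the empty tuple.
    """

    def __init__(self, n_states: int, max_depth: int):
        self.n_states = n_states
        self.max_depth = max_depth
        self.counts: dict[tuple[int, ...], np.ndarray] = {}

    def nodes(self) -> list[tuple[int, ...]]:
        return list(self.counts)

    def children(self, ctx: tuple[int, ...]) -> list[tuple[int, ...]]:
        return [c for c in self.counts
                if len(c) == len(ctx) + 1 and c[:len(ctx)] == ctx]

    def leaves(self) -> list[tuple[int, ...]]:
        return [c for c in self.counts if not self.children(c)]

    def longest_context(self, history: np.ndarray) -> tuple[int, ...]:
        """Deepest stored context matching ``history`` (a 1-D array in
        natural time order; the last element is the most recent)."""
        ctx: tuple[int, ...] = ()
        for back in range(1, min(len(history), self.max_depth) + 1):
            nxt = ctx + (int(history[-back]),)
            if nxt in self.counts:
                ctx = nxt
            else:
                break
        return ctx

    def distribution(self, ctx: tuple[int, ...], smooth: float = 0.0) -> np.ndarray:
        c = self.counts[ctx].astype(float) + smooth
        return c / c.sum()

    def restrict(self, keep: set[tuple[int, ...]]) -> "ContextTree":
        out = ContextTree(self.n_states, self.max_depth)
        out.counts = {c: self.counts[c].copy() for c in keep}
        return out

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "max_depth": self.max_depth,
            "counts": {",".join(map(str, k)): v.tolist()
                       for k, v in self.counts.items()},
        }


def observed_subsequences(panel: SequencePanel) -> list[np.ndarray]:
    """Maximal observed runs of every sequence (gaps split sequences)."""
    subs = []
    for i in range(panel.n):
        row = panel.data[i]
        j = 0
        while j < panel.T:
            if row[j] < 0:
                j += 1
                continue
            start = j
            while j < panel.T and row[j] >= 0:
                j += 1
            subs.append(row[start:j].copy())
    return subs


def grow_tree(subsequences: list[np.ndarray], n_states: int,
              max_depth: int = 6) -> ContextTree:
    """Tally next-state counts for every context up to ``max_depth``.

    Positions near a subsequence start contribute to the (truncated)
    contexts they do have, so a node's counts equal the sum over its
    children plus boundary-truncated occurrences.
    """
    if not any(len(s) >= 2 for s in subsequences):
        raise ValueError("need at least one subsequence of length >= 2")
    tree = ContextTree(n_states, max_depth)
    counts = tree.counts
    for s in subsequences:
        s = np.asarray(s)
        for i in range(len(s)):
            nxt = int(s[i])
            for d in range(min(i, max_depth) + 1):
                ctx = tuple(int(x) for x in s[i - d:i][::-1])
                node = counts.get(ctx)
                if node is None:
                    node = counts[ctx] = np.zeros(n_states, dtype=np.int64)
                node[nxt] += 1
    return tree


def _kept_by_parent_chain(tree: ContextTree,
                          passes: dict[tuple[int, ...], bool]) -> set:
    """A node survives iff it passes its own test and every ancestor
    does (descendants of removed nodes are removed)."""
    keep = {()}
    for ctx in sorted(tree.counts, key=len):
        if not ctx:
            continue
        if ctx[:-1] in keep and passes.get(ctx, False):
            keep.add(ctx)
    return keep


def prune_context(tree: ContextTree, q: float) -> ContextTree:
    """Context-algorithm pruning: a node is kept when the deviance of
    its next-state distribution against its suffix's exceeds the
    (1-q) chi-squared quantile with |alphabet|-1 degrees of freedom."""
    thr = stats.chi2.ppf(1.0 - q, df=tree.n_states - 1)
    passes: dict[tuple[int, ...], bool] = {}
    for ctx in tree.counts:
        if not ctx:
            continue
        parent = ctx[:-1]
        n_c = tree.counts[ctx].astype(float)
        if n_c.sum() == 0:
            passes[ctx] = False
            continue
        p_c = n_c / n_c.sum()
        n_p = tree.counts[parent].astype(float)
        p_p = n_p / n_p.sum()
        nz = n_c > 0
        dev = 2.0 * float(np.sum(n_c[nz] * np.log(p_c[nz] / p_p[nz])))
        passes[ctx] = dev > thr
    return tree.restrict(_kept_by_parent_chain(tree, passes))


def prune_psa(tree: ContextTree, r: float, min_count: int = 2) -> ContextTree:
    """Learn-PSA-style pruning: a node is kept when some observed next
    state's conditional probability differs from the suffix's by a
    factor of at least ``r``.  Contexts occurring fewer than
    ``min_count`` times are pruned regardless."""
    if r < 1:
        raise ValueError("ratio threshold must be >= 1")
    passes: dict[tuple[int, ...], bool] = {}
    for ctx in tree.counts:
        if not ctx:
            continue
        n_c = tree.counts[ctx].astype(float)
        tot = n_c.sum()
        if tot < min_count:
            passes[ctx] = False
            continue
        parent = ctx[:-1]
        p_c = n_c / tot
        n_p = tree.counts[parent].astype(float)
        p_p = n_p / n_p.sum()
        nz = n_c > 0
        ratio = p_c[nz] / p_p[nz]
        passes[ctx] = bool(np.any((ratio >= r) | (ratio <= 1.0 / r)))
    return tree.restrict(_kept_by_parent_chain(tree, passes))


def tree_loglik(tree: ContextTree, subsequences: list[np.ndarray]) -> float:
    """Log-likelihood of the subsequences under longest-matching-context
    prediction with the tree's empirical (MLE) distributions."""
    ll = 0.0
    for s in subsequences:
        s = np.asarray(s)
        for i in range(len(s)):
            ctx = tree.longest_context(s[:i])
            p = tree.distribution(ctx)
            ll += float(np.log(p[int(s[i])]))
    return ll


def tree_aic(tree: ContextTree, subsequences: list[np.ndarray]) -> float:
    """AIC with one free distribution per terminal (leaf) context."""
    k = len(tree.leaves()) * (tree.n_states - 1)
    return -2.0 * tree_loglik(tree, subsequences) + 2.0 * k


@dataclasses.dataclass
class VlmcFitConfig:
    algorithm: str = "context"          # "context" | "learn_psa"
    thresholds: tuple[float, ...] | None = None
    max_depth: int = 6

    def candidates(self) -> tuple[float, ...]:
        if self.thresholds is not None:
            return tuple(self.thresholds)
        return CONTEXT_QUANTILES if self.algorithm == "context" else PSA_RATIOS


def select_model(subsequences: list[np.ndarray], n_states: int,
                 cfg: VlmcFitConfig) -> tuple[ContextTree, float]:
    """Fit and prune at each candidate threshold; return the AIC argmin
    (ties broken toward the smaller tree) and the chosen threshold."""
    full = grow_tree(subsequences, n_states, cfg.max_depth)
    best = None
    for thr in cfg.candidates():
        if cfg.algorithm == "context":
            tree = prune_context(full, thr)
        elif cfg.algorithm == "learn_psa":
            tree = prune_psa(full, thr)
        else:
            raise ValueError(f"unknown algorithm {cfg.algorithm!r}")
        aic = tree_aic(tree, subsequences)
        size = len(tree.counts)
        if best is None or (aic, size) < (best[0], best[1]):
            best = (aic, size, tree, thr)
    return best[2], best[3]


class VLMCImputer(TransformerMixin, BaseEstimator):
    """Left-to-right gap imputation driven by a fitted context tree.

    The tree is fitted once on the observed subsequences; the M
    imputations differ only through the random draws.  Draw
    probabilities are add-1/|alphabet| smoothed so unseen continuations
    stay possible.
    """

    _method_name = "vlmc"

    def __init__(self, algorithm: str = "context",
                 thresholds: tuple[float, ...] | None = None,
                 max_depth: int = 6, random_state: int | None = None):
        self.algorithm = algorithm
        self.thresholds = thresholds
        self.max_depth = max_depth
        self.random_state = random_state

    def _as_panel(self, X) -> SequencePanel:
        from .mict import MICTImputer
        return MICTImputer._as_panel(self, X)

    def fit(self, X, y=None):
        panel = self._as_panel(X)
        cfg = VlmcFitConfig(self.algorithm, self.thresholds, self.max_depth)
        subs = observed_subsequences(panel)
        self.tree_, self.threshold_ = select_model(subs, panel.n_states, cfg)
        counts = np.bincount(panel.data[panel.data >= 0],
                             minlength=panel.n_states).astype(float)
        self.marginal_ = counts / counts.sum()
        self.n_features_in_ = panel.T
        return self

    def transform(self, X) -> np.ndarray:
        return self.impute(self._as_panel(X), M=1).panels[0].data

    def impute(self, panel: SequencePanel, M: int = 1) -> MultipleImputation:
        if M < 1:
            raise ValueError("M must be >= 1")
        if panel.is_complete():
            raise ValueError("nothing to impute: the panel is complete")
        if not hasattr(self, "tree_"):
            self.fit(panel)
        smooth = 1.0 / panel.n_states
        panels = []
        ss = np.random.SeedSequence(self.random_state)
        for child in ss.spawn(M):
            rng = np.random.default_rng(child)
            W = panel.data.copy()
            for i in range(panel.n):
                for t0 in range(panel.T):
                    if W[i, t0] != MISSING:
                        continue
                    # contiguous known prefix ending just before t0
                    start = t0
                    while start > 0 and W[i, start - 1] >= 0:
                        start -= 1
                    prefix = W[i, start:t0]
                    if prefix.size == 0:
                        p = self.marginal_
                    else:
                        ctx = self.tree_.longest_context(prefix)
                        p = self.tree_.distribution(ctx, smooth=smooth)
                    W[i, t0] = rng.choice(panel.n_states, p=p)
            panels.append(panel.copy(data=W))
        return MultipleImputation(panels=panels, method=self._method_name,
                                  config=self.get_params(),
                                  seed=self.random_state, fit_log=[])


def vlmc_impute(panel: SequencePanel, M: int = 1, **params) -> MultipleImputation:
    """Fit a VLMC on the observed subsequences and impute M times."""
    return VLMCImputer(**params).impute(panel, M=M)
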