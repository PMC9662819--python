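"""Neural-network hotspot classifier and feature-combination search.

The classifier is a deliberately small fully connected network — one
hidden layer of 10 ReLU units and a 2-unit softmax output — trained with
Xavier (Glorot) initialization, the Adam optimizer at learning rate 7e-4
and categorical cross-entropy, optionally with a batch-normalization layer
in front of the hidden layer (used for high-dimensional per-mutation
embeddings) and per-class loss weights. It is implemented directly in
numpy: the model is tiny, training is a handful of dense matmuls, and
holding the weights as plain arrays makes warm-started fine-tuning (for
cross-protein transfer learning) trivial.

The fitness of a feature combination is the mean test F1 over 5 repeats of
stratified fivefold cross-validation. Combinations of 1-3 features are
ranked exhaustively; for 4-10 features a genetic algorithm evolves a pool
of 300 combinations by single-feature point mutations with truncation
selection over parents and offspring, never re-evaluating a combination
(an archive of everything evaluated is kept), which makes the best fitness
non-decreasing across generations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap


@njit(cache=False)
def _adam_update(param, g, m, v, lr_t):
    p = param.ravel()
    gf = g.ravel()
    mf = m.ravel()
    vf = v.ravel()
    for i in range(p.size):
        mf[i] = 0.9 * mf[i] + 0.1 * gf[i]
        vf[i] = 0.999 * vf[i] + 0.001 * gf[i] * gf[i]
        p[i] -= lr_t * mf[i] / (np.sqrt(vf[i]) + 1e-8)


@njit(cache=False)
def _train_fullbatch(X, Y, w, W1, b1, W2, b2,
                     mW1, vW1, mb1, vb1, mW2, vW2, mb2, vb2,
                     epochs, lr, t_start):
    """Compiled full-batch Adam training loop (no batch norm)."""
    n = X.shape[0]
    t = t_start
    for _ in range(epochs):
        pre = X @ W1 + b1
        H = np.maximum(pre, 0.0)
        logits = H @ W2 + b2
        P = np.empty_like(logits)
        for i in range(n):
            mx = max(logits[i, 0], logits[i, 1])
            e0 = np.exp(logits[i, 0] - mx)
            e1 = np.exp(logits[i, 1] - mx)
            s = e0 + e1
            P[i, 0] = e0 / s
            P[i, 1] = e1 / s
        dlog = P - Y
        for i in range(n):
            f = w[i] / n
            dlog[i, 0] *= f
            dlog[i, 1] *= f
        gW2 = H.T @ dlog
        gb2 = dlog.sum(0)
        dH = dlog @ W2.T
        dpre = dH * (pre > 0)
        gW1 = X.T @ dpre
        gb1 = dpre.sum(0)
        t += 1
        lr_t = lr * np.sqrt(1 - 0.999 ** t) / (1 - 0.9 ** t)
        _adam_update(W1, gW1, mW1, vW1, lr_t)
        _adam_update(b1, gb1, mb1, vb1, lr_t)
        _adam_update(W2, gW2, mW2, vW2, lr_t)
        _adam_update(b2, gb2, mb2, vb2, lr_t)
    return t


# ---------------------------------------------------------------------------
# Network specification and implementation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NNSpec:
    """Hyperparameters of the shallow classifier.

    ``epochs`` defaults to 1000 full-batch passes with no early stopping —
    at learning rate 7e-4 the cross-validated F1 of this model size
    plateaus by then on datasets of a few hundred residues.
    ``batch_norm`` is reserved for the wide per-mutation feature variants;
    ``class_weights`` optionally reweights the two classes in the loss.
    """

    hidden_units: int = 10
    learning_rate: float = 7e-4
    epochs: int = 1000
    batch_size: int | None = None          # None = full batch
    batch_norm: bool = False
    class_weights: tuple | None = None
    seed_offset: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class ShallowNet:
    """Feedforward net: [batch-norm] -> 10 ReLU -> 2 softmax, Adam training."""

    def __init__(self, n_in: int, spec: NNSpec, seed: int = 0):
        self.spec = spec
        self.n_in = n_in
        rng = np.random.default_rng(seed)
        h = spec.hidden_units
        lim1 = math.sqrt(6.0 / (n_in + h))
        lim2 = math.sqrt(6.0 / (h + 2))
        self.params = {
            "W1": rng.uniform(-lim1, lim1, (n_in, h)),
            "b1": np.zeros(h),
            "W2": rng.uniform(-lim2, lim2, (h, 2)),
            "b2": np.zeros(2),
        }
        if spec.batch_norm:
            self.params["gamma"] = np.ones(n_in)
            self.params["beta"] = np.zeros(n_in)
            self.bn_mean = np.zeros(n_in)
            self.bn_var = np.ones(n_in)
        self._adam = {k: (np.zeros_like(v), np.zeros_like(v))
                      for k, v in self.params.items()}
        self._adam_t = 0
        self._rng = rng

    def copy(self) -> "ShallowNet":
        clone = ShallowNet.__new__(ShallowNet)
        clone.spec = self.spec
        clone.n_in = self.n_in
        clone.params = {k: v.copy() for k, v in self.params.items()}
        clone._adam = {k: (m.copy(), v.copy()) for k, (m, v) in self._adam.items()}
        clone._adam_t = self._adam_t
        clone._rng = np.random.default_rng(self._rng.integers(2**31))
        if self.spec.batch_norm:
            clone.bn_mean = self.bn_mean.copy()
            clone.bn_var = self.bn_var.copy()
        return clone

    def reset_optimizer(self) -> "ShallowNet":
        """Zero the Adam moment estimates (fresh optimizer, same weights)."""
        self._adam = {k: (np.zeros_like(v), np.zeros_like(v))
                      for k, v in self.params.items()}
        self._adam_t = 0
        return self

    # -- forward/backward ---------------------------------------------------

    def _forward(self, X, train: bool):
        cache = {}
        A0 = X
        if self.spec.batch_norm:
            if train and X.shape[0] > 1:
                mu, var = X.mean(0), X.var(0)
                self.bn_mean = 0.9 * self.bn_mean + 0.1 * mu
                self.bn_var = 0.9 * self.bn_var + 0.1 * var
            else:
                mu, var = self.bn_mean, self.bn_var
            Z = (X - mu) / np.sqrt(var + 1e-5)
            A0 = self.params["gamma"] * Z + self.params["beta"]
            cache["Z"] = Z
        pre = A0 @ self.params["W1"] + self.params["b1"]
        H = np.maximum(pre, 0.0)
        logits = H @ self.params["W2"] + self.params["b2"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        P = e / e.sum(axis=1, keepdims=True)
        cache.update(A0=A0, pre=pre, H=H, P=P)
        return cache

    def _step(self, X, Y, w):
        cache = self._forward(X, train=True)
        n = X.shape[0]
        params = self.params
        dlogits = w[:, None] * (cache["P"] - Y)
        dlogits /= n
        grads = {
            "W2": cache["H"].T @ dlogits,
            "b2": dlogits.sum(0),
        }
        dH = dlogits @ params["W2"].T
        dpre = dH * (cache["pre"] > 0)
        grads["W1"] = cache["A0"].T @ dpre
        grads["b1"] = dpre.sum(0)
        if self.spec.batch_norm:
            dA0 = dpre @ params["W1"].T
            grads["gamma"] = (dA0 * cache["Z"]).sum(0)
            grads["beta"] = dA0.sum(0)
        self._adam_t += 1
        t = self._adam_t
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        # bias-corrected step size folded into lr to save per-parameter ops
        lr_t = lr * math.sqrt(1 - b2 ** t) / (1 - b1 ** t)
        adam = self._adam
        for k, g in grads.items():
            m, v = adam[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            params[k] -= lr_t * m / (np.sqrt(v) + eps)

    def fit(self, X, y, epochs: int | None = None) -> "ShallowNet":
        """Train (or continue training) on X, y. Returns self."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        Y = np.eye(2)[y]
        if self.spec.class_weights is not None:
            cw = np.asarray(self.spec.class_weights, dtype=float)
            w = cw[y]
        else:
            w = np.ones(len(y))
        n_epochs = self.spec.epochs if epochs is None else epochs
        bs = self.spec.batch_size
        full_batch = bs is None or bs >= len(y)
        if full_batch and not self.spec.batch_norm and _HAVE_NUMBA:
            p, ad = self.params, self._adam
            self._adam_t = _train_fullbatch(
                np.ascontiguousarray(X), Y, w,
                p["W1"], p["b1"], p["W2"], p["b2"],
                ad["W1"][0], ad["W1"][1], ad["b1"][0], ad["b1"][1],
                ad["W2"][0], ad["W2"][1], ad["b2"][0], ad["b2"][1],
                n_epochs, self.spec.learning_rate, self._adam_t,
            )
            return self
        for _ in range(n_epochs):
            if full_batch:
                self._step(X, Y, w)
            else:
                order = self._rng.permutation(len(y))
                for start in range(0, len(y), bs):
                    idx = order[start:start + bs]
                    self._step(X[idx], Y[idx], w[idx])
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float), train=False)["P"]

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


# ---------------------------------------------------------------------------
# Confusion counts and F1
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionSummary:
    TP: int
    FP: int
    TN: int
    FN: int
    recall: float
    precision: float
    f1: float


def confusion_f1(predictions, labels) -> ConfusionSummary:
    """Recall, precision and F1 from binary predictions vs labels.

    Zero-denominator cases (no predicted positives, no actual positives,
    or recall + precision = 0) are defined as 0.
    """
    pred = np.asarray(predictions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.shape != lab.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {lab.shape}")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    tp = int(np.sum((pred == 1) & (lab == 1)))
    fp = int(np.sum((pred == 1) & (lab == 0)))
    tn = int(np.sum((pred == 0) & (lab == 0)))
    fn = int(np.sum((pred == 0) & (lab == 1)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * recall * precision / (recall + precision)) if recall + precision else 0.0
    return ConfusionSummary(tp, fp, tn, fn, recall, precision, f1)


# ---------------------------------------------------------------------------
# Feature-combination fitness
# ---------------------------------------------------------------------------

def feature_columns(matrix: pd.DataFrame) -> list:
    return [c for c in matrix.columns if c != "label"]


def resolve_combo(matrix: pd.DataFrame, combo) -> tuple:
    """Normalize a combination to a tuple of column names in registry order.

    Integer entries are 1-based indices into the matrix's feature columns
    (the conventional 1..27 feature numbering). The returned tuple is
    ordered by column position, so a combination is a set: any permutation
    of the same features resolves (and therefore trains) identically.
    """
    cols = feature_columns(matrix)
    names = []
    for item in combo:
        if isinstance(item, (int, np.integer)):
            if not 1 <= item <= len(cols):
                raise ValueError(f"feature index {item} outside 1..{len(cols)}")
            names.append(cols[item - 1])
        elif item in cols:
            names.append(item)
        else:
            raise ValueError(f"unknown feature {item!r}")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate features in combination: {names}")
    return tuple(sorted(names, key=cols.index))


def standardize(train: np.ndarray, *others):
    """Z-score by train-set statistics (zero-spread columns left unscaled)."""
    mu = train.mean(0)
    sd = train.std(0)
    sd[sd == 0] = 1.0
    return tuple((a - mu) / sd for a in (train, *others))


def train_eval(matrix: pd.DataFrame, combo, spec: NNSpec,
               train_idx, test_idx, seed: int = 0) -> ConfusionSummary:
    """Train on the selected feature columns and score the held-out set."""
    names = resolve_combo(matrix, combo)
    X = matrix[list(names)].to_numpy(dtype=float)
    y = matrix["label"].to_numpy(dtype=int)
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test index sets overlap")
    ytr = y[train_idx]
    if len(np.unique(ytr)) < 2:
        raise ValueError("training fold contains a single class")
    Xtr, Xte = standardize(X[train_idx], X[test_idx])
    net = ShallowNet(len(names), spec, seed=seed + spec.seed_offset)
    net.fit(Xtr, ytr)
    return confusion_f1(net.predict(Xte), y[test_idx])


def cv_fitness(matrix: pd.DataFrame, combo, spec: NNSpec,
               n_repeats: int = 5, k: int = 5, seed: int = 0,
               stratified: bool = True, return_folds: bool = False):
    """Mean test F1 over ``n_repeats`` rounds of ``k``-fold cross-validation.

    Partitions are stratified by class and reshuffled each repeat. A fold
    whose training split lacks a class (possible only in non-stratified
    mode) triggers a logged re-draw of that repeat's partition.
    """
    y = matrix["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("feature matrix contains a single class")
    if len(y) < k:
        raise ValueError(f"need at least k={k} samples")
    combo = resolve_combo(matrix, combo)
    f1s = []
    for rep in range(n_repeats):
        redraw = 0
        while True:
            rs = seed * 1000 + rep * 10 + redraw
            splitter = (StratifiedKFold(k, shuffle=True, random_state=rs)
                        if stratified else KFold(k, shuffle=True, random_state=rs))
            try:
                rep_f1s = [
                    train_eval(matrix, combo, spec, tr, te, seed=rs * 10 + fold).f1
                    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y))
                ]
                break
            except ValueError as exc:
                redraw += 1
                if redraw > 5:
                    raise
                logger.info("re-drawing CV partition (repeat %d): %s", rep, exc)
        f1s.extend(rep_f1s)
    fitness = float(np.mean(f1s))
    return (fitness, f1s) if return_folds else fitness


# ---------------------------------------------------------------------------
# Exhaustive and genetic search
# ---------------------------------------------------------------------------

def exhaustive_search(matrix: pd.DataFrame, p: int, spec: NNSpec,
                      seed: int = 0, n_repeats: int = 5, k: int = 5) -> pd.DataFrame:
    """Evaluate every p-feature combination (p <= 3), ranked by fitness."""
    if p not in (1, 2, 3):
        raise ValueError("exhaustive search is for p in {1,2,3}; use ga_select for larger p")
    cols = feature_columns(matrix)
    rows = []
    for combo in itertools.combinations(cols, p):
        fit = cv_fitness(matrix, combo, spec, n_repeats=n_repeats, k=k, seed=seed)
        rows.append((combo, fit))
    df = pd.DataFrame(rows, columns=["combo", "fitness"])
    return df.sort_values(
        ["fitness", "combo"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


@dataclass
class GAState:
    """Final state of a genetic-algorithm feature search."""

    pool: pd.DataFrame                 # combo, fitness (current generation)
    archive: dict                      # every evaluated combo -> fitness
    best_trace: list = field(default_factory=list)
    mean_trace: list = field(default_factory=list)
    generations_run: int = 0
    seed: int = 0

    @property
    def best(self) -> tuple:
        row = self.pool.iloc[0]
        return tuple(row["combo"]), float(row["fitness"])


def _sorted_pool(entries) -> pd.DataFrame:
    df = pd.DataFrame(entries, columns=["combo", "fitness"])
    return df.sort_values(
        ["fitness", "combo"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def ga_select(matrix: pd.DataFrame, p: int, spec: NNSpec,
              pool_size: int = 300, generations: int = 15, seed: int = 0,
              patience: int = 5, n_repeats: int = 5, k: int = 5) -> GAState:
    """Evolutionary search over p-feature combinations (p in 4..10).

    Generation 1 is a random pool of distinct combinations. Each parent
    produces one son by a single-feature point mutation, chosen so the son
    has never been evaluated; sons and parents compete, and the fittest
    ``pool_size`` survive. Terminates at the generation budget or when the
    best fitness has not improved for ``patience`` generations.
    """
    cols = feature_columns(matrix)
    n_feat = len(cols)
    if math.comb(n_feat, p) <= pool_size:
        raise ValueError(
            f"C({n_feat},{p}) <= pool_size={pool_size}; use exhaustive evaluation"
        )
    rng = np.random.default_rng(seed)

    # every combination is scored on the same CV partitions (seed fixed per
    # search), so fitness comparisons between combinations are paired and
    # selection is not driven by partition luck
    def evaluate(combo):
        return cv_fitness(matrix, combo, spec, n_repeats=n_repeats, k=k,
                          seed=seed)

    archive: dict[tuple, float] = {}
    pool = set()
    while len(pool) < pool_size:
        combo = tuple(sorted(rng.choice(cols, size=p, replace=False).tolist()))
        pool.add(combo)
    entries = []
    for combo in sorted(pool):
        fit = evaluate(combo)
        archive[combo] = fit
        entries.append((combo, fit))
    pool_df = _sorted_pool(entries)

    state = GAState(pool=pool_df, archive=archive, seed=seed)
    state.best_trace.append(float(pool_df["fitness"].iloc[0]))
    state.mean_trace.append(float(pool_df["fitness"].mean()))
    state.generations_run = 1

    stalled = 0
    for _ in range(2, generations + 1):
        sons = set()
        son_entries = []
        for combo in pool_df["combo"]:
            parent = tuple(combo)
            son = _point_mutation(parent, cols, archive, sons, rng)
            if son is None:
                logger.info("no unevaluated neighbor for %s; parent passes unchanged",
                            parent)
                continue
            sons.add(son)
        for son in sorted(sons):
            fit = evaluate(son)
            archive[son] = fit
            son_entries.append((son, fit))
        combined = list(zip(pool_df["combo"], pool_df["fitness"])) + son_entries
        pool_df = _sorted_pool(combined).head(pool_size).reset_index(drop=True)
        state.generations_run += 1
        best = float(pool_df["fitness"].iloc[0])
        state.best_trace.append(best)
        state.mean_trace.append(float(pool_df["fitness"].mean()))
        if best <= state.best_trace[-2] + 1e-12:
            stalled += 1
            if stalled >= patience:
                break
        else:
            stalled = 0
    state.pool = pool_df
    return state


def _point_mutation(parent, cols, archive, pending, rng):
    """One-feature swap producing a combination never evaluated, or None."""
    positions = rng.permutation(len(parent))
    in_parent = set(parent)
    replacements = [c for c in cols if c not in in_parent]
    for pos in positions:
        for repl in rng.permutation(replacements):
            son = list(parent)
            son[pos] = repl
            son = tuple(sorted(son))
            if son not in archive and son not in pending:
                return son
    return None


# ---------------------------------------------------------------------------
# Feature-frequency analysis and random baseline
# ---------------------------------------------------------------------------

def feature_frequency(results_by_p: dict, top_k: int = 10,
                      feature_names=None):
    """Occurrence counts of each feature among the top-k combinations per p.

    ``results_by_p`` maps p -> a DataFrame with ``combo`` (tuple of feature
    names) and ``fitness``, sorted descending. Returns (freq, summary):
    ``freq`` is features x p counts; ``summary`` holds the mean fitness of
    the combinations counted at each p and how many were counted (fewer
    than ``top_k`` results are used in full, noted by n_models < top_k).
    """
    if feature_names is None:
        from .structure import FEATURE_NAMES as feature_names  # noqa: N811
    ps = sorted(results_by_p)
    freq = pd.DataFrame(0, index=list(feature_names), columns=ps)
    mean_f1, n_models = {}, {}
    for p in ps:
        df = results_by_p[p]
        top = df.head(top_k)
        n_models[p] = len(top)
        mean_f1[p] = float(top["fitness"].mean()) if len(top) else float("nan")
        for combo in top["combo"]:
            for feat in combo:
                freq.loc[feat, p] += 1
    summary = pd.DataFrame({"mean_f1_top": mean_f1, "n_models": n_models}).T
    return freq, summary


def random_baseline(labels) -> float:
    """F1 of a coin-flip model: the hotspot prevalence of the label vector."""
    lab = np.asarray(labels, dtype=float)
    if lab.size == 0:
        raise ValueError("empty label vector")
    return float(lab.mean())
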