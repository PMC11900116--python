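"""The seven-learner bank used to classify miRNAs as disease-associated or random.

Learners share one interface: ``fit_model(spec, table)`` returns a
:class:`TrainedModel` whose ``predict_proba`` maps rows of an aligned feature
table to P(selected).  Four pieces are implemented from first principles
because their update rules are the point:

* Naïve Bayes — posterior ∝ prior × ∏ likelihoods, with add-1 (Laplace)
  Bernoulli estimates on one-hot columns and per-class Gaussians on numeric
  descriptors.
* the Hoeffding bound ε = sqrt(R²·ln(1/δ) / 2n) and the streaming decision
  tree (VFDT) it governs: a leaf splits once the observed gap between its two
  best attributes exceeds ε (or ε falls below a tie threshold).
* the AdaBoost.M1 reweighting β_t = ε_t/(1−ε_t): correctly classified
  instances are down-weighted by β_t each round and the committee votes with
  weight log(1/β_t).
* the sequential network — a dense feed-forward net, input→100→70→50→30→1,
  ReLU on the four hidden layers and a sigmoid output, trained by
  backpropagation with adaptive-moment gradient descent on binary
  cross-entropy.

Random tree, random forest (bagged random trees), and the WEKA-style shallow
MLP delegate tree/perceptron induction to scikit-learn behind the same
interface.  Numeric descriptor columns are z-scored with training-fold
statistics before gradient-trained learners see them; one-hot columns pass
through untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .core import FeatureTable

CLASSIFIER_NAMES = (
    "naive_bayes",
    "random_tree",
    "random_forest",
    "adaboost_m1",
    "hoeffding_tree",
    "mlp",
    "sequential_nn",
)

SEQUENTIAL_LAYERS = (100, 70, 50, 30)


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")


@dataclass
class TrainedModel:
    """A fitted learner bound to the exact training columns.

    Prediction refuses tables whose columns differ from ``feature_names``;
    z-scoring statistics (if any) travel with the model.
    """

    spec: ClassifierSpec
    learner: object
    feature_names: list[str]
    scaler: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None  # mask, mean, std

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} columns, got {X.shape[1]}"
            )
        if self.scaler is not None:
            mask, mean, std = self.scaler
            X = X.copy()
            X[:, mask] = (X[:, mask] - mean) / std
        return X

    def predict_proba(self, table: FeatureTable | np.ndarray) -> np.ndarray:
        """P(selected) per row."""
        if isinstance(table, FeatureTable):
            if table.feature_names != self.feature_names:
                missing = set(self.feature_names) - set(table.feature_names)
                extra = set(table.feature_names) - set(self.feature_names)
                raise ValueError(
                    f"column mismatch: missing={sorted(missing)} extra={sorted(extra)}"
                )
            X = table.matrix
        else:
            X = table
        return self.learner.predict_proba_rows(self._prepare(X))

    def predict(self, table: FeatureTable | np.ndarray) -> np.ndarray:
        """Hard 0/1 labels at the 0.5 threshold."""
        return (self.predict_proba(table) >= 0.5).astype(int)


def _binary_mask(X: np.ndarray) -> np.ndarray:
    return np.array([np.isin(np.unique(X[:, j]), (0.0, 1.0)).all() for j in range(X.shape[1])])


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    numeric = ~_binary_mask(X)
    if not numeric.any():
        return None
    mean = X[:, numeric].mean(axis=0)
    std = X[:, numeric].std(axis=0)
    std[std == 0.0] = 1.0
    return numeric, mean, std


# ---------------------------------------------------------------------------
# Naïve Bayes


class NaiveBayes:
    """Bernoulli/Gaussian Naïve Bayes with add-1 smoothing on binary columns."""

    VAR_FLOOR = 1e-9

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NaiveBayes":
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        self.classes_ = classes
        self.binary_ = _binary_mask(X)
        self.log_prior_ = {}
        self.bern_ = {}   # class -> P(x=1) per binary column
        self.gauss_ = {}  # class -> (mean, var) per numeric column
        n = len(y)
        for c in classes:
            Xc = X[y == c]
            nc = len(Xc)
            self.log_prior_[c] = math.log(nc / n)
            if self.binary_.any():
                ones = Xc[:, self.binary_].sum(axis=0)
                self.bern_[c] = (ones + 1.0) / (nc + 2.0)
            if (~self.binary_).any():
                mu = Xc[:, ~self.binary_].mean(axis=0)
                var = Xc[:, ~self.binary_].var(axis=0)
                self.gauss_[c] = (mu, np.maximum(var, self.VAR_FLOOR))
        return self

    def _log_likelihood(self, X: np.ndarray, c) -> np.ndarray:
        ll = np.full(X.shape[0], self.log_prior_[c])
        if self.binary_.any():
            p = self.bern_[c]
            B = X[:, self.binary_]
            ll += (B * np.log(p) + (1.0 - B) * np.log(1.0 - p)).sum(axis=1)
        if (~self.binary_).any():
            mu, var = self.gauss_[c]
            G = X[:, ~self.binary_]
            ll += (-0.5 * (np.log(2 * np.pi * var) + (G - mu) ** 2 / var)).sum(axis=1)
        return ll

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:
        logp = np.column_stack([self._log_likelihood(X, c) for c in self.classes_])
        logp -= logp.max(axis=1, keepdims=True)
        post = np.exp(logp)
        post /= post.sum(axis=1, keepdims=True)
        # column of the positive class (label 1)
        pos = int(np.where(self.classes_ == 1)[0][0])
        return post[:, pos]

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        """Full posterior matrix, one column per class in ``classes_`` order."""
        logp = np.column_stack([self._log_likelihood(X, c) for c in self.classes_])
        logp -= logp.max(axis=1, keepdims=True)
        post = np.exp(logp)
        return post / post.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Hoeffding bound and streaming tree


def hoeffding_bound(R: float, delta: float, n: int) -> float:
    """Confidence radius ε = sqrt(R²·ln(1/δ) / (2n)).

    After n observations of a statistic with range R, the true mean lies
    within ε of the observed mean with probability 1 − δ, regardless of the
    generating distribution.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.sqrt(R * R * math.log(1.0 / delta) / (2.0 * n))


class _HoeffdingLeaf:
    __slots__ = ("class_counts", "attr_counts", "n_since_eval")

    def __init__(self, n_features: int):
        self.class_counts = np.zeros(2)
        # per feature: {value_code: [count_class0, count_class1]}
        self.attr_counts = [dict() for _ in range(n_features)]
        self.n_since_eval = 0

    def observe(self, codes: np.ndarray, label: int) -> None:
        self.class_counts[label] += 1
        self.n_since_eval += 1
        for j, v in enumerate(codes):
            cell = self.attr_counts[j].setdefault(int(v), [0, 0])
            cell[label] += 1


def _entropy_counts(counts) -> float:
    total = sum(counts)
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


class HoeffdingTree:
    """Incremental decision tree (VFDT) over discretized attributes.

    Instances stream through the tree; each leaf accumulates per-attribute
    class counts and is split on the attribute with the best information
    gain once the gap to the runner-up exceeds the Hoeffding bound (with
    R = 1 bit for binary-class entropy), or once the bound drops below the
    tie threshold.  Leaves predict Laplace-smoothed class frequencies.

    A batch table is far shorter than the streams the algorithm was designed
    for, so fitting re-streams the training rows ``n_passes`` times; the
    bound then operates on the accumulated observation count.
    """

    def __init__(
        self,
        delta: float = 0.05,
        grace_period: int = 20,
        tie_threshold: float = 0.05,
        n_passes: int = 10,
    ):
        self.delta = delta
        self.grace_period = grace_period
        self.tie_threshold = tie_threshold
        self.n_passes = n_passes

    def fit(self, X: np.ndarray, y: np.ndarray, bin_edges: list[np.ndarray]) -> "HoeffdingTree":
        self.bin_edges = bin_edges
        self.n_features = X.shape[1]
        codes = self._codes(X)
        # node is either a _HoeffdingLeaf or (attr, {value: node}, counts)
        self.tree = _HoeffdingLeaf(self.n_features)
        for _ in range(self.n_passes):
            for row, label in zip(codes, y):
                self.tree = self._learn(self.tree, row, int(label))
        return self

    def _codes(self, X: np.ndarray) -> np.ndarray:
        out = np.empty_like(X, dtype=np.int64)
        for j in range(X.shape[1]):
            out[:, j] = np.searchsorted(self.bin_edges[j], X[:, j], side="left")
        return out

    def _learn(self, node, row: np.ndarray, label: int):
        if isinstance(node, _HoeffdingLeaf):
            node.observe(row, label)
            if node.n_since_eval >= self.grace_period:
                node.n_since_eval = 0
                split = self._try_split(node)
                if split is not None:
                    return split
            return node
        attr, children, counts = node
        counts[label] += 1
        v = int(row[attr])
        if v not in children:
            children[v] = _HoeffdingLeaf(self.n_features)
        children[v] = self._learn(children[v], row, label)
        return node

    def _try_split(self, leaf: _HoeffdingLeaf):
        n = int(leaf.class_counts.sum())
        if n < 2 or (leaf.class_counts > 0).sum() < 2:
            return None
        h_node = _entropy_counts(leaf.class_counts)
        gains = np.zeros(self.n_features)
        for j, table in enumerate(leaf.attr_counts):
            if len(table) < 2:
                continue
            h_cond = 0.0
            for cell in table.values():
                h_cond += (sum(cell) / n) * _entropy_counts(cell)
            gains[j] = h_node - h_cond
        order = np.argsort(-gains, kind="stable")
        best, second = order[0], order[1] if self.n_features > 1 else order[0]
        eps = hoeffding_bound(1.0, self.delta, n)
        gap = gains[best] - gains[second] if self.n_features > 1 else gains[best]
        if gains[best] <= 0.0:
            return None
        if gap > eps or eps < self.tie_threshold:
            children = {}
            for v, cell in leaf.attr_counts[best].items():
                child = _HoeffdingLeaf(self.n_features)
                child.class_counts = np.array(cell, dtype=float)
                children[v] = child
            return (int(best), children, leaf.class_counts.copy())
        return None

    def _node_proba(self, counts: np.ndarray) -> float:
        return (counts[1] + 1.0) / (counts.sum() + 2.0)

    def _predict_one(self, node, row: np.ndarray) -> float:
        while not isinstance(node, _HoeffdingLeaf):
            attr, children, counts = node
            v = int(row[attr])
            if v not in children:
                return self._node_proba(counts)
            node = children[v]
        return self._node_proba(node.class_counts)

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:
        codes = self._codes(X)
        return np.array([self._predict_one(self.tree, row) for row in codes])


# ---------------------------------------------------------------------------
# AdaBoost.M1


class PerfectWeakLearner(Exception):
    """Raised internally when a round's weak hypothesis makes no error."""


def adaboost_round(
    weights: np.ndarray, correct: np.ndarray, epsilon: float | None = None
) -> tuple[np.ndarray, float]:
    """One AdaBoost.M1 reweighting step.

    ``correct`` flags instances the round's weak hypothesis got right; the
    weighted error ε_t is computed from ``weights`` unless given.  Returns
    the renormalized weights and β_t = ε_t/(1−ε_t).  ε_t = 0 raises
    :class:`PerfectWeakLearner`; ε_t ≥ 0.5 raises ``ValueError`` (boosting
    must abort and keep the committee built so far).
    """
    weights = np.asarray(weights, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if epsilon is None:
        epsilon = float(weights[~correct].sum() / weights.sum())
    if epsilon == 0.0:
        raise PerfectWeakLearner
    if epsilon >= 0.5:
        raise ValueError(f"weak-learner error {epsilon:.3f} >= 0.5; abort boosting")
    beta = epsilon / (1.0 - epsilon)
    new_w = weights.copy()
    new_w[correct] *= beta
    new_w /= new_w.sum()
    return new_w, beta


class AdaBoostM1:
    """AdaBoost.M1 over depth-1 decision stumps.

    The committee votes with weight log(1/β_t); the returned probability is
    the normalized vote share for the positive class.
    """

    def __init__(self, n_rounds: int = 10, seed: int = 0):
        self.n_rounds = n_rounds
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AdaBoostM1":
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.stumps_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        for t in range(self.n_rounds):
            stump = DecisionTreeClassifier(max_depth=1, random_state=self.seed + t)
            stump.fit(X, y, sample_weight=w * n)
            pred = stump.predict(X)
            correct = pred == y
            try:
                w, beta = adaboost_round(w, correct)
            except PerfectWeakLearner:
                self.stumps_.append(stump)
                self.alphas_.append(math.log(1e12))  # effectively decisive vote
                break
            except ValueError:
                break  # ε ≥ 0.5: keep the committee built so far
            self.stumps_.append(stump)
            self.alphas_.append(math.log(1.0 / beta))
        if not self.stumps_:
            # first stump was too weak; fall back to a single majority vote
            stump = DecisionTreeClassifier(max_depth=1, random_state=self.seed)
            stump.fit(X, y)
            self.stumps_ = [stump]
            self.alphas_ = [1.0]
        return self

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros(X.shape[0])
        total = sum(self.alphas_)
        for stump, a in zip(self.stumps_, self.alphas_):
            votes += a * (stump.predict(X) == 1)
        return votes / total


# ---------------------------------------------------------------------------
# random tree / random forest


class RandomTree:
    """A single decision tree considering sqrt(m) random attributes per split."""

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomTree":
        self.tree_ = DecisionTreeClassifier(max_features="sqrt", random_state=self.seed)
        self.tree_.fit(X, y)
        return self

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:
        proba = self.tree_.predict_proba(X)
        pos = int(np.where(self.tree_.classes_ == 1)[0][0])
        return proba[:, pos]


class RandomForest:
    """Bagging of :class:`RandomTree` learners with averaged votes.

    With ``n_trees=1`` and ``bootstrap=False`` the forest is exactly the
    random tree trained with the same seed.
    """

    def __init__(self, n_trees: int = 100, seed: int = 0, bootstrap: bool = True):
        self.n_trees = n_trees
        self.seed = seed
        self.bootstrap = bootstrap

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        rng = np.random.default_rng(self.seed)
        n = len(y)
        self.trees_ = []
        for i in range(self.n_trees):
            if self.bootstrap:
                idx = rng.integers(0, n, size=n)
                Xi, yi = X[idx], y[idx]
                if len(np.unique(yi)) < 2:  # resample until both classes present
                    continue
            else:
                Xi, yi = X, y
            self.trees_.append(RandomTree(seed=self.seed + i).fit(Xi, yi))
        if not self.trees_:
            self.trees_ = [RandomTree(seed=self.seed).fit(X, y)]
        return self

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:
        return np.mean([t.predict_proba_rows(X) for t in self.trees_], axis=0)


# ---------------------------------------------------------------------------
# shallow MLP (WEKA-style single hidden layer)


class ShallowMLP:
    """One-hidden-layer perceptron; hidden size (attributes + classes) / 2."""

    def __init__(self, seed: int = 0, max_iter: int = 500):
        self.seed = seed
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShallowMLP":
        hidden = max(2, (X.shape[1] + 2) // 2)
        self.net_ = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            max_iter=self.max_iter,
            random_state=self.seed,
            solver="adam",
        )
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # the epoch budget is a fixed training parameter, not a target
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_.fit(X, y)
        return self

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:
        proba = self.net_.predict_proba(X)
        pos = int(np.where(self.net_.classes_ == 1)[0][0])
        return proba[:, pos]


# ---------------------------------------------------------------------------
# sequential network


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_sequential_weights(n_inputs: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """He-normal initialization of the fixed input→100→70→50→30→1 stack."""
    rng = np.random.default_rng(seed)
    dims = (n_inputs,) + SEQUENTIAL_LAYERS + (1,)
    weights = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        W = rng.normal(0.0, math.sqrt(2.0 / d_in), size=(d_in, d_out))
        b = np.zeros(d_out)
        weights.append((W, b))
    return weights


def _check_shapes(weights: Sequence[tuple[np.ndarray, np.ndarray]], n_inputs: int) -> None:
    dims = (n_inputs,) + SEQUENTIAL_LAYERS + (1,)
    if len(weights) != len(dims) - 1:
        raise ValueError(f"expected {len(dims) - 1} layers, got {len(weights)}")
    for k, (W, b) in enumerate(weights):
        if W.shape != (dims[k], dims[k + 1]) or b.shape != (dims[k + 1],):
            raise ValueError(
                f"layer {k}: weight shape {W.shape} does not match "
                f"({dims[k]}, {dims[k + 1]})"
            )


def sequential_forward(
    weights: Sequence[tuple[np.ndarray, np.ndarray]], row: np.ndarray
) -> float:
    """Deterministic forward pass of the five-layer network for one row.

    ReLU on the four dense layers, sigmoid on the scalar output; the result
    is clipped to lie strictly inside (0, 1).
    """
    row = np.asarray(row, dtype=float)
    _check_shapes(weights, row.shape[-1])
    a = row
    for W, b in weights[:-1]:
        a = np.maximum(a @ W + b, 0.0)
    W, b = weights[-1]
    z = float((a @ W + b).item())
    p = float(_sigmoid(np.array([z]))[0])
    return min(max(p, 1e-12), 1.0 - 1e-12)


class SequentialNet:
    """The five-layer dense network trained with Adam on binary cross-entropy.

    Reproducible: weight initialization and minibatch shuffling both derive
    from ``seed``.  ``loss_history_`` records the mean epoch loss.
    """

    def __init__(
        self,
        epochs: int = 200,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SequentialNet":
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("sequential network requires binary 0/1 labels")
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        n, d = X.shape
        self.weights_ = init_sequential_weights(d, self.seed)
        rng = np.random.default_rng(self.seed + 1)
        m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self.weights_]
        v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self.weights_]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        self.loss_history_ = []
        y = y.astype(float)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                Xb, yb = X[idx], y[idx]
                # forward with cached activations
                acts = [Xb]
                a = Xb
                for W, bb in self.weights_[:-1]:
                    a = np.maximum(a @ W + bb, 0.0)
                    acts.append(a)
                W, bb = self.weights_[-1]
                z = (a @ W + bb).ravel()
                p = np.clip(_sigmoid(z), 1e-12, 1.0 - 1e-12)
                losses.append(
                    float(-(yb * np.log(p) + (1 - yb) * np.log(1 - p)).mean())
                )
                # backward: d(BCE)/dz = p − y for a sigmoid output
                grads = []
                delta = ((p - yb) / len(yb))[:, None]
                for k in range(len(self.weights_) - 1, -1, -1):
                    a_prev = acts[k]
                    gW = a_prev.T @ delta
                    gb = delta.sum(axis=0)
                    grads.append((gW, gb))
                    if k > 0:
                        delta = (delta @ self.weights_[k][0].T) * (acts[k] > 0)
                grads.reverse()
                # Adam update
                t += 1
                new_weights = []
                for k, ((W, bb), (gW, gb)) in enumerate(zip(self.weights_, grads)):
                    mW, mb = m[k]
                    vW, vb = v[k]
                    mW = b1 * mW + (1 - b1) * gW
                    mb = b1 * mb + (1 - b1) * gb
                    vW = b2 * vW + (1 - b2) * gW**2
                    vb = b2 * vb + (1 - b2) * gb**2
                    m[k], v[k] = (mW, mb), (vW, vb)
                    mW_hat = mW / (1 - b1**t)
                    mb_hat = mb / (1 - b1**t)
                    vW_hat = vW / (1 - b2**t)
                    vb_hat = vb / (1 - b2**t)
                    W = W - self.learning_rate * mW_hat / (np.sqrt(vW_hat) + eps)
                    bb = bb - self.learning_rate * mb_hat / (np.sqrt(vb_hat) + eps)
                    new_weights.append((W, bb))
                self.weights_ = new_weights
            self.loss_history_.append(float(np.mean(losses)))
        return self

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        _check_shapes(self.weights_, a.shape[1])
        for W, b in self.weights_[:-1]:
            a = np.maximum(a @ W + b, 0.0)
        W, b = self.weights_[-1]
        p = _sigmoid((a @ W + b).ravel())
        return np.clip(p, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# factory


def _make_learner(spec: ClassifierSpec):
    hp = spec.hyperparams
    if spec.name == "naive_bayes":
        return NaiveBayes()
    if spec.name == "random_tree":
        return RandomTree(seed=spec.seed)
    if spec.name == "random_forest":
        return RandomForest(
            n_trees=hp.get("n_trees", 100),
            seed=spec.seed,
            bootstrap=hp.get("bootstrap", True),
        )
    if spec.name == "adaboost_m1":
        return AdaBoostM1(n_rounds=hp.get("n_rounds", 10), seed=spec.seed)
    if spec.name == "hoeffding_tree":
        return HoeffdingTree(
            delta=hp.get("delta", 0.05),
            grace_period=hp.get("grace_period", 20),
            tie_threshold=hp.get("tie_threshold", 0.05),
            n_passes=hp.get("n_passes", 10),
        )
    if spec.name == "mlp":
        return ShallowMLP(seed=spec.seed, max_iter=hp.get("max_iter", 500))
    if spec.name == "sequential_nn":
        return SequentialNet(
            epochs=hp.get("epochs", 200),
            batch_size=hp.get("batch_size", 16),
            learning_rate=hp.get("learning_rate", 1e-3),
            seed=spec.seed,
        )
    raise ValueError(spec.name)


_NEEDS_SCALING = {"mlp", "sequential_nn"}


def fit_model(spec: ClassifierSpec, table: FeatureTable) -> TrainedModel:
    """Fit one learner of the bank on a feature table.

    Gradient-trained learners (``mlp``, ``sequential_nn``) get numeric
    columns z-scored with statistics of this table; the statistics are
    stored on the model and reapplied at prediction time.
    """
    X = table.matrix
    y = table.y()
    scaler = _fit_scaler(X) if spec.name in _NEEDS_SCALING else None
    if scaler is not None:
        mask, mean, std = scaler
        X = X.copy()
        X[:, mask] = (X[:, mask] - mean) / std
    learner = _make_learner(spec)
    if isinstance(learner, HoeffdingTree):
        edges = [
            np.unique(np.quantile(table.matrix[:, j], np.linspace(0, 1, 11)[1:-1]))
            if not table.is_binary_column(j)
            else np.array([0.5])
            for j in range(table.n_features)
        ]
        learner.fit(X, y, bin_edges=edges)
    else:
        learner.fit(X, y)
    return TrainedModel(
        spec=spec, learner=learner, feature_names=list(table.feature_names), scaler=scaler
    )
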