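"""Feed-forward classifier family and the re-weighted cross-entropy loss.

Three members of one architecture template are used downstream:

* LSM — linear single-horizon model: fully-connected layers with no
  activation between them (the pre-soft-max map is affine), one model per
  follow-up year;
* NSM — nonlinear single-horizon model: same layout with ReLUs;
* NMM — nonlinear multi-horizon model: same layout with one extra input,
  the time-to-follow-up in months, so a single network covers every
  horizon.

The default layout is 3 hidden layers of width 128, then 5 of width 64,
then 2 of width 32, followed by a soft-max output of width 3 (the CN, MCI
and AD probabilities) — 11 layers in total.  Training minimizes a
sample-weighted categorical cross-entropy in which the four
baseline-by-outcome categories (CN stable / CN converter / MCI stable /
MCI converter) are balanced within each follow-up year, and the years are
balanced against each other.

Implemented on NumPy: forward/backward passes, inverted dropout and an
Adam optimizer are defined here so training is fully deterministic given
the initialization and shuffling seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "MLP",
    "AdamOptimizer",
    "WeightPlan",
    "build_model",
    "compute_sample_weights",
    "weighted_cross_entropy",
    "softmax",
]

LOG_EPS = 1e-12  #: clamp inside log() so a zero predicted probability is finite

DEFAULT_HIDDEN_LAYOUT = ((128, 3), (64, 5), (32, 2))
N_CLASSES = 3


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description.

    ``hidden_layout`` is a sequence of (width, repeat) blocks; the default
    expands to 10 hidden layers plus the soft-max output layer.
    """

    input_width: int = 113
    hidden_layout: tuple[tuple[int, int], ...] = DEFAULT_HIDDEN_LAYOUT
    nonlinear: bool = True
    multi_year: bool = False
    dropout_rate: float = 0.2
    l2_weight: float = 1e-6

    def __post_init__(self):
        if not self.hidden_layout:
            raise SpecError("hidden_layout must contain at least one block")
        expected = 114 if self.multi_year else 113
        # Custom widths are allowed for reduced-scale work; only the
        # multi-year +1 consistency is enforced when using template widths.
        if self.input_width in (113, 114) and self.input_width != expected:
            raise SpecError(
                f"multi_year={self.multi_year} requires input width {expected}")

    @classmethod
    def three_layer(cls, multi_year: bool = False, width: int = 128,
                    input_width: int | None = None,
                    nonlinear: bool = True,
                    l2_weight: float = 1e-6) -> "ModelSpec":
        """Compact variant: 2 hidden layers plus the output layer."""
        return cls(
            input_width=input_width or (114 if multi_year else 113),
            hidden_layout=((width, 2),), nonlinear=nonlinear,
            multi_year=multi_year, l2_weight=l2_weight)

    @classmethod
    def desk(cls, kind: str, input_width: int | None = None) -> "ModelSpec":
        """Desk-scale spec for reduced-protocol runs.

        The compact 3-layer variant at width 64 with a stronger L2 weight:
        with full-batch training and per-year loss normalization, the
        effective regularization of the reference coefficient would be far
        weaker than intended at cohort sizes of a few thousand rows.
        """
        return cls.three_layer(
            multi_year=(kind == "nmm"), width=64,
            input_width=input_width, nonlinear=(kind != "lsm"),
            l2_weight=2e-5)

    @property
    def hidden_widths(self) -> list[int]:
        out: list[int] = []
        for width, repeat in self.hidden_layout:
            out += [int(width)] * int(repeat)
        return out

    @property
    def n_layers(self) -> int:
        """Hidden layers plus the output layer (11 for the default)."""
        return len(self.hidden_widths) + 1

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        widths = [self.input_width] + self.hidden_widths + [N_CLASSES]
        return list(zip(widths[:-1], widths[1:]))

    @property
    def n_params(self) -> int:
        return sum(fi * fo + fo for fi, fo in self.layer_dims)

    def to_json(self) -> str:
        return json.dumps({
            "input_width": self.input_width,
            "hidden_layout": [list(b) for b in self.hidden_layout],
            "nonlinear": self.nonlinear,
            "multi_year": self.multi_year,
            "dropout_rate": self.dropout_rate,
            "l2_weight": self.l2_weight,
        })

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        doc = json.loads(text)
        doc["hidden_layout"] = tuple(tuple(b) for b in doc["hidden_layout"])
        return cls(**doc)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLP:
    """Fully-connected network with optional ReLUs and inverted dropout.

    Parameters are initialized deterministically from ``init_seed``
    (He-style scaling when nonlinear, Glorot-style otherwise).  Dropout is
    active only in training-mode passes; inference is deterministic.
    """

    def __init__(self, spec: ModelSpec, init_seed: int = 0,
                 dtype: np.dtype = np.float64):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(np.random.SeedSequence([int(init_seed), 811]))
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in spec.layer_dims:
            if spec.nonlinear:
                scale = np.sqrt(2.0 / fan_in)
            else:
                scale = np.sqrt(1.0 / fan_in)
            self.W.append((rng.standard_normal((fan_in, fan_out)) * scale)
                          .astype(self.dtype))
            self.b.append(np.zeros(fan_out, dtype=self.dtype))

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.W, self.b))

    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[...] = s

    def save(self, path) -> None:
        """Checkpoint parameters plus the spec (numpy .npz container)."""
        arrays = {f"W{l}": w for l, w in enumerate(self.W)}
        arrays.update({f"b{l}": b for l, b in enumerate(self.b)})
        arrays["spec_json"] = np.array(self.spec.to_json())
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MLP":
        with np.load(path, allow_pickle=False) as data:
            spec = ModelSpec.from_json(str(data["spec_json"]))
            model = cls(spec, init_seed=0)
            model.W = [data[f"W{l}"] for l in range(len(model.W))]
            model.b = [data[f"b{l}"] for l in range(len(model.b))]
            model.dtype = model.W[0].dtype
        return model

    # ------------------------------------------------------------------
    def logits(self, X: np.ndarray) -> np.ndarray:
        """Pre-soft-max activations (inference mode, no dropout)."""
        h = np.asarray(X, dtype=self.dtype)
        last = len(self.W) - 1
        for l, (w, bias) in enumerate(zip(self.W, self.b)):
            h = h @ w + bias
            if self.spec.nonlinear and l < last:
                h = np.maximum(h, 0.0)
        return h

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.logits(X))

    # ------------------------------------------------------------------
    def loss_and_grads(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        w: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[float, list[np.ndarray]]:
        """Weighted cross-entropy + L2, with gradients by backprop.

        When ``dropout_rng`` is given, inverted dropout at the spec's rate
        is applied after every hidden activation (training mode).
        """
        n = X.shape[0]
        rate = self.spec.dropout_rate if dropout_rng is not None else 0.0
        last = len(self.W) - 1

        h = X
        caches: list[tuple[np.ndarray, np.ndarray, np.ndarray | None]] = []
        for l, (wm, bias) in enumerate(zip(self.W, self.b)):
            inp = h
            z = inp @ wm + bias
            drop_mask = None
            if l < last:
                if self.spec.nonlinear:
                    h = np.maximum(z, 0.0)
                else:
                    h = z
                if rate > 0.0:
                    drop_mask = (dropout_rng.uniform(size=h.shape) >= rate)
                    h = h * drop_mask / (1.0 - rate)
            else:
                h = z
            caches.append((inp, z, drop_mask))

        probs = softmax(h)
        data_loss = weighted_cross_entropy(Y, probs, w)
        l2 = self.spec.l2_weight
        reg_loss = l2 * sum(float(np.sum(p * p)) for p in self.parameters())

        grads_W = [np.zeros_like(wm) for wm in self.W]
        grads_b = [np.zeros_like(bias) for bias in self.b]
        delta = (probs - Y) * (w[:, None] / n)
        for l in range(last, -1, -1):
            inp, z, drop_mask = caches[l]
            grads_W[l] = inp.T @ delta + 2.0 * l2 * self.W[l]
            grads_b[l] = delta.sum(axis=0) + 2.0 * l2 * self.b[l]
            if l > 0:
                delta = delta @ self.W[l].T
                prev_mask = caches[l - 1][2]
                if prev_mask is not None:
                    delta = delta * prev_mask / (1.0 - rate)
                if self.spec.nonlinear:
                    delta = delta * (caches[l - 1][1] > 0.0)
        return data_loss + reg_loss, grads_W + grads_b


class AdamOptimizer:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_model(spec: ModelSpec, init_seed: int = 0) -> MLP:
    """Construct a network from a spec; deterministic in ``init_seed``."""
    return MLP(spec, init_seed)


# ---------------------------------------------------------------------------
# Sample weighting
# ---------------------------------------------------------------------------

@dataclass
class WeightPlan:
    """Per-(year, category) sample weights.

    Step 1 sets the weight of each category within a year to one over its
    size; step 2 rescales so every year's total weight is the same
    (normalized here to 1 per year, the constant being absorbed by the
    learning rate).  The result: within a year each present category
    carries equal total weight, and across years each year carries equal
    total weight.
    """

    weights: dict[tuple[int, str], float]
    sizes: dict[tuple[int, str], int]
    missing_categories: list[tuple[int, str]] = field(default_factory=list)

    def weight_for(self, year: int, category: str) -> float:
        key = (int(year), str(category))
        if key in self.weights:
            return self.weights[key]
        # category unseen in the fitting rows for this year: fall back to
        # the year's mean per-sample weight so held-out rows stay usable
        year_w = [w for (y, _), w in self.weights.items() if y == int(year)]
        if not year_w:
            return 1.0
        return float(np.mean(year_w))

    def apply(self, labels: pd.DataFrame) -> np.ndarray:
        return np.array([
            self.weight_for(y, c)
            for y, c in zip(labels["year"], labels["category"])
        ])


def compute_sample_weights(labels: pd.DataFrame) -> WeightPlan:
    """Two-step category/year re-weighting from a label table.

    ``labels`` needs columns ``year`` and ``category``.  Categories absent
    from a year contribute no weight (logged on the plan); each present
    category's per-sample weight is 1 / (group size x number of present
    categories in that year), so per-category totals within a year are
    equal and every year totals exactly 1.
    """
    from .cohort_builder import CATEGORIES

    sizes: dict[tuple[int, str], int] = {}
    for (year, cat), grp in labels.groupby(["year", "category"]):
        sizes[(int(year), str(cat))] = len(grp)

    years = sorted({y for y, _ in sizes})
    weights: dict[tuple[int, str], float] = {}
    missing: list[tuple[int, str]] = []
    for year in years:
        present = [c for c in CATEGORIES if (year, c) in sizes]
        for cat in CATEGORIES:
            if (year, cat) not in sizes:
                missing.append((year, cat))
        for cat in present:
            weights[(year, cat)] = 1.0 / (sizes[(year, cat)] * len(present))
    return WeightPlan(weights=weights, sizes=sizes, missing_categories=missing)


def weighted_cross_entropy(Y: np.ndarray, P: np.ndarray, w: np.ndarray) -> float:
    """-(1/N) sum_i w_i <y_i, log p_i>, with log clamped at ``LOG_EPS``.

    With all weights 1 this is the plain categorical cross-entropy.
    """
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    w = np.asarray(w, dtype=float)
    n = Y.shape[0]
    logp = np.log(np.clip(P, LOG_EPS, None))
    return float(-(w * np.sum(Y * logp, axis=1)).sum() / n)
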