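"""Fusing per-scale entropies into a single 0-100 DOA index with an ANN.

A small feed-forward network (N scale-entropy inputs -> 20 tanh hidden
units -> 1 linear output) is trained by backpropagation against a gold
standard, with samples split randomly 70/15/15 into training, validation
(early stopping) and test sets.  The trained weights, biases and input
standardisation are stored in a portable :class:`ANNModel` whose forward
pass is a plain matrix expression, so models serialise to JSON and predict
without the training backend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor

from .entropy import MSEMatrix
from .records import EvalReport, GoldStandard


@dataclass
class AlignedSamples:
    """Feature rows paired with gold-standard targets on a common grid."""

    features: np.ndarray      # (n, n_scales)
    target: np.ndarray        # (n,)
    times_s: np.ndarray       # (n,) gold sample times
    scales: tuple
    n_dropped: int = 0


def align_features_to_target(mse: MSEMatrix, gold: GoldStandard,
                             max_offset_s: float = 2.5) -> AlignedSamples:
    """Pair each gold sample with the window whose end time is nearest.

    Windows step every 5 s and the gold standard ticks at 0.2 Hz, so the
    two grids share a period but may be offset; samples with no window end
    within ``max_offset_s`` are dropped and counted.
    """
    ends = mse.window_end_s()
    gt = gold.times()
    if gt.max() < ends.min() - max_offset_s or gt.min() > ends.max() + max_offset_s:
        raise ValueError("gold standard and MSE matrix do not overlap in time")
    idx = np.searchsorted(ends, gt)
    rows, targets, times = [], [], []
    dropped = 0
    for k, t in enumerate(gt):
        cands = [c for c in (idx[k] - 1, idx[k]) if 0 <= c < ends.size]
        best = min(cands, key=lambda c: abs(ends[c] - t))
        if abs(ends[best] - t) <= max_offset_s:
            rows.append(mse.values[best])
            targets.append(gold.values[k])
            times.append(t)
        else:
            dropped += 1
    if not rows:
        raise ValueError("no gold samples could be matched to a window")
    return AlignedSamples(np.array(rows), np.array(targets), np.array(times),
                          mse.scales, dropped)


@dataclass
class ANNModel:
    """Trained feed-forward index model: weights, biases and normalisation."""

    weights: list              # [W_hidden (n_in, hidden), W_out (hidden, 1)]
    biases: list               # [b_hidden (hidden,), b_out (1,)]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    scales: tuple
    hidden: int
    seed: int
    activation: str = "tanh"
    split: tuple = (0.70, 0.15, 0.15)
    test_index: np.ndarray | None = None
    loss_curve: list = field(default_factory=list)

    @property
    def n_in(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Raw network output (no clipping); NaN rows propagate to NaN."""
        x = (np.atleast_2d(features) - self.x_mean) / self.x_sd
        h = np.tanh(x @ self.weights[0] + self.biases[0])
        z = (h @ self.weights[1] + self.biases[1]).ravel()
        return self.y_mean + self.y_sd * z

    def to_json(self) -> str:
        d = {
            "architecture": [self.n_in, self.hidden, 1],
            "activation": self.activation,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "scales": list(self.scales),
            "seed": self.seed,
            "split": list(self.split),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ANNModel":
        d = json.loads(text)
        return cls(
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            x_mean=np.asarray(d["x_mean"]), x_sd=np.asarray(d["x_sd"]),
            y_mean=d["y_mean"], y_sd=d["y_sd"],
            scales=tuple(d["scales"]), hidden=d["architecture"][1],
            seed=d["seed"], activation=d["activation"],
            split=tuple(d["split"]))


def split_indices(n: int, split=(0.70, 0.15, 0.15), seed: int = 0):
    """Random disjoint train/validation/test index sets covering 0..n-1."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(split[2] * n))
    n_val = int(round(split[1] * n))
    test = perm[:n_test]
    val = perm[n_test:n_test + n_val]
    train = perm[n_test + n_val:]
    return train, val, test


def train_ann(samples: AlignedSamples, hidden: int = 20,
              split=(0.70, 0.15, 0.15), seed: int = 0,
              max_iter: int = 1000, patience: int = 20) -> ANNModel:
    """Train the index network against the gold standard.

    Rows with undefined (NaN) entropies are dropped before splitting.
    Training minimises squared error with early stopping on validation
    loss; inputs are standardised with training-split statistics.  The
    same seed always reproduces the same weights.
    """
    ok = np.all(np.isfinite(samples.features), axis=1) & np.isfinite(samples.target)
    X, y = samples.features[ok], samples.target[ok]
    n = X.shape[0]
    if n < 30:
        raise ValueError(f"need at least 30 complete paired samples, have {n}")
    if np.ptp(y) == 0:
        raise ValueError("gold-standard target is constant; nothing to regress")
    train, val, test = split_indices(n, split, seed)
    fit_idx = np.concatenate([train, val])
    x_mean = X[train].mean(axis=0)
    x_sd = X[train].std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Xs = (X - x_mean) / x_sd
    # standardise the 0-100 target as well: tanh hidden layers train far
    # better when the output layer works near unit scale
    y_mean = float(y[train].mean())
    y_sd = float(y[train].std()) or 1.0
    ys = (y - y_mean) / y_sd
    # the validation share handed to the backend reproduces the requested
    # overall 70/15/15 proportions
    val_fraction = len(val) / max(len(fit_idx), 1)
    reg = MLPRegressor(hidden_layer_sizes=(hidden,), activation="tanh",
                       solver="adam", learning_rate_init=0.01,
                       max_iter=max_iter,
                       early_stopping=val_fraction > 0,
                       validation_fraction=max(val_fraction, 1e-6),
                       n_iter_no_change=patience, random_state=seed,
                       tol=1e-6)
    reg.fit(Xs[fit_idx], ys[fit_idx])
    return ANNModel(
        weights=[np.asarray(w) for w in reg.coefs_],
        biases=[np.asarray(b) for b in reg.intercepts_],
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        scales=samples.scales, hidden=hidden,
        seed=seed, split=tuple(split), test_index=test,
        loss_curve=list(map(float, reg.loss_curve_)))


def predict_index(model: ANNModel, mse: MSEMatrix):
    """DOA index per window, clipped to [0, 100].

    Returns ``(times_s, index)`` where times are window end times; windows
    with undefined entropies yield NaN rather than being dropped.
    """
    if mse.values.shape[1] != model.n_in:
        raise ValueError(
            f"feature matrix has {mse.values.shape[1]} scales but the model "
            f"expects {model.n_in}")
    raw = model.forward(mse.values)
    return mse.window_end_s(), np.clip(raw, 0.0, 100.0)


def evaluate(pred: np.ndarray, gold: np.ndarray | GoldStandard) -> EvalReport:
    """Pearson correlation and coefficient of determination of pred vs gold."""
    g = gold.values if isinstance(gold, GoldStandard) else np.asarray(gold, float)
    p = np.asarray(pred, dtype=float)
    if p.shape != g.shape:
        raise ValueError("prediction and gold series must have equal length")
    ok = np.isfinite(p) & np.isfinite(g)
    p, g = p[ok], g[ok]
    if p.size < 3:
        raise ValueError("need at least 3 finite paired values")
    if p.std() == 0 or g.std() == 0:
        return EvalReport(corr=np.nan, r_squared=np.nan, n=p.size)
    corr = float(np.corrcoef(p, g)[0, 1])
    return EvalReport(corr=corr, r_squared=corr ** 2, n=p.size)


def combine_pre_post(mse_pre: MSEMatrix, mse_post: MSEMatrix,
                     post_scales=()) -> MSEMatrix:
    """Feature matrix taking columns in ``post_scales`` from the filtered
    analysis and the remaining columns from the unfiltered one.

    This is the pre/post-filter optimisation: the filter helps the scales
    it was designed for (scale 1 and nearby) and hurts the large scales,
    so each scale is sourced from whichever analysis tracks the gold
    standard better.
    """
    if mse_pre.scales != mse_post.scales or \
            mse_pre.values.shape != mse_post.values.shape or \
            not np.allclose(mse_pre.window_start_s, mse_post.window_start_s):
        raise ValueError("pre- and post-filter matrices must share the window grid")
    post = set(int(s) for s in post_scales)
    unknown = post - set(mse_pre.scales)
    if unknown:
        raise ValueError(f"post_scales {sorted(unknown)} not in the scale grid")
    values = mse_pre.values.copy()
    for col, s in enumerate(mse_pre.scales):
        if s in post:
            values[:, col] = mse_post.values[:, col]
    return MSEMatrix(values, mse_pre.window_start_s.copy(), mse_pre.scales,
                     mse_pre.params, mse_pre.window_s, mse_pre.step_s,
                     filtered=bool(post))


def select_post_scales(per_scale_corr_pre: np.ndarray,
                       per_scale_corr_post: np.ndarray,
                       scales=None) -> set:
    """Scales where the post-filter correlation strictly beats pre-filter."""
    pre = np.asarray(per_scale_corr_pre, dtype=float)
    post = np.asarray(per_scale_corr_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("correlation vectors must have equal length")
    scales = tuple(range(1, pre.size + 1)) if scales is None else tuple(scales)
    return {s for s, a, b in zip(scales, pre, post) if b > a}


def summarize_cases(per_case_corr) -> EvalReport:
    """Multi-recording summary: mean correlation and its CV across cases.

    Mirrors how a cohort evaluation is reported — one correlation per
    recording, summarised as mean +- SD with CV = 100*SD/mean (sample SD).
    """
    corrs = np.asarray(list(per_case_corr), dtype=float)
    corrs = corrs[np.isfinite(corrs)]
    if corrs.size < 2:
        raise ValueError("need at least 2 finite per-case correlations")
    mean = float(corrs.mean())
    cv_pct = float(100.0 * corrs.std(ddof=1) / mean) if mean != 0 else np.nan
    return EvalReport(corr=mean, r_squared=mean ** 2, n=corrs.size,
                      cv_pct=cv_pct, per_case_corr=[float(c) for c in corrs])


def per_scale_correlations(samples: AlignedSamples) -> np.ndarray:
    """Pearson correlation of each single-scale entropy with the target."""
    out = np.full(samples.features.shape[1], np.nan)
    for c in range(samples.features.shape[1]):
        x = samples.features[:, c]
        ok = np.isfinite(x) & np.isfinite(samples.target)
        if ok.sum() >= 3 and x[ok].std() > 0 and samples.target[ok].std() > 0:
            out[c] = np.corrcoef(x[ok], samples.target[ok])[0, 1]
    return out
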