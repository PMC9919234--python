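"""Neural-network fusion of radar and depth tracks.

Two fusers share a single-hidden-layer architecture (tanh hidden units,
linear outputs) mapping the four sensor coordinates (x_r, y_r, x_d, y_d) to
one fused coordinate pair (x_f, y_f):

* **MLP** — a feedforward network that fuses each time-aligned sample
  independently of the movement history.
* **NARX** — a nonlinear autoregressive network with exogenous inputs: its
  own outputs, delayed by the configured lags (default 1 and 2 samples),
  are fed back as additional inputs, so each fused position depends on the
  previous fused positions.  Training is open-loop (teacher forcing: the
  reference coordinates are placed at the feedback taps); application is
  closed-loop.

Both networks are trained on synthetic walks only.  All channels are
affinely scaled to [-1, 1] over the training region; weights are fitted by
full-batch L-BFGS with an 80/20 by-realisation validation split, keeping
the iterate with the lowest validation error (early stopping).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .tracks import FusedTrack, SensorTrack, Trajectory

__all__ = [
    "NetworkSpec",
    "TrainedNetwork",
    "TrainingConfig",
    "PairedSamples",
    "AffineScaler",
    "pair_sensor_streams",
    "train_network",
    "apply_network",
    "save_network",
    "load_network",
]


@dataclass
class NetworkSpec:
    """Architecture of a fuser network."""

    kind: str  # "mlp" or "narx"
    n_hidden: int = 6
    n_inputs: int = 4
    n_outputs: int = 2
    feedback_delays: tuple = ()
    hidden_activation: str = "tanh"
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in ("mlp", "narx"):
            raise ValueError("kind must be 'mlp' or 'narx'")
        if self.kind == "narx" and not self.feedback_delays:
            self.feedback_delays = (1, 2)
        self.feedback_delays = tuple(int(d) for d in self.feedback_delays)
        if self.kind == "mlp" and self.feedback_delays:
            raise ValueError("an MLP has no feedback delays")
        if self.kind == "narx" and any(d < 1 for d in self.feedback_delays):
            raise ValueError("feedback delays must be positive lags")
        if self.hidden_activation != "tanh" or self.output_activation != "linear":
            raise ValueError("only tanh hidden / linear output units are supported")

    @property
    def total_inputs(self) -> int:
        return self.n_inputs + self.n_outputs * len(self.feedback_delays)


@dataclass
class AffineScaler:
    """Per-channel affine map onto [-1, 1] over the training region."""

    center: np.ndarray
    half_range: np.ndarray

    @classmethod
    def fit(cls, v: np.ndarray) -> "AffineScaler":
        lo, hi = v.min(axis=0), v.max(axis=0)
        half = (hi - lo) / 2.0
        half[half == 0] = 1.0  # constant channel: identity shift
        return cls(center=(hi + lo) / 2.0, half_range=half)

    def scale(self, v: np.ndarray) -> np.ndarray:
        return (v - self.center) / self.half_range

    def unscale(self, v: np.ndarray) -> np.ndarray:
        return v * self.half_range + self.center


@dataclass
class PairedSamples:
    """Time-aligned sensor samples on the radar clock.

    ``imputed`` marks samples whose depth channel was filled by hold or by
    the radar value because no depth observation was close enough in time.
    """

    t: np.ndarray
    radar_xy: np.ndarray
    depth_xy: np.ndarray
    imputed: np.ndarray
    target_xy: np.ndarray | None = None

    def __len__(self) -> int:
        return self.t.size

    @property
    def features(self) -> np.ndarray:
        return np.hstack([self.radar_xy, self.depth_xy])


def pair_sensor_streams(
    radar: SensorTrack, depth: SensorTrack, max_gap: float = 0.15
) -> PairedSamples:
    """Align the depth stream with the radar clock.

    For each radar timestamp the nearest depth sample within ``max_gap``
    seconds is used; failing that the last observed depth value is held
    (imputed), and before any depth sample exists the radar value stands in.
    """
    if len(radar) == 0:
        raise ValueError("radar track must be non-empty")
    n = len(radar)
    depth_xy = np.empty((n, 2))
    imputed = np.zeros(n, dtype=bool)
    if len(depth) == 0:
        depth_xy[:] = radar.xy
        imputed[:] = True
        return PairedSamples(radar.t.copy(), radar.xy.copy(), depth_xy, imputed)

    idx = np.searchsorted(depth.t, radar.t)
    for i, tr in enumerate(radar.t):
        j = idx[i]
        cand = [k for k in (j - 1, j) if 0 <= k < len(depth)]
        k = min(cand, key=lambda k: abs(depth.t[k] - tr))
        if abs(depth.t[k] - tr) <= max_gap:
            depth_xy[i] = depth.xy[k]
        elif depth.t[0] <= tr:
            last = np.searchsorted(depth.t, tr, side="right") - 1
            depth_xy[i] = depth.xy[last]
            imputed[i] = True
        else:
            depth_xy[i] = radar.xy[i]
            imputed[i] = True
    return PairedSamples(radar.t.copy(), radar.xy.copy(), depth_xy, imputed)


@dataclass
class TrainingConfig:
    """Hyperparameters of the L-BFGS trainer.

    ``tap_noise_std`` (metres) is zero-mean Gaussian noise added to the
    teacher-forced NARX feedback taps during training; without it the
    network learns to copy its (perfect) delayed targets and becomes
    unstable when run closed-loop on its own imperfect outputs.
    """

    max_iter: int = 400
    l2: float = 1e-6
    val_fraction: float = 0.2
    max_gap: float = 0.15
    tap_noise_std: float = 0.05
    refine_rounds: int = 8  # NARX scheduled-sampling rounds (0 disables)
    refine_max_iter: int = 200


@dataclass
class TrainedNetwork:
    spec: NetworkSpec
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    input_scaler: AffineScaler
    output_scaler: AffineScaler
    training_seed: int = 0
    training_loss: float = float("nan")  # MSE on the training set, m^2
    validation_loss: float = float("nan")

    def forward(self, x_scaled: np.ndarray) -> np.ndarray:
        return np.tanh(x_scaled @ self.w1 + self.b1) @ self.w2 + self.b2


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta: np.ndarray, d: int, h: int, o: int):
    i = 0
    w1 = theta[i : i + d * h].reshape(d, h); i += d * h
    b1 = theta[i : i + h]; i += h
    w2 = theta[i : i + h * o].reshape(h, o); i += h * o
    b2 = theta[i : i + o]
    return w1, b1, w2, b2


def _loss_grad(theta, x, y, d, h, o, l2):
    w1, b1, w2, b2 = _unpack(theta, d, h, o)
    a = np.tanh(x @ w1 + b1)
    pred = a @ w2 + b2
    resid = pred - y
    n = x.shape[0]
    loss = 0.5 * np.mean(resid**2) + 0.5 * l2 * (np.sum(w1**2) + np.sum(w2**2))
    dpred = resid / (n * o)
    gw2 = a.T @ dpred + l2 * w2
    gb2 = dpred.sum(axis=0)
    da = dpred @ w2.T * (1.0 - a**2)
    gw1 = x.T @ da + l2 * w1
    gb1 = da.sum(axis=0)
    return loss, _pack(gw1, gb1, gw2, gb2)


def _as_triple(item):
    if hasattr(item, "radar"):
        return item.radar, item.depth, item.trajectory
    radar, depth, traj = item
    return radar, depth, traj


def _design_matrices(spec: NetworkSpec, exo: np.ndarray, y: np.ndarray,
                     tap_noise: np.ndarray | None = None):
    """Open-loop (teacher-forced) design rows for one realisation.

    ``tap_noise`` (same shape as ``y``, scaled units) perturbs the
    teacher-forced feedback taps so the closed-loop network tolerates its
    own prediction errors.
    """
    if spec.kind == "mlp":
        return exo, y
    y_tap = y if tap_noise is None else y + tap_noise
    lag = max(spec.feedback_delays)
    taps = [y_tap[lag - d : len(y) - d] for d in spec.feedback_delays]
    return np.hstack([exo[lag:]] + taps), y[lag:]


def train_network(
    spec: NetworkSpec,
    dataset,
    hyperparams: TrainingConfig | None = None,
    seed: int = 0,
) -> TrainedNetwork:
    """Fit a fuser network on paired synthetic walks.

    ``dataset`` is a sequence of (radar, depth, trajectory) triples or
    :class:`~gaitfuse.synthetic.WalkRealisation` objects.  Minimises the MSE
    between the network output and the reference coordinates.  The NARX is
    first trained open-loop (teacher forcing with noise-perturbed reference
    values at the feedback taps), then refined by a few scheduled-sampling
    rounds in which the taps are replaced by the network's own closed-loop
    outputs; the round with the lowest closed-loop validation error wins.
    All fusers are evaluated closed-loop by :func:`apply_network`.
    """
    hp = hyperparams or TrainingConfig()
    if not len(dataset):
        raise ValueError("training dataset is empty")

    paired, targets = [], []
    for item in dataset:
        radar, depth, traj = _as_triple(item)
        ps = pair_sensor_streams(radar, depth, max_gap=hp.max_gap)
        paired.append(ps)
        targets.append(traj.position_at(ps.t))

    in_scaler = AffineScaler.fit(np.vstack([ps.features for ps in paired]))
    out_scaler = AffineScaler.fit(np.vstack(targets))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(paired))
    n_val = int(round(hp.val_fraction * len(paired)))
    val_ids, train_ids = order[:n_val], order[n_val:]
    if train_ids.size == 0:
        train_ids, val_ids = order, order[:0]

    def stack(ids, tap_source=None, noisy_taps=False):
        """Design rows for the given walks; ``tap_source`` optionally maps a
        walk index to the (unscaled) sequence placed at the feedback taps."""
        xs, ys = [], []
        for i in ids:
            y = out_scaler.scale(targets[i])
            y_tap_noise = None
            if noisy_taps and spec.kind == "narx" and hp.tap_noise_std > 0:
                y_tap_noise = rng.normal(
                    0.0, hp.tap_noise_std / out_scaler.half_range, size=y.shape
                )
            exo = in_scaler.scale(paired[i].features)
            if tap_source is None:
                x_i, y_i = _design_matrices(spec, exo, y, y_tap_noise)
            else:
                tap = out_scaler.scale(tap_source[i])
                lag = max(spec.feedback_delays)
                cols = [tap[lag - d : len(tap) - d] for d in spec.feedback_delays]
                x_i, y_i = np.hstack([exo[lag:]] + cols), y[lag:]
            xs.append(x_i)
            ys.append(y_i)
        return np.vstack(xs), np.vstack(ys)

    d, h, o = spec.total_inputs, spec.n_hidden, spec.n_outputs
    lim1 = np.sqrt(6.0 / (d + h))
    lim2 = np.sqrt(6.0 / (h + o))
    theta = _pack(
        rng.uniform(-lim1, lim1, size=(d, h)),
        np.zeros(h),
        rng.uniform(-lim2, lim2, size=(h, o)),
        np.zeros(o),
    )

    def fit(theta0, x_tr, y_tr, x_val, y_val, max_iter):
        """L-BFGS with iterate selection on open-loop validation error."""
        best = {"theta": theta0.copy(), "val": np.inf}

        def track_best(th):
            if x_val is None:
                return
            w1, b1, w2, b2 = _unpack(th, d, h, o)
            pred = np.tanh(x_val @ w1 + b1) @ w2 + b2
            val = float(np.mean((pred - y_val) ** 2))
            if val < best["val"]:
                best["val"] = val
                best["theta"] = th.copy()

        track_best(theta0)
        res = minimize(
            _loss_grad,
            theta0,
            args=(x_tr, y_tr, d, h, o, hp.l2),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter},
            callback=track_best,
        )
        if not np.all(np.isfinite(res.x)):
            raise RuntimeError("training diverged: non-finite weights")
        return best["theta"] if x_val is not None else res.x

    x_tr, y_tr = stack(train_ids, noisy_taps=True)
    x_val, y_val = (
        stack(val_ids, noisy_taps=True) if val_ids.size else (None, None)
    )
    theta = fit(theta, x_tr, y_tr, x_val, y_val, hp.max_iter)

    def make_net(th):
        w1, b1, w2, b2 = _unpack(th, d, h, o)
        return TrainedNetwork(
            spec=spec, w1=w1, b1=b1, w2=w2, b2=b2,
            input_scaler=in_scaler, output_scaler=out_scaler, training_seed=seed,
        )

    def closed_loop_mse(net, ids):
        """Mean squared closed-loop error (m^2) over the given walks."""
        if not len(ids):
            return float("nan")
        errs = [
            np.mean((apply_network(net, paired[i]).xy - targets[i]) ** 2)
            for i in ids
        ]
        return float(np.mean(errs))

    net = make_net(theta)
    if spec.kind == "narx" and hp.refine_rounds > 0:
        best_theta, best_val = theta, closed_loop_mse(net, val_ids)
        for _ in range(hp.refine_rounds):
            preds = {
                int(i): apply_network(net, paired[i]).xy
                for i in np.concatenate([train_ids, val_ids])
            }
            x_tr, y_tr = stack(train_ids, tap_source=preds)
            x_val, y_val = (
                stack(val_ids, tap_source=preds) if val_ids.size else (None, None)
            )
            theta = fit(theta, x_tr, y_tr, x_val, y_val, hp.refine_max_iter)
            net = make_net(theta)
            val = closed_loop_mse(net, val_ids)
            if val_ids.size and val < best_val:
                best_val, best_theta = val, theta
        if val_ids.size:
            net = make_net(best_theta)

    if spec.kind == "narx":
        net.training_loss = closed_loop_mse(net, train_ids)
        net.validation_loss = closed_loop_mse(net, val_ids)
    else:
        def metre_mse(x, y):
            pred = np.tanh(x @ net.w1 + net.b1) @ net.w2 + net.b2
            return float(np.mean(((pred - y) * out_scaler.half_range) ** 2))

        net.training_loss = metre_mse(x_tr, y_tr)
        net.validation_loss = (
            metre_mse(x_val, y_val) if x_val is not None else float("nan")
        )
    return net


def apply_network(net: TrainedNetwork, samples: PairedSamples) -> FusedTrack:
    """Apply a trained fuser to aligned sensor samples.

    The MLP maps each sample independently.  The NARX runs closed-loop,
    feeding its own (scaled) outputs back at the configured delays; feedback
    taps reaching before the start of the sequence are seeded with the first
    radar position.
    """
    if len(samples) == 0:
        raise ValueError("samples must be non-empty")
    spec = net.spec
    exo = net.input_scaler.scale(samples.features)
    if spec.kind == "mlp":
        out = net.forward(exo)
        return FusedTrack(samples.t.copy(), net.output_scaler.unscale(out), source="mlp")

    n = len(samples)
    out = np.empty((n, spec.n_outputs))
    # feedback taps live in the output scaling (they are past outputs)
    seed_val = net.output_scaler.scale(samples.radar_xy[:1])[0]
    for i in range(n):
        taps = []
        for dlt in spec.feedback_delays:
            taps.append(out[i - dlt] if i - dlt >= 0 else seed_val)
        x = np.concatenate([exo[i]] + taps)
        out[i] = np.tanh(x @ net.w1 + net.b1) @ net.w2 + net.b2
    return FusedTrack(samples.t.copy(), net.output_scaler.unscale(out), source="narx")


def save_network(net: TrainedNetwork, path) -> None:
    """Persist a trained network (spec, weights, scalings, seed) as JSON."""
    payload = {
        "spec": {
            "kind": net.spec.kind,
            "n_hidden": net.spec.n_hidden,
            "n_inputs": net.spec.n_inputs,
            "n_outputs": net.spec.n_outputs,
            "feedback_delays": list(net.spec.feedback_delays),
            "hidden_activation": net.spec.hidden_activation,
            "output_activation": net.spec.output_activation,
        },
        "weights": {
            "w1": net.w1.tolist(),
            "b1": net.b1.tolist(),
            "w2": net.w2.tolist(),
            "b2": net.b2.tolist(),
        },
        "input_scaling": {
            "center": net.input_scaler.center.tolist(),
            "half_range": net.input_scaler.half_range.tolist(),
        },
        "output_scaling": {
            "center": net.output_scaler.center.tolist(),
            "half_range": net.output_scaler.half_range.tolist(),
        },
        "training_seed": net.training_seed,
        "training_loss": net.training_loss,
        "validation_loss": net.validation_loss,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_network(path) -> TrainedNetwork:
    with open(path, encoding="utf-8") as fh:
        p = json.load(fh)
    spec = NetworkSpec(**{**p["spec"], "feedback_delays": tuple(p["spec"]["feedback_delays"])})
    return TrainedNetwork(
        spec=spec,
        w1=np.asarray(p["weights"]["w1"]),
        b1=np.asarray(p["weights"]["b1"]),
        w2=np.asarray(p["weights"]["w2"]),
        b2=np.asarray(p["weights"]["b2"]),
        input_scaler=AffineScaler(
            np.asarray(p["input_scaling"]["center"]),
            np.asarray(p["input_scaling"]["half_range"]),
        ),
        output_scaler=AffineScaler(
            np.asarray(p["output_scaling"]["center"]),
            np.asarray(p["output_scaling"]["half_range"]),
        ),
        training_seed=p["training_seed"],
        training_loss=p["training_loss"],
        validation_loss=p["validation_loss"],
    )
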