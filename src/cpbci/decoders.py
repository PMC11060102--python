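"""Deep decoders: a compact EEGNet-style CNN and a PointNet-style network.

Both regress a free 2D direction vector from a trailing EEG window and emit
one control output per 40 ms tick. The EEGNet-style network operates on
band-passed, decimated raw time series (temporal convolution, depthwise
spatial convolution with a unit max-norm constraint, separable convolution,
then a linear head). The PointNet-style network treats the electrode array
as a point cloud: each electrode carries its 3D position plus its log
amplitude spectrum on 4-40 Hz, and three successive set-abstraction stages
(farthest-point sampling, radius grouping, shared per-point MLP, max-pool)
feed a fully connected head with batch norm, ReLU and 40% dropout. Online,
outputs with norm above 1 are scaled back to the unit circle; smaller
outputs pass through, letting an uncertain model move the cursor slowly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .labeling import preprocess_for, spectrum_freqs
from .montage import Montage

__all__ = [
    "EEGNetSpec",
    "PointNetSpec",
    "DecoderModel",
    "build_eegnet",
    "build_pointnet",
    "DLDecoder",
    "save_checkpoint",
    "load_checkpoint",
    "eegnet_n_params",
]


@dataclass(frozen=True)
class EEGNetSpec:
    n_channels: int = 64
    n_samples: int = 125  # window length after decimation to 125 Hz
    f1: int = 8
    depth: int = 2
    f2: int = 16
    kernel_t: int = 63  # about half the post-decimation rate
    kernel_sep: int = 15
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.25

    def __post_init__(self) -> None:
        if self.f2 != self.f1 * self.depth:
            raise ValueError("canonical architecture requires f2 = f1 * depth")
        if self.n_samples // self.pool1 // self.pool2 < 1:
            raise ValueError("window too short for the pooling factors")


@dataclass(frozen=True)
class PointNetSpec:
    n_points: int = 64
    n_freq_bins: int = 37  # 4..40 Hz at 1 Hz resolution
    centroids: tuple[int, ...] = (32, 16, 1)
    radii: tuple[float, ...] = (0.4, 0.8, float("inf"))
    group_k: tuple[int, ...] = (16, 8, 16)
    widths: tuple[tuple[int, ...], ...] = ((32, 32, 64), (64, 64, 128), (128, 256))
    head_width: int = 128
    dropout: float = 0.40

    def __post_init__(self) -> None:
        if not (len(self.centroids) == len(self.radii) == len(self.widths) == 3):
            raise ValueError("exactly three set-abstraction stages are required")

    @property
    def point_attr_dim(self) -> int:
        return 3 + self.n_freq_bins


# ---------------------------------------------------------------------------
# EEGNet-style network


class _EEGNetNet(nn.Sequential):
    def __init__(self, spec: EEGNetSpec, rng: np.random.Generator):
        t_out = spec.n_samples // spec.pool1 // spec.pool2
        super().__init__(
            [
                nn.TemporalConv(spec.f1, spec.kernel_t, rng),
                nn.BatchNorm(spec.f1, feature_axis=1),
                nn.DepthwiseSpatialConv(spec.f1, spec.depth, spec.n_channels, rng, max_norm=1.0),
                nn.BatchNorm(spec.f1 * spec.depth, feature_axis=1),
                nn.ELU(),
                nn.AvgPoolTime(spec.pool1),
                nn.Dropout(spec.dropout, rng),
                nn.DepthwiseTemporalConv(spec.f1 * spec.depth, spec.kernel_sep, rng),
                nn.PointwiseConv(spec.f1 * spec.depth, spec.f2, rng),
                nn.BatchNorm(spec.f2, feature_axis=1),
                nn.ELU(),
                nn.AvgPoolTime(spec.pool2),
                nn.Dropout(spec.dropout, rng),
                nn.Flatten(),
                nn.Dense(spec.f2 * t_out, 2, rng, max_norm=0.25),
            ]
        )

    def forward(self, x):
        # x: (N, channels, samples) -> add the singleton map axis
        return super().forward(x[:, None, :, :])

    def backward(self, dy):
        return super().backward(dy)[:, 0]


def eegnet_n_params(spec: EEGNetSpec) -> int:
    """Trainable parameter count of the EEGNet-style recipe."""
    t_out = spec.n_samples // spec.pool1 // spec.pool2
    n = spec.f1 * spec.kernel_t  # temporal conv (no bias)
    n += 2 * spec.f1  # batch norm gamma/beta
    n += spec.f1 * spec.depth * spec.n_channels  # depthwise spatial
    n += 2 * spec.f1 * spec.depth
    n += spec.f1 * spec.depth * spec.kernel_sep  # separable: depthwise temporal
    n += spec.f2 * spec.f1 * spec.depth  # separable: pointwise
    n += 2 * spec.f2
    n += spec.f2 * t_out * 2 + 2  # dense head with bias
    return n


# ---------------------------------------------------------------------------
# PointNet-style network


def _geom_order(values: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Sort by value with ties broken by coordinates, so the ordering is a
    function of geometry alone and electrode input order never matters
    (symmetric montages have exact distance ties)."""
    return np.lexsort((xyz[:, 2], xyz[:, 1], xyz[:, 0], values))


def _geom_extremum(values: np.ndarray, xyz: np.ndarray, largest: bool) -> int:
    order = _geom_order(-values if largest else values, xyz)
    return int(order[0])


def farthest_point_sampling(xyz: np.ndarray, n: int) -> np.ndarray:
    """Deterministic FPS on the unit sphere; starts at the point nearest the
    spatial centroid, with all ties broken by coordinates."""
    centroid = xyz.mean(axis=0)
    start = _geom_extremum(((xyz - centroid) ** 2).sum(axis=1), xyz, largest=False)
    chosen = [start]
    d2 = ((xyz - xyz[start]) ** 2).sum(axis=1)
    for _ in range(n - 1):
        nxt = _geom_extremum(d2, xyz, largest=True)
        chosen.append(nxt)
        d2 = np.minimum(d2, ((xyz - xyz[nxt]) ** 2).sum(axis=1))
    return np.array(chosen)


def _group_indices(xyz: np.ndarray, centroid_idx: np.ndarray, radius: float, k: int) -> np.ndarray:
    """(n_centroids, k) neighbor indices: within radius, nearest-k capped,
    padded by repeating the nearest member (padding never changes a max-pool)."""
    out = np.empty((centroid_idx.size, k), dtype=int)
    for j, ci in enumerate(centroid_idx):
        d = np.sqrt(((xyz - xyz[ci]) ** 2).sum(axis=1))
        order = _geom_order(d, xyz)
        within = order[d[order] <= radius]
        if within.size == 0:
            within = order[:1]  # fall back to the nearest neighbor
        members = within[:k]
        out[j] = np.concatenate([members, np.repeat(members[:1], k - members.size)])
    return out


class _SAStage:
    """One set-abstraction stage: group -> shared MLP -> max-pool per group."""

    def __init__(self, n_in: int, widths: tuple[int, ...], rng: np.random.Generator):
        layers: list[nn.Layer] = []
        cur = n_in + 3  # relative xyz concatenated with attributes
        for w in widths:
            layers.append(nn.Dense(cur, w, rng))
            layers.append(nn.BatchNorm(w, feature_axis=-1))
            layers.append(nn.ReLU())
            cur = w
        self.mlp = nn.Sequential(layers)
        self.n_out = cur

    def forward(self, attrs: np.ndarray, xyz: np.ndarray, groups: np.ndarray,
                centroid_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # attrs (N, P, A); groups (M, K) indices into P
        rel = xyz[groups] - xyz[centroid_idx][:, None, :]  # (M, K, 3)
        g = attrs[:, groups, :]  # (N, M, K, A)
        rel_b = np.broadcast_to(rel[None], (attrs.shape[0],) + rel.shape)
        feats = np.concatenate([rel_b, g], axis=-1)
        h = self.mlp.forward(feats)  # (N, M, K, W)
        self._argmax = h.argmax(axis=2)  # (N, M, W)
        self._in_shape = (attrs.shape, feats.shape)
        self._groups = groups
        pooled = np.take_along_axis(h, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]
        return pooled, xyz[centroid_idx]

    def backward(self, dpooled: np.ndarray, attrs_shape) -> np.ndarray:
        n, m, k, w = self._in_shape[1][:3] + (dpooled.shape[-1],)
        dh = np.zeros((n, m, k, w))
        np.put_along_axis(dh, self._argmax[:, :, None, :], dpooled[:, :, None, :], axis=2)
        dfeat = self.mlp.backward(dh)  # (N, M, K, 3+A)
        dattr_group = dfeat[..., 3:]  # gradient w.r.t. gathered attributes
        dattrs = np.zeros(attrs_shape)
        # scatter-add back to the points (groups may repeat indices)
        np.add.at(dattrs, (slice(None), self._groups), dattr_group)
        return dattrs


class _PointNetNet:
    """Three SA stages + fully connected head; operates on (N, P, 3+F)."""

    def __init__(self, spec: PointNetSpec, montage_xyz: np.ndarray, rng: np.random.Generator):
        self.spec = spec
        self.xyz0 = np.asarray(montage_xyz, dtype=float)
        self.stages = []
        n_in = spec.n_freq_bins
        for widths in spec.widths:
            stage = _SAStage(n_in, widths, rng)
            self.stages.append(stage)
            n_in = stage.n_out
        self.head = nn.Sequential(
            [
                nn.Dense(n_in, spec.head_width, rng),
                nn.BatchNorm(spec.head_width, feature_axis=-1),
                nn.ReLU(),
                nn.Dropout(spec.dropout, rng),
                nn.Dense(spec.head_width, 2, rng),
            ]
        )

    def set_train(self, flag: bool) -> None:
        for s in self.stages:
            s.mlp.set_train(flag)
        self.head.set_train(flag)

    def params(self):
        out = []
        for s in self.stages:
            out.extend(s.mlp.params())
        out.extend(self.head.params())
        return out

    def _plan(self, xyz: np.ndarray):
        """Grouping structure from geometry alone (recomputed per point set)."""
        plan = []
        spec = self.spec
        for s in range(3):
            m = spec.centroids[s]
            if m >= xyz.shape[0]:
                cidx = np.arange(xyz.shape[0])
            elif m == 1:
                cidx = np.array(
                    [_geom_extremum(((xyz - xyz.mean(0)) ** 2).sum(1), xyz, largest=False)]
                )
            else:
                cidx = farthest_point_sampling(xyz, m)
            radius = spec.radii[s]
            k = min(spec.group_k[s], xyz.shape[0])
            if not np.isfinite(radius):
                # global stage: every remaining point in one group
                groups = np.tile(np.arange(xyz.shape[0]), (cidx.size, 1))
            else:
                groups = _group_indices(xyz, cidx, radius, k)
            plan.append((cidx, groups))
            xyz = xyz[cidx]
        return plan

    def forward(self, x: np.ndarray) -> np.ndarray:
        xyz = x[0, :, :3]  # positions are identical across the batch
        attrs = x[:, :, 3:]
        plan = self._plan(xyz)
        self._attr_shapes = []
        cur_xyz = xyz
        for stage, (cidx, groups) in zip(self.stages, plan):
            self._attr_shapes.append(attrs.shape)
            attrs, cur_xyz = stage.forward(attrs, cur_xyz, groups, cidx)
        self._pre_head_shape = attrs.shape
        flat = attrs.reshape(attrs.shape[0], -1)  # final stage has 1 centroid
        if flat.shape[1] != self.stages[-1].n_out:
            # more than one global centroid: average them
            flat = attrs.mean(axis=1)
            self._avg = attrs.shape[1]
        else:
            self._avg = None
        return self.head.forward(flat)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dflat = self.head.backward(dy)
        if self._avg is not None:
            dattrs = np.repeat(dflat[:, None, :] / self._avg, self._avg, axis=1)
        else:
            dattrs = dflat.reshape(self._pre_head_shape)
        for stage, shape in zip(reversed(self.stages), reversed(self._attr_shapes)):
            dattrs = stage.backward(dattrs, shape)
        return dattrs


# ---------------------------------------------------------------------------
# model wrapper


@dataclass
class DecoderModel:
    """A trained (or initialized) deep decoder plus its provenance."""

    kind: str  # "eegnet" | "pointnet"
    spec: EEGNetSpec | PointNetSpec
    net: object
    preprocessing: str
    seed: int
    provenance: dict = field(default_factory=dict)

    def set_train(self, flag: bool) -> None:
        self.net.set_train(flag)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward pass on a feature batch."""
        self.set_train(False)
        return self.net.forward(features)

    def copy(self) -> "DecoderModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def state_arrays(self) -> list[np.ndarray]:
        """Snapshot of parameters plus batch-norm running statistics."""
        out = [p.value.copy() for p in self.params()]
        for lyr in _iter_layers(self):
            if isinstance(lyr, nn.BatchNorm):
                out.append(lyr.run_mean.copy())
                out.append(lyr.run_var.copy())
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        for p, v in zip(params, arrays):
            p.value[...] = v
        i = len(params)
        for lyr in _iter_layers(self):
            if isinstance(lyr, nn.BatchNorm):
                lyr.run_mean[...] = arrays[i]
                lyr.run_var[...] = arrays[i + 1]
                i += 2


def build_eegnet(spec: EEGNetSpec, seed: int = 0) -> DecoderModel:
    rng = np.random.default_rng(seed)
    net = _EEGNetNet(spec, rng)
    return DecoderModel(
        kind="eegnet", spec=spec, net=net, preprocessing="raw_downsampled", seed=seed
    )


def build_pointnet(spec: PointNetSpec, montage: Montage, seed: int = 0) -> DecoderModel:
    if montage.n_channels != spec.n_points:
        raise ValueError("montage size does not match spec.n_points")
    rng = np.random.default_rng(seed)
    net = _PointNetNet(spec, montage.xyz, rng)
    return DecoderModel(
        kind="pointnet", spec=spec, net=net, preprocessing="band_spectrum", seed=seed
    )


# ---------------------------------------------------------------------------
# streaming decoder


class DLDecoder:
    """Online wrapper: sliding window buffer emitting one output per tick.

    The first ``window_s`` of each trial emits (0, 0) while the buffer fills;
    afterwards each tick preprocesses the trailing window and runs an
    evaluation-mode forward pass; outputs with norm > 1 are rescaled to 1.
    """

    kind = "dl"

    def __init__(self, model: DecoderModel, montage: Montage, fs: float, window_s: float = 1.0):
        self.model = model
        self.montage = montage
        self.fs = float(fs)
        self.window_n = int(round(window_s * fs))
        self.decoder_id = model.kind
        model.set_train(False)
        self.reset_trial()

    def reset(self) -> None:
        self.reset_trial()

    def reset_trial(self) -> None:
        self._buffer = np.zeros((self.montage.n_channels, 0))
        self._seen = 0

    def step(self, chunk: np.ndarray, aux=None) -> np.ndarray:
        chunk = np.asarray(chunk, dtype=float)
        self._seen += chunk.shape[1]
        self._buffer = np.concatenate([self._buffer, chunk], axis=1)[:, -self.window_n :]
        if self._seen <= self.window_n:
            return np.zeros(2)
        feats = preprocess_for(
            self.model.preprocessing, self._buffer, self.fs, montage_xyz=self.montage.xyz
        )
        out = self.model.predict(feats[None])[0]
        norm = float(np.hypot(*out))
        if norm > 1.0:
            out = out / norm
        return out


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: DecoderModel, path) -> None:
    """Single-file checkpoint: spec + provenance + flat parameter arrays."""
    meta = {
        "kind": model.kind,
        "spec": asdict(model.spec),
        "preprocessing": model.preprocessing,
        "seed": model.seed,
        "provenance": model.provenance,
    }
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    # batch-norm running statistics are state, not parameters; store them too
    stats = {}
    for i, lyr in enumerate(_iter_layers(model)):
        if isinstance(lyr, nn.BatchNorm):
            stats[f"bn{i}_mean"] = lyr.run_mean
            stats[f"bn{i}_var"] = lyr.run_var
    np.savez(path, meta=json.dumps(meta), **arrays, **stats)


def _iter_layers(model: DecoderModel):
    if model.kind == "eegnet":
        yield from model.net.layers
    else:
        for s in model.net.stages:
            yield from s.mlp.layers
        yield from model.net.head.layers


def load_checkpoint(path, montage: Montage | None = None) -> DecoderModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["kind"] == "eegnet":
            spec = EEGNetSpec(**{k: v for k, v in meta["spec"].items()})
            model = build_eegnet(spec, seed=meta["seed"])
        else:
            raw = dict(meta["spec"])
            for k in ("centroids", "radii", "group_k"):
                raw[k] = tuple(raw[k])
            raw["widths"] = tuple(tuple(w) for w in raw["widths"])
            spec = PointNetSpec(**raw)
            if montage is None:
                raise ValueError("loading a pointnet checkpoint requires the montage")
            model = build_pointnet(spec, montage, seed=meta["seed"])
        model.provenance = meta.get("provenance", {})
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        for i, lyr in enumerate(_iter_layers(model)):
            if isinstance(lyr, nn.BatchNorm):
                lyr.run_mean[...] = data[f"bn{i}_mean"]
                lyr.run_var[...] = data[f"bn{i}_var"]
    return model
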