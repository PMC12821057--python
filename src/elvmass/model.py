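"""The LVM regressor: per-lead-group TCN encoders fused with scalar branches.

Each lead group is encoded by its own temporal convolutional network (stacked
dilated residual blocks), pooled and embedded; group embeddings are
concatenated and projected; demographic and ECG-parameter vectors pass
through their own small MLPs; the concatenation of all embeddings feeds an
MLP regressor with a single linear output — predicted LV mass in grams.
Training minimizes mean absolute error.

Sex-specific variants use the same architecture trained on one sex's rows,
with the (then constant) sex indicator dropped from the demographics branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .io_cohort import CohortError
from .preprocess import LeadGrouping, lead_grouping

DEMOGRAPHIC_FEATURES = ("age", "sex_male", "height", "weight")
ECG_PARAM_FEATURES = ("qrs_duration", "p_axis", "r_axis", "t_axis")

INPUT_SETS = ("ecg_only", "ecg_demo", "ecg_demo_params", "ecg_params")

#: scalar branches active under each input set
BRANCHES_FOR_INPUT_SET = {
    "ecg_only": (),
    "ecg_demo": ("demographics",),
    "ecg_demo_params": ("demographics", "ecg_params"),
    "ecg_params": ("ecg_params",),
}


@dataclass
class TcnConfig:
    """Depth/width of one group encoder.

    The receptive field of ``n_blocks`` residual blocks (two convolutions
    each) with kernel ``k`` and dilation ``base**i`` is
    ``R = 1 + sum_i 2*(k-1)*base**i``; construction requires R >= the input
    length so every output sample can see the whole beat.
    """

    n_blocks: int = 5
    channels: int = 32
    kernel_size: int = 7
    dilation_base: int = 2
    dropout: float = 0.1
    embedding_dim: int = 64

    def __post_init__(self):
        for name in ("n_blocks", "channels", "kernel_size", "dilation_base",
                     "embedding_dim"):
            if getattr(self, name) < 1:
                raise CohortError(f"TcnConfig.{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise CohortError("dropout must be in [0, 1)")

    @property
    def receptive_field(self) -> int:
        k, b = self.kernel_size, self.dilation_base
        return 1 + sum(2 * (k - 1) * b ** i for i in range(self.n_blocks))


@dataclass
class ModelSpec:
    grouping_name: str = "electrical"
    tcn: TcnConfig = field(default_factory=TcnConfig)
    scalar_hidden: tuple = (32,)
    projection_dim: int = 128
    regressor_hidden: tuple = (128, 64)
    input_set: str = "ecg_demo_params"
    sex_scope: str = "all"
    causal: bool = False

    def __post_init__(self):
        if self.input_set not in INPUT_SETS:
            raise CohortError(f"input_set must be one of {INPUT_SETS}")
        if self.sex_scope not in ("all", "male", "female"):
            raise CohortError("sex_scope must be all, male or female")

    @property
    def grouping(self) -> LeadGrouping:
        return lead_grouping(self.grouping_name)

    @property
    def branch_names(self) -> tuple:
        return BRANCHES_FOR_INPUT_SET[self.input_set]

    def branch_features(self, branch: str) -> tuple:
        if branch == "demographics":
            feats = DEMOGRAPHIC_FEATURES
            if self.sex_scope != "all":
                feats = tuple(f for f in feats if f != "sex_male")
            return feats
        if branch == "ecg_params":
            return ECG_PARAM_FEATURES
        raise CohortError(f"unknown scalar branch {branch!r}")


def small_model_spec(**overrides) -> ModelSpec:
    """A lighter preset (half-width encoders) used for the shipped
    experiments; same depth, so the receptive field is unchanged."""
    spec = ModelSpec(
        tcn=TcnConfig(channels=16, embedding_dim=32, dropout=0.1),
        projection_dim=64, regressor_hidden=(64, 32))
    for k, v in overrides.items():
        setattr(spec, k, v)
    spec.__post_init__()
    return spec


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics frozen from the training fold."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def transform(self, x: np.ndarray) -> np.ndarray:
        if np.isnan(x).any():
            raise CohortError("NaN scalar input: impute before encoding")
        return (x - self.mean) / self.sd


class LvmRegressor:
    """The assembled network.  Build with :func:`build_model`."""

    def __init__(self, spec: ModelSpec, input_length: int, seed: int = 0):
        tcn = spec.tcn
        if tcn.receptive_field < input_length:
            raise CohortError(
                f"receptive field {tcn.receptive_field} < input length "
                f"{input_length}: increase n_blocks/kernel_size/dilation_base "
                f"(R = 1 + sum 2*(k-1)*base^i must reach the window)")
        self.spec = spec
        self.input_length = input_length
        self.seed = seed
        rng = np.random.default_rng(seed)
        grouping = spec.grouping
        self.group_sizes = [len(leads) for _, leads in grouping.groups]

        self.encoders = []
        for n_leads in self.group_sizes:
            blocks = []
            c_in = n_leads
            for i in range(tcn.n_blocks):
                blocks.append(_nn.TcnBlock(
                    c_in, tcn.channels, tcn.kernel_size,
                    tcn.dilation_base ** i, tcn.dropout, rng,
                    causal=spec.causal))
                c_in = tcn.channels
            blocks.append(_nn.GlobalAvgPool())
            blocks.append(_nn.Linear(tcn.channels, tcn.embedding_dim, rng))
            self.encoders.append(_nn.Sequential(*blocks))

        n_groups = len(self.group_sizes)
        self.projection = _nn.Sequential(
            _nn.Linear(n_groups * tcn.embedding_dim, spec.projection_dim, rng),
            _nn.ReLU())

        self.branches: dict[str, _nn.Sequential] = {}
        self.branch_dims: dict[str, int] = {}
        fused_dim = spec.projection_dim
        for branch in spec.branch_names:
            n_in = len(spec.branch_features(branch))
            layers, prev = [], n_in
            for h in spec.scalar_hidden:
                layers += [_nn.Linear(prev, h, rng), _nn.ReLU()]
                prev = h
            self.branches[branch] = _nn.Sequential(*layers)
            self.branch_dims[branch] = prev
            fused_dim += prev

        layers, prev = [], fused_dim
        for h in spec.regressor_hidden:
            layers += [_nn.Linear(prev, h, rng), _nn.ReLU()]
            prev = h
        layers.append(_nn.Linear(prev, 1, rng))
        self.regressor = _nn.Sequential(*layers)

        self.standardizers: dict[str, Standardizer] = {}

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[_nn.Param]:
        out = []
        for enc in self.encoders:
            out.extend(enc.params())
        out.extend(self.projection.params())
        for br in self.branches.values():
            out.extend(br.params())
        out.extend(self.regressor.params())
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- forward / backward -------------------------------------------------
    def _check_inputs(self, group_waveforms, scalars):
        if len(group_waveforms) != len(self.group_sizes):
            raise CohortError(
                f"expected {len(self.group_sizes)} lead groups "
                f"({self.spec.grouping_name}), got {len(group_waveforms)}")
        for g, (x, size) in enumerate(zip(group_waveforms, self.group_sizes)):
            if x.ndim != 3 or x.shape[1] != size or x.shape[2] != self.input_length:
                raise CohortError(
                    f"group {g}: expected (batch, {size}, "
                    f"{self.input_length}), got {x.shape}")
        for branch in self.spec.branch_names:
            if branch not in scalars:
                raise CohortError(f"missing scalar branch {branch!r}")

    def forward(self, group_waveforms: list[np.ndarray],
                scalars: dict[str, np.ndarray] | None = None,
                train: bool = False) -> np.ndarray:
        scalars = scalars or {}
        self._check_inputs(group_waveforms, scalars)
        embeds = [enc.forward(np.asarray(x, dtype=float), train=train)
                  for enc, x in zip(self.encoders, group_waveforms)]
        fused = self.projection.forward(np.concatenate(embeds, axis=1),
                                        train=train)
        pieces = [fused]
        for branch in self.spec.branch_names:
            pieces.append(self.encode_scalars(scalars[branch], branch,
                                              train=train, _standardize=True))
        self._n_groups_emb = [e.shape[1] for e in embeds]
        out = self.regressor.forward(np.concatenate(pieces, axis=1),
                                     train=train)
        return out[:, 0]

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        """Backpropagate d(loss)/d(prediction); accumulates parameter grads
        and returns d(loss)/d(waveform input) per lead group."""
        g = self.regressor.backward(dout[:, None])
        # split the fused gradient back into projection + branch parts
        cut = self.spec.projection_dim
        g_proj = g[:, :cut]
        for branch in self.spec.branch_names:
            d = self.branch_dims[branch]
            self.branches[branch].backward(g[:, cut:cut + d])
            cut += d
        g_embed = self.projection.backward(g_proj)
        grads, cut = [], 0
        for enc, d in zip(self.encoders, self._n_groups_emb):
            grads.append(enc.backward(g_embed[:, cut:cut + d]))
            cut += d
        return grads

    def encode_scalars(self, values: np.ndarray, branch: str,
                       train: bool = False, _standardize: bool = True
                       ) -> np.ndarray:
        """Standardize (training-fold statistics) and embed one scalar
        branch.  Rejects NaN input: imputation must happen upstream."""
        if branch not in self.branches:
            raise CohortError(
                f"branch {branch!r} not active under input_set "
                f"{self.spec.input_set!r}")
        x = np.asarray(values, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if _standardize:
            if branch in self.standardizers:
                x = self.standardizers[branch].transform(x)
            elif np.isnan(x).any():
                raise CohortError("NaN scalar input: impute before encoding")
        return self.branches[branch].forward(x, train=train)

    def fit_standardizers(self, scalars: dict[str, np.ndarray]):
        for branch in self.spec.branch_names:
            self.standardizers[branch] = Standardizer.fit(
                np.asarray(scalars[branch], dtype=float))

    # -- persistence --------------------------------------------------------
    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        for branch, st in self.standardizers.items():
            arrays[f"std_{branch}_mean"] = st.mean
            arrays[f"std_{branch}_sd"] = st.sd
        np.savez(directory / "weights.npz", **arrays)
        meta = {"spec": asdict(self.spec), "input_length": self.input_length,
                "seed": self.seed}
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "LvmRegressor":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        spec_d = dict(meta["spec"])
        spec_d["tcn"] = TcnConfig(**spec_d["tcn"])
        spec_d["scalar_hidden"] = tuple(spec_d["scalar_hidden"])
        spec_d["regressor_hidden"] = tuple(spec_d["regressor_hidden"])
        spec = ModelSpec(**spec_d)
        model = cls(spec, meta["input_length"], seed=meta["seed"])
        with np.load(directory / "weights.npz") as data:
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
            for branch in spec.branch_names:
                if f"std_{branch}_mean" in data:
                    model.standardizers[branch] = Standardizer(
                        mean=data[f"std_{branch}_mean"],
                        sd=data[f"std_{branch}_sd"])
        return model


def build_model(spec: ModelSpec, input_length: int, seed: int = 0
                ) -> LvmRegressor:
    """Construct the regressor; raises if the encoder receptive field does
    not cover ``input_length``."""
    return LvmRegressor(spec, input_length, seed=seed)


def mae_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error in grams — the training loss."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise CohortError("pred and truth must be equal-length, non-empty")
    return float(np.mean(np.abs(pred - truth)))


def mae_loss_grad(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """d(MAE)/d(pred): sign(pred - truth) / n  (0 at exact ties)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return np.sign(pred - truth) / pred.size


def predict_lvm(model: LvmRegressor, group_waveforms: list[np.ndarray],
                scalars: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Deterministic evaluation-mode prediction (dropout off)."""
    out = model.forward(group_waveforms, scalars, train=False)
    if not np.all(np.isfinite(out)):
        raise CohortError("non-finite prediction")
    return out
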