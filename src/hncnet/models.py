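"""Model builders: the compact CNN, its clinical-fusion variant, the
11-8-4-1 ANN on structured data, and a logistic baseline.

The CNN layer configuration lives in a versioned YAML file
(``configs/default_cnn.yaml``) rather than in code: the builder refuses any
configuration whose conv segment does not produce the contracted 4x4x32
embedding, and the default configuration counts exactly 85,505 trainable
parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ArchitectureError, ConfigurationError
from .nn import SGD, Conv2D, Dense, Dropout, Flatten, FusionNetwork, LeakyReLU, MaxPool2D, Network

#: Parameter count of the Diamant et al. reference network the compact CNN
#: is measured against (printed constant; the network itself is not rebuilt).
DIAMANT_PARAMETER_COUNT = 2_316_385

EXPECTED_EMBEDDING = (32, 4, 4)
EXPECTED_FLAT_FEATURES = 512


@dataclass(frozen=True)
class CNNArchitecture:
    input_hw: tuple[int, int] = (180, 180)
    in_channels: int = 1
    conv_blocks: tuple = ()  # of (filters, kernel, stride, pool)
    fc_sizes: tuple = ()
    leaky_slope: float = 0.01
    dropout_p: float = 0.25
    init: str = "he_uniform_fan_in"
    name: str = "compact-hnc-cnn"
    version: int = 1

    def __post_init__(self):
        if len(self.conv_blocks) != 3:
            raise ArchitectureError(f"expected exactly 3 conv blocks, got {len(self.conv_blocks)}")
        if len(self.fc_sizes) != 4 or self.fc_sizes[-1] != 1:
            raise ArchitectureError(f"expected 4 FC layers ending in 1, got {self.fc_sizes}")

    def config_hash(self) -> str:
        payload = json.dumps({
            "input_hw": self.input_hw, "in_channels": self.in_channels,
            "conv_blocks": [list(b) for b in self.conv_blocks],
            "fc_sizes": list(self.fc_sizes), "leaky_slope": self.leaky_slope,
            "dropout_p": self.dropout_p, "init": self.init, "version": self.version,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class FusionSpec:
    clinical_dim: int
    inject_at_fc: int = 4

    def __post_init__(self):
        if self.clinical_dim <= 0:
            raise ConfigurationError("clinical_dim must be positive")
        if self.inject_at_fc not in (1, 2, 3, 4):
            raise ConfigurationError(f"inject_at_fc must be in 1..4, got {self.inject_at_fc}")


@dataclass
class ModelHandle:
    """A network plus the metadata needed to rebuild or audit it."""

    net: Network
    kind: str                     # "cnn" | "fused_cnn" | "ann" | "logistic"
    seed: int | None = None
    architecture: CNNArchitecture | None = None
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, x, clinical=None) -> np.ndarray:
        return self.net.predict_proba(x, clinical=clinical)

    @property
    def n_params(self) -> int:
        return self.net.n_params()


def load_architecture(path=None) -> CNNArchitecture:
    """Read an architecture YAML; default is the packaged configuration."""
    if path is None:
        with resources.files("hncnet.configs").joinpath("default_cnn.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return CNNArchitecture(
        input_hw=(raw["input"]["height"], raw["input"]["width"]),
        in_channels=raw["input"]["channels"],
        conv_blocks=tuple(
            (b["filters"], b["kernel"], b["stride"], b["pool"]) for b in raw["conv_blocks"]
        ),
        fc_sizes=tuple(raw["fc_sizes"]),
        leaky_slope=float(raw["leaky_slope"]),
        dropout_p=float(raw["dropout_p"]),
        init=str(raw["init"]),
        name=str(raw.get("name", "cnn")),
        version=int(raw.get("version", 1)),
    )


def conv_output_shape(arch: CNNArchitecture) -> tuple[int, int, int]:
    """(channels, height, width) after the three conv blocks."""
    h, w = arch.input_hw
    ch = arch.in_channels
    for filters, kernel, stride, pool in arch.conv_blocks:
        h = (h - kernel) // stride + 1
        w = (w - kernel) // stride + 1
        h, w = h // pool, w // pool
        ch = filters
        if h < 1 or w < 1:
            raise ArchitectureError("conv segment collapses the spatial dimensions")
    return ch, h, w


def _build_layers(arch: CNNArchitecture, rng):
    """Trunk (conv + flatten) and head (FC) layer lists; validates shapes."""
    if arch.init != "he_uniform_fan_in":
        raise ConfigurationError(f"unknown init scheme {arch.init!r}")
    ch, h, w = conv_output_shape(arch)
    if (ch, h, w) != EXPECTED_EMBEDDING:
        raise ArchitectureError(
            f"conv segment produces {ch}x{h}x{w}, contract requires "
            f"{EXPECTED_EMBEDDING[0]}x{EXPECTED_EMBEDDING[1]}x{EXPECTED_EMBEDDING[2]}"
        )
    trunk: list = []
    in_ch = arch.in_channels
    for filters, kernel, stride, pool in arch.conv_blocks:
        trunk.append(Conv2D(in_ch, filters, kernel, stride=stride, rng=rng))
        trunk.append(MaxPool2D(pool))
        trunk.append(LeakyReLU(arch.leaky_slope))
        in_ch = filters
    trunk.append(Flatten())

    head: list = []
    fan_in = ch * h * w
    for i, width in enumerate(arch.fc_sizes):
        head.append(Dense(fan_in, width, rng=rng))
        if i < len(arch.fc_sizes) - 1:
            head.append(LeakyReLU(arch.leaky_slope))
            head.append(Dropout(arch.dropout_p))  # no dropout after the final layer
        fan_in = width
    return trunk, head


def build_cnn(arch: CNNArchitecture | None = None, seed: int = 0) -> ModelHandle:
    """Image-only CNN; seeded so two builds share bit-identical weights."""
    arch = arch or load_architecture()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    trunk, head = _build_layers(arch, rng)
    net = Network(trunk + head)
    return ModelHandle(net=net, kind="cnn", seed=seed, architecture=arch,
                       metadata={"config_hash": arch.config_hash()})


def build_fused_cnn(arch: CNNArchitecture | None = None, fusion: FusionSpec | None = None,
                    seed: int = 0) -> ModelHandle:
    """CNN with the clinical vector concatenated at one FC layer's input."""
    if fusion is None:
        raise ConfigurationError("build_fused_cnn requires a FusionSpec")
    arch = arch or load_architecture()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    trunk, head = _build_layers(arch, rng)
    # widen the injected Dense layer by clinical_dim input columns
    dense_idx = [i for i, l in enumerate(head) if isinstance(l, Dense)]
    pos = dense_idx[fusion.inject_at_fc - 1]
    old: Dense = head[pos]
    head[pos] = Dense(old.in_dim + fusion.clinical_dim, old.out_dim, rng=rng)
    net = FusionNetwork(trunk, head, fusion.inject_at_fc, fusion.clinical_dim)
    return ModelHandle(net=net, kind="fused_cnn", seed=seed, architecture=arch,
                       metadata={"config_hash": arch.config_hash(), "fusion": fusion})


def build_ann(input_dim: int = 11, seed: int = 0, leaky_slope: float = 0.01) -> ModelHandle:
    """Structured-data network: input -> 8 -> 4 -> 1 with leaky ReLU."""
    if input_dim < 1:
        raise ConfigurationError("input_dim must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    layers = [
        Dense(input_dim, 8, rng=rng), LeakyReLU(leaky_slope),
        Dense(8, 4, rng=rng), LeakyReLU(leaky_slope),
        Dense(4, 1, rng=rng),
    ]
    return ModelHandle(net=Network(layers), kind="ann", seed=seed)


def build_logistic_baseline(input_dim: int, seed: int = 0) -> ModelHandle:
    """Single affine layer + sigmoid, fitted with the same SGD machinery."""
    if input_dim < 1:
        raise ConfigurationError("input_dim must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return ModelHandle(net=Network([Dense(input_dim, 1, rng=rng)]), kind="logistic", seed=seed)


def count_parameters(m: ModelHandle) -> int:
    """Sum of all trainable weight and bias entries."""
    return m.n_params


# ---------------------------------------------------------------------------
# checkpoints: single-file npz with weights + config hash + seed
# ---------------------------------------------------------------------------

def save_checkpoint(m: ModelHandle, path) -> None:
    arrays = {f"w{i:03d}": w for i, w in enumerate(m.net.get_weights())}
    meta = {"kind": m.kind, "seed": m.seed,
            "config_hash": m.metadata.get("config_hash", "")}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(m: ModelHandle, path) -> ModelHandle:
    """Load weights saved by :func:`save_checkpoint` into a compatible model."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("config_hash") and meta["config_hash"] != m.metadata.get("config_hash", ""):
            raise ConfigurationError("checkpoint was saved for a different architecture config")
        weights = [data[k] for k in sorted(k for k in data.files if k.startswith("w"))]
    m.net.set_weights(weights)
    return m
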