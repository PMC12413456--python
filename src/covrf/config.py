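"""Run configuration, validation and manifests.

A run is described by a hierarchical YAML configuration with a strict
schema: kernel-bank parameters, neuron parameters, simulator settings,
network architecture and training hyper-parameters, plus the master seed
and output directory.  Loading fills every default and rejects unknown
keys, so a saved configuration always carries complete provenance; a run
manifest records the seeds, configuration hash, package version and every
artifact a run wrote.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "run_manifest",
]


@dataclass
class KernelBankSection:
    orientations: int = 4
    scales: int = 4
    skews: int = 3
    derivative_set: list = field(
        default_factory=lambda: [[1, 0], [0, 1], [1, 1]]
    )
    size: int = 9
    supersample_resolution: int = 81
    sigma_base: float = 1.0

    def validate(self) -> None:
        if min(self.orientations, self.scales, self.skews) < 1:
            raise ValueError("kernel_bank counts must be >= 1")
        for pair in self.derivative_set:
            if len(pair) != 2 or sum(pair) > 2 or min(pair) < 0:
                raise ValueError(
                    "kernel_bank.derivative_set entries must be (m1, m2) "
                    "with m1 + m2 <= 2"
                )


@dataclass
class NeuronSection:
    mu: float = 2.0
    theta_thr: float = 1.0
    theta_reset: float = 0.0
    mu_r: float = 0.0
    dt: float = 1.0
    surrogate_slope: float = 10.0

    def validate(self) -> None:
        if self.mu <= 0:
            raise ValueError("neuron.mu must be positive")
        if self.mu_r < 0:
            raise ValueError("neuron.mu_r must be non-negative")
        if self.theta_thr <= self.theta_reset:
            raise ValueError("neuron.theta_thr must exceed neuron.theta_reset")
        if self.dt <= 0:
            raise ValueError("neuron.dt must be positive")


@dataclass
class SimulatorSection:
    resolution: int = 300
    n_frames: int = 50
    noise_rate: float = 5.0
    threshold: float = 0.15
    noise_convention: str = "per_movie"
    supersample: int = 8

    def validate(self) -> None:
        if self.threshold <= 0:
            raise ValueError("simulator.threshold must be positive")
        if self.noise_convention not in ("per_movie", "per_frame"):
            raise ValueError(
                "simulator.noise_convention must be per_movie or per_frame"
            )


@dataclass
class NetworkSection:
    n_scale_channels: int = 4
    kernels_per_block: int = 144
    kernel_size: int = 9
    kernel_size_late: int | None = None
    n_output_shapes: int = 3
    variant: str = "LI"
    init: str = "rf"
    mf_frames: int = 8
    use_batchnorm: bool = False
    strides: list = field(default_factory=lambda: [2, 2, 2])
    input_gain: float = 1.0
    head_weighting: str = "linear"
    head_temperature: float = 1.0

    def validate(self) -> None:
        if self.variant not in ("LI", "LIF", "ReLU-SF", "ReLU-MF"):
            raise ValueError("network.variant invalid")
        if self.init not in ("rf", "uniform"):
            raise ValueError("network.init invalid")


@dataclass
class TrainingSection:
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    n_runs: int = 5
    validation_fraction: float = 0.2

    def validate(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("training.validation_fraction must be in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("training.epochs/batch_size invalid")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    kernel_bank: KernelBankSection = field(default_factory=KernelBankSection)
    neuron: NeuronSection = field(default_factory=NeuronSection)
    simulator: SimulatorSection = field(default_factory=SimulatorSection)
    network: NetworkSection = field(default_factory=NetworkSection)
    training: TrainingSection = field(default_factory=TrainingSection)

    def validate(self) -> None:
        for section in (self.kernel_bank, self.neuron, self.simulator,
                        self.network, self.training):
            section.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "kernel_bank": KernelBankSection,
    "neuron": NeuronSection,
    "simulator": SimulatorSection,
    "network": NetworkSection,
    "training": TrainingSection,
}


def _build_section(cls, data: dict, prefix: str):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(valid)
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in '{prefix}'; "
            f"valid keys: {sorted(valid)}"
        )
    kwargs = {}
    for name, value in data.items():
        f = valid[name]
        if f.type in ("int",) and not isinstance(value, bool) and isinstance(value, int):
            kwargs[name] = int(value)
        elif f.type == "float" and isinstance(value, (int, float)) and not isinstance(value, bool):
            kwargs[name] = float(value)
        elif f.type == "bool" and isinstance(value, bool):
            kwargs[name] = value
        elif f.type == "str" and isinstance(value, str):
            kwargs[name] = value
        elif f.type in ("list", "int | None") or f.type.startswith("list"):
            kwargs[name] = value
        else:
            # exact-type fallback: accept if it round-trips through YAML
            expected = f.type
            actual = type(value).__name__
            raise ValueError(
                f"type mismatch for '{prefix}.{name}': expected {expected}, "
                f"got {actual}"
            )
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing keys take their defaults; unknown keys and type mismatches are
    hard errors.  An empty file yields the all-defaults configuration.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    top_valid = {"seed", "out_dir", *_SECTIONS}
    unknown = set(data) - top_valid
    if unknown:
        raise ValueError(
            f"unknown top-level key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(top_valid)}"
        )
    kwargs = {}
    if "seed" in data:
        if isinstance(data["seed"], bool) or not isinstance(data["seed"], int):
            raise ValueError("type mismatch for 'seed': expected int")
        kwargs["seed"] = data["seed"]
    if "out_dir" in data:
        kwargs["out_dir"] = str(data["out_dir"])
    for name, cls in _SECTIONS.items():
        section = data.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ValueError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    config = RunConfig(**kwargs)
    config.validate()
    return config


def save_config(config: RunConfig, path) -> None:
    """Write the full configuration (all defaults made explicit) to YAML."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of the configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_manifest(
    outputs: dict[str, str],
    config: RunConfig,
    path=None,
) -> dict:
    """Build (and optionally write) a manifest of a finished run.

    Lists every artifact with an existence check (missing files produce a
    warning entry rather than an error), the seeds, the configuration hash
    and the package version, so any figure-style output can be regenerated
    from the manifest alone.
    """
    from . import __version__

    artifacts = {}
    warnings = []
    for name, p in outputs.items():
        exists = Path(p).exists()
        artifacts[name] = {"path": str(p), "exists": exists}
        if not exists:
            warnings.append(f"artifact '{name}' missing at manifest time: {p}")
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "package_version": __version__,
        "artifacts": artifacts,
        "warnings": warnings,
    }
    if path is not None:
        Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
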