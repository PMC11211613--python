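"""Run configuration, orchestration and reproducibility bookkeeping.

A :class:`RunConfig` fully determines an experiment: the sequence material,
the functioning mode, durations, frequency-scaling factors and the master
seed.  Every output artifact embeds the config echo and its content hash,
and all per-run noise seeds are derived from the master seed by a stable
counter scheme, so a pipeline run is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .network import Network, build_network, scale_time_constants
from .plasticity import LearningParams, train_sequences
from .protocols import MODE_TRANSFORMS, apply_mode
from .sequences import (
    SequenceSet,
    make_nonorthogonal_set,
    make_orthogonal_set,
    make_random_set,
)
from .assessment import SuccessTable, success_table
from .units import DEFAULT_DT, ConfigurationError

__all__ = ["RunConfig", "load_config", "save_config", "run_experiment", "derive_seed"]

_FIXTURES = {
    "orthogonal": make_orthogonal_set,
    "nonorthogonal": make_nonorthogonal_set,
}

_KNOWN_KEYS = {
    "fixture", "mode", "duration", "dt", "theta_factor", "gamma_factor",
    "n_runs", "seed", "out_dir", "unit_overrides",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated experiment configuration with defaults filled in."""

    fixture: str = "orthogonal"       # fixture name or path to a YAML set
    mode: str = "retrieval"
    duration: float = 1.0             # s, per assessment run
    dt: float = DEFAULT_DT            # s
    theta_factor: float = 1.0         # time-constant multiplier, theta unit
    gamma_factor: float = 1.0         # time-constant multiplier, L1/L2 fast GABA
    n_runs: int = 10
    seed: int = 0
    out_dir: str = "runs"
    unit_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        if self.theta_factor <= 0 or self.gamma_factor <= 0:
            raise ConfigurationError("frequency factors must be > 0")
        if self.mode not in MODE_TRANSFORMS:
            raise ConfigurationError(f"unknown mode {self.mode!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sequence_set(self) -> SequenceSet:
        if self.fixture in _FIXTURES:
            return _FIXTURES[self.fixture]()
        path = Path(self.fixture)
        if path.exists():
            return SequenceSet.from_yaml(path.read_text())
        raise ConfigurationError(
            f"fixture {self.fixture!r} is neither a named set {sorted(_FIXTURES)} nor a file"
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**doc)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def derive_seed(master: int, *counters: int) -> int:
    """Stable per-(stage, sequence, run) seed derived from the master seed."""
    h = hashlib.sha256(np.array([master, *counters], dtype=np.int64).tobytes())
    return int.from_bytes(h.digest()[:4], "little") % (2**31 - 1)


def build_trained_network(cfg: RunConfig) -> tuple[Network, SequenceSet]:
    """Train a network on the configured material with the configured
    frequency scalings applied afterwards."""
    seqs = cfg.sequence_set()
    net = build_network(mode="retrieval", unit_overrides=cfg.unit_overrides or None)
    trained = train_sequences(net, seqs, LearningParams(), dt=cfg.dt,
                              seed=derive_seed(cfg.seed, 0))
    if cfg.theta_factor != 1.0:
        scale_time_constants(trained, ["theta_glutamatergic_and_slowGABA"], cfg.theta_factor)
    if cfg.gamma_factor != 1.0:
        scale_time_constants(trained, ["L1L2_fastGABA"], cfg.gamma_factor)
    return trained, seqs


def run_experiment(cfg: RunConfig) -> dict:
    """Full pipeline: train, run the configured mode, assess.

    Returns a bundle with the trained network, the success table (for
    retrieval mode) and metadata; writes nothing unless ``out_dir`` is used
    by the caller (the CLI persists artifacts)."""
    trained, seqs = build_trained_network(cfg)
    bundle: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "network": trained,
        "sequence_set": seqs,
    }
    if cfg.mode == "retrieval":
        table = success_table(
            trained, seqs, n_runs=cfg.n_runs, duration=cfg.duration,
            seed=derive_seed(cfg.seed, 1), dt=cfg.dt,
        )
        table.meta["config_hash"] = cfg.content_hash()
        bundle["table"] = table
    else:
        from .protocols import run_isolation

        bundle["result"] = run_isolation(
            trained, cfg.mode, duration=cfg.duration,
            seed=derive_seed(cfg.seed, 2),
        )
    return bundle
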