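"""Config parsing, trace/snapshot I/O, and run logging.

The run configuration is a flat ``key = value`` text file (``#`` comments
allowed).  Unset keys fall back to mode defaults; the ``stable_demo`` and
``unstable_demo`` modes default to the two reference parameter sets of the
numerical experiments (balanced vs over-strong lateral gains).  Unknown keys
are rejected and all validation problems are reported together.

Traces are CSV (epoch, distortion, mean_weight_change, field_max); snapshots
are HDF5 with bit-exact array round trips and a config digest so a snapshot
can be matched to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ExperimentConfig", "ConfigError", "read_config", "write_config",
    "write_trace", "read_trace", "SnapshotRecord", "write_snapshot",
    "read_snapshot", "config_digest", "setup_run_logger",
    "DEFAULT_SWEEP_PAIRS", "scaled_down",
]

MODES = ("stable_demo", "unstable_demo", "sweep", "custom")

#: (Ke, Ki) pairs of the reference sweep; the last two violate the stability
#: condition.
DEFAULT_SWEEP_PAIRS: tuple[tuple[float, float], ...] = (
    (0.30, 0.25), (0.4, 0.35), (0.5, 0.45), (0.7, 0.63),
    (0.9, 0.86), (1.0, 0.92), (2.0, 1.85), (3.0, 2.85),
)


class ConfigError(ValueError):
    """Invalid configuration; ``problems`` lists every offending field."""

    def __init__(self, problems: list[str]):
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))
        self.problems = problems


@dataclass
class ExperimentConfig:
    """Full parameter set for one experiment (kernel + grid + integration)."""

    mode: str = "stable_demo"
    Ke: float = 0.90
    sigma_e: float = 0.1
    Ki: float = 0.86
    sigma_i: float = 1.0
    grid_n: int = 40
    domain_a: float = 0.0
    domain_b: float = 1.0
    q: int = 2
    tau: float = 1.0
    gamma: float = 0.002
    dt: float = 0.015
    t: float = 25.0
    epochs: int = 7000
    seed: int = 10
    init_low: float = 0.0
    init_high: float = 0.01
    log_stride: int = 1
    sweep_pairs: tuple[tuple[float, float], ...] = field(default=DEFAULT_SWEEP_PAIRS)

    def validate(self) -> None:
        problems = []
        if self.mode not in MODES:
            problems.append(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("Ke", "sigma_e", "Ki", "sigma_i", "tau", "dt", "t"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0, got {getattr(self, name)}")
        if self.gamma < 0:
            problems.append(f"gamma must be >= 0, got {self.gamma}")
        if self.grid_n < 1:
            problems.append(f"grid_n must be >= 1, got {self.grid_n}")
        if self.q not in (1, 2):
            problems.append(f"q must be 1 or 2, got {self.q}")
        if self.domain_b < self.domain_a:
            problems.append(f"domain_b ({self.domain_b}) must be >= domain_a ({self.domain_a})")
        if self.epochs < 0:
            problems.append(f"epochs must be >= 0, got {self.epochs}")
        if self.log_stride < 1:
            problems.append(f"log_stride must be >= 1, got {self.log_stride}")
        if not (self.init_low <= self.init_high):
            problems.append("init_low must be <= init_high")
        if not (0.0 <= self.init_low and self.init_high <= 1.0):
            problems.append("codebook initialization range must lie in [0, 1]")
        if self.mode == "sweep" and not self.sweep_pairs:
            problems.append("sweep mode requires a non-empty sweep_pairs list")
        if problems:
            raise ConfigError(problems)


#: Per-mode overrides applied on top of the dataclass defaults (which are the
#: stable reference parameters).
_MODE_DEFAULTS = {
    "stable_demo": {},
    "unstable_demo": {"Ke": 3.0, "Ki": 2.80},
    "sweep": {},
    "custom": {},
}


def scaled_down(config: ExperimentConfig) -> ExperimentConfig:
    """Desk-scale profile: shorter epochs (t=5) at preserved per-epoch learning.

    The grid stays at full resolution — the discrete lateral gain scales with
    the number of nodes under the kernel, so shrinking the lattice changes
    the dynamics regime, not just its accuracy.  Instead the within-epoch
    horizon is cut 5x with the learning rate raised 5x (preserving the
    per-epoch learning pull t*gamma) and the epoch count reduced.  Runs in
    minutes; the full-scale profile stays available via the plain config.
    """
    return replace(config, epochs=1500, t=5.0, gamma=config.gamma * config.t / 5.0)


_FLOAT_KEYS = {"Ke", "sigma_e", "Ki", "sigma_i", "domain_a", "domain_b",
               "tau", "gamma", "dt", "t", "init_low", "init_high"}
_INT_KEYS = {"grid_n", "q", "epochs", "seed", "log_stride"}


def _parse_pairs(text: str) -> tuple[tuple[float, float], ...]:
    pairs = []
    for chunk in text.split(","):
        ke, ki = chunk.split(":")
        pairs.append((float(ke), float(ki)))
    return tuple(pairs)


def _format_pairs(pairs) -> str:
    return ",".join(f"{ke:g}:{ki:g}" for ke, ki in pairs)


def read_config(path, mode: str | None = None) -> ExperimentConfig:
    """Parse and validate a flat key=value config file.

    ``mode`` (or a ``mode`` key in the file) selects the default parameter
    set; explicit keys override it.  Unknown keys and invalid values are
    reported collectively in a :class:`ConfigError`.
    """
    path = Path(path)
    raw: dict[str, str] = {}
    problems: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            problems.append(f"line {lineno}: expected 'key = value', got {line!r}")
            continue
        key, value = (part.strip() for part in stripped.split("=", 1))
        raw[key] = value

    mode = raw.pop("mode", mode) or "stable_demo"
    if mode not in MODES:
        raise ConfigError([f"mode must be one of {MODES}, got {mode!r}"])
    values: dict = {"mode": mode, **_MODE_DEFAULTS[mode]}
    for key, text in raw.items():
        try:
            if key in _FLOAT_KEYS:
                values[key] = float(text)
            elif key in _INT_KEYS:
                values[key] = int(text)
            elif key == "sweep_pairs":
                values[key] = _parse_pairs(text)
            else:
                problems.append(f"unknown config key {key!r}")
        except ValueError:
            problems.append(f"could not parse {key} = {text!r}")
    if problems:
        raise ConfigError(problems)
    config = ExperimentConfig(**values)
    config.validate()
    return config


def write_config(config: ExperimentConfig, path) -> None:
    """Write a config in the flat key=value format (read_config inverse)."""
    lines = []
    for key, value in asdict(config).items():
        if key == "sweep_pairs":
            value = _format_pairs(value)
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def config_digest(config: ExperimentConfig) -> str:
    """Stable SHA-256 digest of the canonical key=value serialization."""
    canon = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------- traces ---

_TRACE_COLUMNS = ["epoch", "distortion", "mean_weight_change", "field_max"]


def write_trace(path, trace: pd.DataFrame) -> None:
    """Write the per-epoch scalar trace as CSV (NaN serialized as empty)."""
    missing = [c for c in _TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"trace is missing columns {missing}")
    trace.to_csv(path, index=False, columns=_TRACE_COLUMNS)


def read_trace(path) -> pd.DataFrame:
    """Read a trace CSV back; exact inverse of write_trace for finite values."""
    try:
        trace = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    missing = [c for c in _TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"trace file {path} is missing columns {missing}")
    return trace


# ------------------------------------------------------------- snapshots ---


@dataclass
class SnapshotRecord:
    """One training snapshot: codebook + field at an epoch, tied to a config."""

    codebook: np.ndarray
    field: np.ndarray
    epoch: int
    config_digest: str = ""


def write_snapshot(path, record: SnapshotRecord) -> None:
    """Write a snapshot to HDF5 (bit-exact array round trip)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("codebook", data=record.codebook)
        h5.create_dataset("field", data=record.field)
        h5.attrs["epoch"] = record.epoch
        h5.attrs["config_digest"] = record.config_digest


def read_snapshot(path, expected_digest: str | None = None,
                  expected_k: int | None = None) -> SnapshotRecord:
    """Read a snapshot; warn on digest mismatch, error on shape mismatch."""
    with h5py.File(path, "r") as h5:
        record = SnapshotRecord(
            codebook=h5["codebook"][...],
            field=h5["field"][...],
            epoch=int(h5.attrs["epoch"]),
            config_digest=str(h5.attrs.get("config_digest", "")),
        )
    if expected_k is not None:
        k = record.codebook.reshape(-1, record.codebook.shape[-1]).shape[0]
        if k != expected_k:
            raise ValueError(f"snapshot has k={k} codebook vectors, expected {expected_k}")
    if expected_digest is not None and record.config_digest != expected_digest:
        logging.getLogger("nfsom").warning(
            "snapshot %s was produced under a different configuration", path)
    return record


def setup_run_logger(outdir) -> logging.Logger:
    """Timestamped, level-tagged file logger under the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger(f"nfsom.run.{outdir.name}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    return logger
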