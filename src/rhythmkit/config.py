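"""Algorithm and run configuration.

All thresholds of the sleep-detection algorithm live in
:class:`AlgorithmConfig`; the CLI wraps it in :class:`RunConfig` together
with I/O paths.  Both serialize to/from YAML or JSON mappings and reject
unknown keys so that a typo in a config file fails loudly instead of being
silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from datetime import time
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError

__all__ = ["AlgorithmConfig", "RunConfig", "load_run_config", "config_hash"]


def _parse_clock(value: Any) -> time:
    """Accept ``datetime.time`` or an ``HH:MM[:SS]`` string."""
    if isinstance(value, time):
        return value
    if isinstance(value, str):
        parts = value.split(":")
        if len(parts) in (2, 3) and all(p.isdigit() for p in parts):
            h, m = int(parts[0]), int(parts[1])
            s = int(parts[2]) if len(parts) == 3 else 0
            if h < 24 and m < 60 and s < 60:
                return time(h, m, s)
    raise ConfigError(f"not a clock time (HH:MM): {value!r}")


def _fmt_clock(t: time) -> str:
    return t.strftime("%H:%M:%S") if t.second else t.strftime("%H:%M")


@dataclass
class AlgorithmConfig:
    """Thresholds and windows of the sleep-detection algorithm.

    Parameters
    ----------
    reactive_lookback_s:
        A usage episode is *reactive* when a notification falls within this
        many seconds before screen-on (half-open ``[on - lookback, on)``).
    flood_threshold:
        Apps posting more than this many notifications on one calendar day
        have all that day's notifications excluded before classification.
    window_start, window_end:
        Nightly sleep-search window (default 22:00 -> 10:00 the next day);
        the maximal non-usage episode inside it is taken as sleep.
    scan_start, scan_end:
        Bounds on how far outside the window the original screen-off /
        screen-on may be traced back (default noon to next noon), so
        boundary resumption cannot absorb a daytime nap.
    exclude_first_last_days:
        Drop the nights that wake on the first and last calendar day of a
        participant's log, which are incomplete in field recordings.
    min_sleep_floor_s:
        Detected sleep shorter than this raises a warning (naps/shift work
        are out of scope for the algorithm).
    weekend_basis:
        ``"wake_date"`` (night counts as weekend when the morning is Sat/Sun)
        or ``"onset_date"`` (the evening is Sat/Sun).
    timezone:
        IANA zone used to localize epoch or zone-aware timestamps; ``None``
        keeps epoch timestamps in UTC.
    """

    reactive_lookback_s: int = 60
    flood_threshold: int = 500
    window_start: time = time(22, 0)
    window_end: time = time(10, 0)
    scan_start: time = time(12, 0)
    scan_end: time = time(12, 0)
    exclude_first_last_days: bool = True
    min_sleep_floor_s: int = 3 * 3600
    weekend_basis: str = "wake_date"
    timezone: str | None = None

    def __post_init__(self) -> None:
        self.window_start = _parse_clock(self.window_start)
        self.window_end = _parse_clock(self.window_end)
        self.scan_start = _parse_clock(self.scan_start)
        self.scan_end = _parse_clock(self.scan_end)
        if self.reactive_lookback_s <= 0:
            raise ConfigError("reactive_lookback_s must be > 0")
        if self.flood_threshold < 1:
            raise ConfigError("flood_threshold must be >= 1")
        if self.window_start == self.window_end:
            raise ConfigError("sleep window must be non-empty")
        if self.weekend_basis not in ("wake_date", "onset_date"):
            raise ConfigError("weekend_basis must be 'wake_date' or 'onset_date'")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("window_start", "window_end", "scan_start", "scan_end"):
            d[key] = _fmt_clock(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AlgorithmConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown algorithm config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunConfig:
    """A full CLI run: algorithm settings plus I/O paths and options."""

    algorithm: AlgorithmConfig = field(default_factory=AlgorithmConfig)
    input_paths: list[str] = field(default_factory=list)
    output_dir: str = "."
    input_format: str = "csv"  # csv | jsonl
    strict: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.algorithm, dict):
            self.algorithm = AlgorithmConfig.from_dict(self.algorithm)
        if self.input_format not in ("csv", "jsonl"):
            raise ConfigError("input_format must be 'csv' or 'jsonl'")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["algorithm"] = self.algorithm.to_dict()
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)


def config_hash(cfg: RunConfig | AlgorithmConfig) -> str:
    """Stable SHA-256 of the canonical JSON form, for provenance blocks."""
    canonical = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
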