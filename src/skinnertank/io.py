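"""Configuration loading, presets, session logs, manifests, end-to-end runs.

Session logs are JSONL: a header object (preset, seed, agent parameters,
artifact version) followed by one object per trial record. The format is
append-safe and streams; re-running the same (preset, params, seed) yields
a byte-identical log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from . import __version__
from .agents import AgentParams
from .engine import (ProtocolConfig, SubjectRun, TrialRecord, run_ladder)

__all__ = [
    "ConfigError",
    "load_config",
    "load_preset",
    "preset_names",
    "load_agent_params",
    "write_session_log",
    "read_session_log",
    "RunManifest",
    "end_to_end",
]


class ConfigError(ValueError):
    pass


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ProtocolConfig)}
_AGENT_FIELDS = {f.name for f in dataclasses.fields(AgentParams)}


def _config_from_mapping(data: dict, source: str) -> ProtocolConfig:
    if not isinstance(data, dict):
        raise ConfigError(f"{source}: expected a mapping")
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"{source}: unknown fields {sorted(unknown)}")
    if "ladder" in data:
        data = {**data, "ladder": tuple(data["ladder"])}
    if "max_days" in data:
        data = {**data, "max_days": {str(k): int(v)
                                     for k, v in data["max_days"].items()}}
    try:
        return ProtocolConfig(**data)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{source}: {err}") from err


def load_config(path) -> ProtocolConfig:
    """Load and validate a protocol configuration from a YAML file.
    Unknown fields are rejected with a clear message."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    return _config_from_mapping(data, str(path))


def preset_names() -> tuple:
    return tuple(sorted(
        p.name.removesuffix(".yaml")
        for p in resources.files("skinnertank.presets").iterdir()
        if p.name.endswith(".yaml")))


def load_preset(name: str) -> ProtocolConfig:
    """Load a shipped experiment preset by name (exp1_manual ... exp5)."""
    ref = resources.files("skinnertank.presets").joinpath(f"{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {preset_names()}") from None
    return _config_from_mapping(yaml.safe_load(text), f"preset {name}")


def load_agent_params(path) -> AgentParams:
    """Load agent parameters from a YAML file (unknown fields rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - _AGENT_FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown agent fields {sorted(unknown)}")
    try:
        return AgentParams(**data)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{path}: {err}") from err


# ---------------------------------------------------------------------------
# session logs

def _header_for(run: SubjectRun) -> dict:
    return {"type": "header", "version": __version__,
            "subject_id": run.subject_id, "preset": run.preset,
            "seed": run.seed, "agent": dataclasses.asdict(run.params),
            "gate": dataclasses.asdict(run.gate) if run.gate else None,
            "results": {t: dataclasses.asdict(r)
                        for t, r in run.results.items()}}


def write_session_log(path, run: SubjectRun) -> None:
    """Write a subject run as JSONL: one header line, one line per trial."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps(_header_for(run), sort_keys=True) + "\n")
        for sess in run.sessions:
            for trial in sess.trials:
                fh.write(json.dumps(dataclasses.asdict(trial),
                                    sort_keys=True) + "\n")


def read_session_log(path) -> tuple[dict, list]:
    """Read a JSONL session log; returns (header, [TrialRecord])."""
    path = Path(path)
    header = None
    trials = []
    trial_fields = {f.name for f in dataclasses.fields(TrialRecord)}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if obj.get("type") == "header":
                header = obj
                continue
            unknown = set(obj) - trial_fields
            if unknown:
                raise ConfigError(
                    f"{path}:{lineno}: unknown trial fields {sorted(unknown)}")
            trials.append(TrialRecord(**obj))
    if header is None:
        raise ConfigError(f"{path}: missing header line")
    return header, trials


@dataclass(frozen=True)
class RunManifest:
    """Provenance record: re-running the same preset/agent/seed with the
    same artifact version reproduces byte-identical logs."""

    preset: str
    seed: int
    version: str
    output_sha256: dict

    @staticmethod
    def for_outputs(preset: str, seed: int, paths) -> "RunManifest":
        hashes = {}
        for p in paths:
            p = Path(p)
            hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        return RunManifest(preset, seed, __version__, hashes)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# end-to-end

def end_to_end(preset: str, params: AgentParams | None, seed: int,
               out: str | Path | None = None,
               subject_id: str = "S1") -> tuple[SubjectRun, dict]:
    """Run one subject through a preset and summarize the outcome.

    Returns the run and a report dict (per-task accuracy, criterion
    outcomes). When ``out`` is given, the JSONL log and a manifest are
    written next to it.
    """
    from .stats import summarize_run

    config = load_preset(preset)
    params = params or AgentParams()
    run = run_ladder(params, config, seed, subject_id=subject_id)
    report = summarize_run(run)
    if out is not None:
        out = Path(out)
        write_session_log(out, run)
        RunManifest.for_outputs(preset, seed, [out]).write(
            out.with_suffix(".manifest.json"))
    return run, report
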