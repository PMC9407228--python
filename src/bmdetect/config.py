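"""YAML run configuration: one file drives simulation, candidates, training, NS.

Sections map onto the package's dataclasses::

    phantom:    PhantomParams fields
    candidates: CandidateConfig fields
    model:      teacher/student ModelSpec fields
    noise:      NoiseConfig fields
    training:   TrainingConfig fields (lam/ts/iterations live under `ns`)
    ns:         ts, lam, iterations

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from typing import Any

import yaml

from .candidates import CandidateConfig
from .cropnet import ModelSpec
from .noising import NoiseConfig
from .ns_training import TrainingConfig
from .phantom import PhantomParams

__all__ = ["RunConfig", "load_config", "save_config"]


def _build(cls, data: dict | None, **extra):
    data = dict(data or {})
    data.update(extra)
    names = {f.name for f in dc_fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for f in dc_fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


class RunConfig:
    """All stage configurations of one run, loadable from a single YAML file."""

    def __init__(
        self,
        phantom: PhantomParams,
        candidates: CandidateConfig,
        teacher: ModelSpec,
        student: ModelSpec,
        noise: NoiseConfig,
        training: TrainingConfig,
        ts: float = 0.90,
        lam: float = 1.0,
        ns_iterations: int = 1,
    ):
        self.phantom = phantom
        self.candidates = candidates
        self.teacher = teacher
        self.student = student
        self.noise = noise
        self.training = training
        self.ts = ts
        self.lam = lam
        self.ns_iterations = ns_iterations

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {"phantom", "candidates", "teacher", "student", "noise", "training", "ns"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        noise = _build(NoiseConfig, raw.get("noise"))
        teacher_raw = dict(raw.get("teacher") or {})
        teacher_raw.setdefault("blocks_per_level", 2)
        student_raw = dict(raw.get("student") or {})
        student_raw.setdefault("blocks_per_level", 4)
        ns = dict(raw.get("ns") or {})
        return cls(
            phantom=_build(PhantomParams, raw.get("phantom")),
            candidates=_build(CandidateConfig, raw.get("candidates")),
            teacher=_build(ModelSpec, teacher_raw),
            student=_build(ModelSpec, student_raw),
            noise=noise,
            training=_build(TrainingConfig, raw.get("training"), noise=noise),
            ts=float(ns.get("ts", 0.90)),
            lam=float(ns.get("lam", 1.0)),
            ns_iterations=int(ns.get("iterations", 1)),
        )

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        out = {
            "phantom": asdict(self.phantom),
            "candidates": asdict(self.candidates),
            "teacher": asdict(self.teacher),
            "student": asdict(self.student),
            "noise": asdict(self.noise),
            "training": {
                k: v for k, v in asdict(self.training).items() if k != "noise"
            },
            "ns": {"ts": self.ts, "lam": self.lam, "iterations": self.ns_iterations},
        }

        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            return obj

        return clean(out)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
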