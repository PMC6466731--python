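"""Serialization of traces, cohorts and cohort specifications.

Traces are stored as two-column CSV (``time_ms,voltage_uV``) with a JSON
sidecar carrying sampling metadata; a cohort is a directory tree
``group/eye/intensity_XX/sweep_YY.csv``.  Floats are written with ``repr``
precision so a round trip is bit-exact and regeneration from the same spec
and seed is byte-identical after serialization.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .synth import Cohort, CohortSpec, ComponentParams, Eye, GroupSpec, StimulusSeries, Trace, TraceConfig

__all__ = ["write_trace", "read_trace", "save_cohort", "load_cohort", "cohort_spec_to_yaml", "cohort_spec_from_yaml"]


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Write one sweep as CSV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("time_ms,voltage_uV\n")
        for t, v in zip(trace.t_ms, trace.v_uV):
            fh.write(f"{float(t)!r},{float(v)!r}\n")
    sidecar = {"fs_hz": trace.fs_hz, "onset_ms": trace.onset_ms, **_jsonable(trace.meta)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    return path


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    meta = json.loads(path.with_suffix(".json").read_text())
    fs = meta.pop("fs_hz")
    onset = meta.pop("onset_ms")
    return Trace(data[:, 0], data[:, 1], onset_ms=onset, fs_hz=fs, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_cohort(cohort: Cohort, root: str | Path) -> Path:
    """Directory tree ``group/eye/intensity_XX/sweep_YY.csv`` plus spec YAML."""
    root = Path(root)
    for eye in cohort.eyes:
        for i, sweeps in enumerate(eye.sweep_sets, start=1):
            for j, sweep in enumerate(sweeps, start=1):
                write_trace(sweep, root / eye.group / eye.eye_id / f"intensity_{i:02d}" / f"sweep_{j:02d}.csv")
        truth = root / eye.group / eye.eye_id / "truth.json"
        truth.write_text(json.dumps({
            "params": dataclasses.asdict(eye.params), "animal_id": eye.animal_id,
            "qc_flags": list(eye.qc_flags),
        }, sort_keys=True, indent=1))
    cohort_spec_to_yaml(cohort.spec, root / "cohort_spec.yaml")
    return root


def load_cohort(root: str | Path) -> Cohort:
    root = Path(root)
    spec = cohort_spec_from_yaml(root / "cohort_spec.yaml")
    eyes = []
    for group_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for eye_dir in sorted(p for p in group_dir.iterdir() if p.is_dir()):
            truth = json.loads((eye_dir / "truth.json").read_text())
            sweep_sets = []
            for int_dir in sorted(eye_dir.glob("intensity_*")):
                sweep_sets.append([read_trace(p) for p in sorted(int_dir.glob("sweep_*.csv"))])
            eyes.append(Eye(
                eye_id=eye_dir.name, animal_id=truth["animal_id"], group=group_dir.name,
                params=ComponentParams(**truth["params"]), sweep_sets=sweep_sets,
                qc_flags=tuple(truth["qc_flags"]),
            ))
    return Cohort(spec=spec, eyes=eyes)


def cohort_spec_to_yaml(spec: CohortSpec, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "seed": spec.seed,
        "sweeps_per_intensity": spec.sweeps_per_intensity,
        "stimulus": {"intensities_log": list(spec.stimulus.intensities_log), "lambda_max_nm": spec.stimulus.lambda_max_nm},
        "trace": dataclasses.asdict(spec.config),
        "groups": [
            {"name": g.name, "eyes": g.eyes, "eyes_per_animal": g.eyes_per_animal,
             "means": dataclasses.asdict(g.means), "sds": dict(g.sds)}
            for g in spec.groups
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def cohort_spec_from_yaml(path: str | Path) -> CohortSpec:
    doc = yaml.safe_load(Path(path).read_text())
    groups = tuple(
        GroupSpec(name=g["name"], eyes=g["eyes"], eyes_per_animal=g.get("eyes_per_animal", 2),
                  means=ComponentParams(**g["means"]), sds=g.get("sds", {}))
        for g in doc["groups"]
    )
    return CohortSpec(
        groups=groups,
        stimulus=StimulusSeries(tuple(doc["stimulus"]["intensities_log"]), doc["stimulus"]["lambda_max_nm"]),
        config=TraceConfig(**doc["trace"]),
        sweeps_per_intensity=doc["sweeps_per_intensity"],
        seed=doc["seed"],
    )
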