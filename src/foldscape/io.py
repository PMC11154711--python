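"""File I/O, fit reports and the reproducible pipeline runner.

Data travel as TSV with a '#'-prefixed YAML header carrying provenance
(ground-truth parameters, seeds, units); fit results are JSON documents;
trajectories are multi-frame XYZ or minimal multi-MODEL PDB.  Everything is
plain text and diffable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .md import Trajectory

__all__ = [
    "TableError",
    "MissingColumnError",
    "NonNumericError",
    "MonotonicityError",
    "read_table",
    "write_table",
    "read_xyz",
    "write_xyz",
    "read_pdb_ca",
    "write_pdb_ca",
    "FitReport",
    "RunConfig",
    "run_pipeline",
]


class TableError(ValueError):
    """Base class for tabular-input problems."""


class MissingColumnError(TableError):
    pass


class NonNumericError(TableError):
    pass


class MonotonicityError(TableError):
    pass


def write_table(
    path: str | Path, data: dict | pd.DataFrame, metadata: dict | None = None
) -> None:
    """Write a TSV table with a commented YAML metadata header."""
    df = pd.DataFrame(data)
    path = Path(path)
    with open(path, "w") as fh:
        if metadata:
            for line in yaml.safe_dump(metadata, sort_keys=True).splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_table(
    path: str | Path,
    expected_columns: list[str] | None = None,
    monotone_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Read a TSV table with an optional '#'-prefixed YAML header.

    Validates presence of ``expected_columns``, numeric content, and strict
    monotonicity of ``monotone_columns`` — each failure raises a distinct
    error type naming the offending column.
    """
    path = Path(path)
    header_lines = []
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            header_lines.append(line.lstrip("#").rstrip("\n").removeprefix(" "))
        else:
            body_start = i
            break
    metadata = yaml.safe_load("\n".join(header_lines)) if header_lines else {}
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    if expected_columns:
        missing = [c for c in expected_columns if c not in df.columns]
        if missing:
            raise MissingColumnError(f"missing column(s): {', '.join(missing)}")
        for c in expected_columns:
            vals = pd.to_numeric(df[c], errors="coerce")
            if vals.isna().any():
                raise NonNumericError(f"non-numeric cells in column {c!r}")
            df[c] = vals
    for c in monotone_columns or []:
        if c not in df.columns:
            raise MissingColumnError(f"missing column(s): {c}")
        if np.any(np.diff(df[c].to_numpy(dtype=float)) <= 0):
            raise MonotonicityError(f"column {c!r} must be strictly increasing")
    return df, metadata or {}


# --------------------------------------------------------------------------
# trajectory formats


def write_xyz(path: str | Path, traj: Trajectory, comment: str = "frame") -> None:
    """Write a multi-frame XYZ file (element, x, y, z per atom; frame blocks)."""
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.coordinates):
            fh.write(f"{traj.n_atoms}\n{comment} {i}\n")
            for label, (x, y, z) in zip(traj.atom_labels, frame):
                el = label[:1] if label else "C"
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path, frame_interval: float = 20.0) -> Trajectory:
    """Read a multi-frame XYZ file into a trajectory."""
    frames, labels = [], None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        coords, labs = [], []
        for ln in block:
            parts = ln.split()
            labs.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append(coords)
        if labels is None:
            labels = labs
        i += 2 + n
    return Trajectory(
        coordinates=np.array(frames, dtype=float),
        frame_interval=frame_interval,
        atom_labels=labels,
    )


def write_pdb_ca(path: str | Path, traj: Trajectory) -> None:
    """Write a minimal multi-MODEL PDB with one CA atom per residue."""
    with open(path, "w") as fh:
        for m, frame in enumerate(traj.coordinates, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (x, y, z) in enumerate(frame, start=1):
                fh.write(
                    f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb_ca(path: str | Path, frame_interval: float = 20.0) -> Trajectory:
    """Read CA atoms from a multi-MODEL PDB into a trajectory."""
    frames, current = [], []
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = []
            elif rec == "ATOM" and line[12:16].strip() == "CA":
                current.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            elif rec == "ENDMDL":
                frames.append(current)
    if not frames and current:
        frames = [current]
    return Trajectory(
        coordinates=np.array(frames, dtype=float), frame_interval=frame_interval
    )


# --------------------------------------------------------------------------
# reports and pipeline


@dataclass
class FitReport:
    """A serializable record of one fitting stage."""

    stage: str
    parameters: dict  # name -> {"value": float, "stderr": float | None}
    residual_norm: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "parameters": self.parameters,
            "residual_norm": self.residual_norm,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FitReport":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            stage=d["stage"],
            parameters=d["parameters"],
            residual_norm=d.get("residual_norm"),
            provenance=d.get("provenance", {}),
        )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunConfig:
    """Declarative description of a pipeline run."""

    stages: list  # list of {"stage": name, **params}
    seed: int = 0
    outdir: str | Path = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            stages=d.get("stages", []),
            seed=int(d.get("seed", 0)),
            outdir=d.get("outdir", "."),
        )


def _provenance(stage_cfg: dict, seed: int, inputs: list[str | Path]) -> dict:
    return {
        "config": {k: v for k, v in stage_cfg.items()},
        "package_version": __version__,
        "seed": seed,
        "input_hashes": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }


def run_pipeline(config: RunConfig) -> list[FitReport]:
    """Execute pipeline stages in order, returning one report per stage.

    Stage failure raises a stage-scoped error; reports from completed
    stages are already written under the output directory.  Identical
    config + seed gives identical reports (no timestamps are recorded).
    """
    from . import pipeline_stages

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: list[FitReport] = []
    for i, stage_cfg in enumerate(config.stages):
        stage_cfg = dict(stage_cfg)
        name = stage_cfg.pop("stage", None)
        fn = pipeline_stages.REGISTRY.get(name)
        if fn is None:
            raise ValueError(f"stage {i}: unknown stage {name!r}")
        try:
            report = fn(stage_cfg, seed=config.seed, outdir=outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {i} ({name}) failed: {exc}") from exc
        report.provenance.update(_provenance(stage_cfg, config.seed, []))
        report.to_json(outdir / f"{i:02d}_{name}.json")
        reports.append(report)
    return reports
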