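"""File formats and run configuration.

Contour stacks travel as JSON lines: a header record with the subject id
and acquisition metadata, then one record per (slice, frame) carrying the
contour's millimetre coordinates.  Subject and result tables are plain CSV.
Run configuration is YAML or JSON and, together with the master seed, fully
determines a run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import Contour
from .synthetic import (
    AcquisitionParams,
    CohortConfig,
    ContourStack,
    GroupDistributions,
    Normal,
    default_distributions,
)

__all__ = [
    "ContourFileError",
    "write_contour_stack",
    "read_contour_stack",
    "RunConfig",
    "load_config",
    "audit_percentage",
]


class ContourFileError(ValueError):
    """Malformed contour-stack file; message names the line and field."""


def write_contour_stack(stack: ContourStack, path) -> None:
    """Serialise a cine contour stack to a JSON-lines file."""
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "record": "header",
            "subject_id": stack.subject_id,
            "acquisition": dataclasses.asdict(stack.acquisition),
            "n_slices": stack.n_slices,
            "n_frames": stack.n_frames,
        }
        fh.write(json.dumps(header) + "\n")
        for s, frames in enumerate(stack.contours):
            for t, contour in enumerate(frames):
                rec = {
                    "record": "contour",
                    "slice": s,
                    "frame": t,
                    "x": np.round(contour.points[:, 0], 6).tolist(),
                    "y": np.round(contour.points[:, 1], 6).tolist(),
                }
                fh.write(json.dumps(rec) + "\n")


def read_contour_stack(path) -> ContourStack:
    """Read a JSON-lines contour stack, validating shape and completeness."""
    path = Path(path)
    header = None
    grid: dict[tuple[int, int], Contour] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ContourFileError(f"{path}:{lineno}: invalid JSON ({exc.msg})") from exc
            kind = rec.get("record")
            if kind == "header":
                if header is not None:
                    raise ContourFileError(f"{path}:{lineno}: duplicate header")
                header = rec
            elif kind == "contour":
                for key in ("slice", "frame", "x", "y"):
                    if key not in rec:
                        raise ContourFileError(f"{path}:{lineno}: missing field {key!r}")
                if len(rec["x"]) != len(rec["y"]):
                    raise ContourFileError(f"{path}:{lineno}: x/y length mismatch")
                pts = np.column_stack([rec["x"], rec["y"]])
                grid[(int(rec["slice"]), int(rec["frame"]))] = Contour(pts)
            else:
                raise ContourFileError(f"{path}:{lineno}: unknown record type {kind!r}")
    if header is None:
        raise ContourFileError(f"{path}: missing header record")
    n_slices, n_frames = int(header["n_slices"]), int(header["n_frames"])
    contours = []
    for s in range(n_slices):
        frames = []
        for t in range(n_frames):
            if (s, t) not in grid:
                raise ContourFileError(f"{path}: missing contour for slice {s}, frame {t}")
            frames.append(grid[(s, t)])
        contours.append(frames)
    acq = AcquisitionParams(**header["acquisition"])
    return ContourStack(subject_id=header["subject_id"], acquisition=acq, contours=contours)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs besides the master seed."""

    group_sizes: dict = field(default_factory=dict)
    distribution_overrides: dict = field(default_factory=dict)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    outlier_k: float = 2.7
    bootstrap_reps: int = 1000
    bsa_method: str = "du_bois"
    healthy_cell_size: int = 100

    def cohort_config(self) -> CohortConfig:
        dists = default_distributions()
        for key, overrides in self.distribution_overrides.items():
            health, band = key.rsplit("_", 1)
            base = dists[(health, band)]
            updates = {}
            for name, value in overrides.items():
                if isinstance(value, dict):
                    updates[name] = Normal(**value)
                else:
                    updates[name] = value
            dists[(health, band)] = dataclasses.replace(base, **updates)
        return CohortConfig(
            group_sizes=dict(self.group_sizes),
            distributions=dists,
            acquisition=self.acquisition,
        )


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    acq_raw = raw.pop("acquisition", {})
    acq = AcquisitionParams(**acq_raw) if acq_raw else AcquisitionParams()
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(acquisition=acq, **raw)


def audit_percentage(n_corrected: int, n_total: int, decimals: int = 2) -> float:
    """Percentage of contours needing manual correction, as reported.

    E.g. 636 corrected of 29,826 segmented → 2.13 (%).
    """
    if n_total <= 0 or n_corrected < 0 or n_corrected > n_total:
        raise ValueError("need 0 <= n_corrected <= n_total with n_total > 0")
    return round(100.0 * n_corrected / n_total, decimals)
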