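"""Configuration files, CSV schemas, manifests, and the reference generator.

All tabular interchange is plain CSV (header row, UTF-8, '.' decimal):

* ``season_rankings.csv``: run, season, fencer_id, rank, total_points, talent
* ``event_results.csv``: run, season, event, fencer_id, initial_position,
  final_placement, points
* ``transition_matrix.csv``: direction, from_bin, to_bin, probability, sd,
  pooled
* ``points_curve.csv``: position, normalized_points

``make_reference`` runs the simulator at a known talent strength and writes
these same files, so calibration can be exercised end-to-end without any
external dataset.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import RankBins, TransitionMatrix, normalized_points_curve, \
    transition_matrix
from .config import SimulationConfig
from .season import SimulationOutput, run_simulation

__all__ = [
    "RunManifest",
    "load_config",
    "save_config",
    "write_simulation_output",
    "load_reference_transition",
    "load_reference_curve",
    "make_reference",
]


@dataclass
class RunManifest:
    """Everything needed to reproduce a set of output files bit-exactly."""

    config: dict[str, Any]
    root_seed: Optional[int]
    n_runs: int
    version: str = __version__
    a_true: Optional[float] = None
    created: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc).isoformat()
    )
    files: list[str] = field(default_factory=list)

    def write(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n",
                              encoding="utf-8")

    @classmethod
    def read(cls, path: Path | str) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def load_config(path: Path | str) -> SimulationConfig:
    """Read a YAML (or JSON) configuration; an empty file gives the full
    default (Junior Men) setup. Unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(raw).__name__}")
    return SimulationConfig.from_dict(raw)


def save_config(config: SimulationConfig, path: Path | str) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False),
                          encoding="utf-8")


def write_simulation_output(output: SimulationOutput, out_dir: Path | str,
                            a_true: Optional[float] = None) -> RunManifest:
    """Write an entire simulation as the standard CSV set plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    rankings = output.rankings_frame()
    rankings.to_csv(out / "season_rankings.csv", index=False)
    files.append("season_rankings.csv")

    events = output.events_frame()
    events.to_csv(out / "event_results.csv", index=False)
    files.append("event_results.csv")

    tm = transition_matrix(output)
    tm.to_frame().to_csv(out / "transition_matrix.csv", index=False)
    files.append("transition_matrix.csv")

    curve = normalized_points_curve(output)
    pd.DataFrame({"position": np.arange(1, len(curve) + 1),
                  "normalized_points": curve}
                 ).to_csv(out / "points_curve.csv", index=False)
    files.append("points_curve.csv")

    manifest = RunManifest(config=output.config.to_dict(),
                           root_seed=output.root_seed,
                           n_runs=output.n_runs, a_true=a_true, files=files)
    manifest.write(out / "manifest.json")
    return manifest


def load_reference_transition(path: Path | str,
                              direction: str = "backward") -> TransitionMatrix:
    """Rebuild a ``TransitionMatrix`` from ``transition_matrix.csv``."""
    path = Path(path)
    if path.is_dir():
        path = path / "transition_matrix.csv"
    df = pd.read_csv(path)
    df = df[df["direction"] == direction]
    if df.empty:
        raise ValueError(f"no rows with direction {direction!r} in {path}")
    labels = list(dict.fromkeys(df["from_bin"]))
    k = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    mean = np.full((k, k), np.nan)
    sd = np.full((k, k), np.nan)
    pooled = np.full((k, k), np.nan)
    for _, row in df.iterrows():
        i, j = idx[row["from_bin"]], idx[row["to_bin"]]
        mean[i, j] = row["probability"]
        sd[i, j] = row["sd"]
        pooled[i, j] = row.get("pooled", np.nan)
    edges = tuple(RankBins.parse_label(lab)[1] for lab in labels[:-1])
    bins = RankBins(edges=tuple(int(e) for e in edges)) if edges else RankBins(edges=(1,))
    return TransitionMatrix(bins=bins, direction=direction, mean=mean, sd=sd,
                            pooled=pooled, counts=np.zeros((k, k)))


def load_reference_curve(path: Path | str) -> np.ndarray:
    path = Path(path)
    if path.is_dir():
        path = path / "points_curve.csv"
    df = pd.read_csv(path).sort_values("position")
    return df["normalized_points"].to_numpy()


def make_reference(config: SimulationConfig, a_true: float,
                   out_dir: Path | str, seed: Optional[int] = None,
                   n_runs: Optional[int] = None) -> RunManifest:
    """Generate reference data by running the simulator at ``a_true``.

    Writes the same CSV schemas the calibration reader consumes, standing in
    for an external standings dataset.
    """
    cfg = config.replace(talent_strength=float(a_true))
    output = run_simulation(cfg, seed=seed, n_runs=n_runs)
    return write_simulation_output(output, out_dir, a_true=float(a_true))
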