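"""File formats, pipeline configuration and provenance.

Formats are plain text throughout:

* recordings — long-format TSV (subject, group, channel, sample, value) with
  a TSV marker sidecar (subject, group, onset_sample, case) and a small JSON
  metadata file carrying the sampling rate and channel order;
* matrices — labeled square TSV (correlation or binary adjacency);
* BrainNet Viewer exports — standard ``.node`` (x y z color size label) and
  ``.edge`` (N×N matrix) text files for 3D rendering of a network.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .connectivity import CorrelationMatrix
from .graph_metrics import BinaryNetwork
from .synthetic_data import CASES, GROUPS, Recording, SimulationConfig

__all__ = [
    "PipelineConfig",
    "write_recordings",
    "read_recordings",
    "write_matrix",
    "read_matrix",
    "read_correlation",
    "read_network",
    "export_brainnet",
    "example_channel_coords",
    "write_provenance",
]

logger = logging.getLogger(__name__)


def _part(stem: Path, suffix: str) -> Path:
    return stem.parent / f"{stem.name}.{suffix}"


def write_recordings(recordings: Sequence[Recording], stem: str | Path) -> None:
    """Write a cohort as ``<stem>.data.tsv``, ``<stem>.markers.tsv`` and
    ``<stem>.meta.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    marker_rows = []
    meta = {"fs": None, "channels": {}}
    for rec in recordings:
        n = rec.n_samples
        for ci, channel in enumerate(rec.channels):
            frames.append(
                pd.DataFrame(
                    {
                        "subject": rec.subject_id,
                        "group": rec.group,
                        "channel": channel,
                        "sample": np.arange(n),
                        "value": rec.data[ci],
                    }
                )
            )
        for onset, case in rec.markers:
            marker_rows.append(
                {
                    "subject": rec.subject_id,
                    "group": rec.group,
                    "onset_sample": onset,
                    "case": case,
                }
            )
        meta["fs"] = rec.fs
        meta["channels"][f"{rec.subject_id}|{rec.group}"] = list(rec.channels)
    pd.concat(frames, ignore_index=True).to_csv(
        _part(stem, "data.tsv"), sep="\t", index=False, float_format="%.17g"
    )
    pd.DataFrame(marker_rows).to_csv(
        _part(stem, "markers.tsv"), sep="\t", index=False
    )
    _part(stem, "meta.json").write_text(json.dumps(meta, indent=1))


def read_recordings(stem: str | Path) -> list[Recording]:
    """Read a cohort written by :func:`write_recordings`.

    Schema violations are reported with row numbers; markers that do not fit
    inside their recording are rejected with a warning.
    """
    stem = Path(stem)
    data = pd.read_csv(_part(stem, "data.tsv"), sep="\t")
    markers = pd.read_csv(_part(stem, "markers.tsv"), sep="\t")
    meta = json.loads(_part(stem, "meta.json").read_text())
    required = {"subject", "group", "channel", "sample", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"data file lacks columns {required - set(data.columns)}")
    bad_case = ~markers["case"].isin(CASES)
    if bad_case.any():
        rows = (markers.index[bad_case] + 2).tolist()  # +2: header + 0-base
        raise ValueError(f"unknown case labels in marker rows {rows}")
    bad_group = ~data["group"].isin(GROUPS)
    if bad_group.any():
        raise ValueError(
            f"unknown group label at data row {int(data.index[bad_group][0]) + 2}"
        )
    recordings = []
    for (subject, group), sub in data.groupby(["subject", "group"], sort=False):
        channels = meta["channels"][f"{subject}|{group}"]
        n = int(sub["sample"].max()) + 1
        mat = np.full((len(channels), n), np.nan)
        for ci, channel in enumerate(channels):
            chan = sub[sub["channel"] == channel]
            idx = chan["sample"].to_numpy()
            if not np.array_equal(np.sort(idx), np.arange(len(idx))) or len(idx) != n:
                first = int(chan.index[0]) + 2
                raise ValueError(
                    f"non-contiguous sample indices for {subject}/{channel} "
                    f"(data rows starting near {first})"
                )
            if not np.all(np.diff(idx) > 0):
                raise ValueError(
                    f"non-monotone sample indices for {subject}/{channel}"
                )
            mat[ci] = chan["value"].to_numpy()
        sub_markers = markers[
            (markers["subject"] == subject) & (markers["group"] == group)
        ]
        kept = []
        for _, row in sub_markers.iterrows():
            onset = int(row["onset_sample"])
            if onset < 0 or onset >= n:
                logger.warning(
                    "rejecting marker at sample %d for %s/%s: beyond recording end",
                    onset, subject, group,
                )
                continue
            kept.append((onset, str(row["case"])))
        recordings.append(
            Recording(
                subject_id=str(subject),
                group=str(group),
                channels=list(channels),
                data=mat,
                fs=float(meta["fs"]),
                markers=kept,
            )
        )
    return recordings


def write_matrix(matrix: CorrelationMatrix | BinaryNetwork, path: str | Path) -> None:
    """Labeled square TSV; binary adjacencies are written as integers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(matrix, BinaryNetwork):
        values, labels = matrix.adjacency.astype(int), matrix.labels
        fmt = "%d"
    else:
        values, labels = matrix.values, matrix.labels
        fmt = "%.17g"
    pd.DataFrame(values, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format=fmt, index_label="label"
    )


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a labeled square TSV back as (labels, values)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in frame.columns]
    if list(map(str, frame.index)) != labels:
        raise ValueError("row and column labels differ: not a square matrix file")
    return labels, frame.to_numpy()


def read_correlation(
    path: str | Path, subject_id: str = "", case: str = "", group: str = ""
) -> CorrelationMatrix:
    labels, values = read_matrix(path)
    return CorrelationMatrix(
        labels=labels,
        values=values,
        n_samples_used=0,
        subject_id=subject_id,
        case=case,
        group=group,
    )


def read_network(path: str | Path, threshold: float | None = None) -> BinaryNetwork:
    labels, values = read_matrix(path)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("file does not contain a binary adjacency matrix")
    return BinaryNetwork(
        labels=labels, adjacency=values.astype(np.int8), threshold=threshold
    )


def example_channel_coords(n_channels: int = 24) -> pd.DataFrame:
    """A packaged synthetic 24-channel layout: two 4 × 3 bilateral frontal
    patches on a flattened MNI-like grid (x lateral, y anterior, z constant).

    Stand-in coordinates for demonstrations and exports when no digitizer
    data are available; not a registration of any real optode montage.
    """
    rows = []
    half = n_channels // 2
    for i in range(n_channels):
        side = -1 if i < half else 1
        j = i % half
        rows.append(
            {
                "label": f"CH{i + 1:02d}",
                "x": side * (20 + 12 * (j % 3)),
                "y": 40 + 12 * (j // 3),
                "z": 40,
            }
        )
    return pd.DataFrame(rows)


def export_brainnet(
    net: BinaryNetwork,
    coords: pd.DataFrame,
    path_stem: str | Path,
    node_color: int = 1,
) -> tuple[Path, Path]:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files for ``net``.

    ``coords`` must have one row per node with columns label, x, y, z (order
    is matched on labels).  Node size encodes degree.
    """
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    coords = coords.set_index(coords["label"].astype(str))
    missing = [lab for lab in net.labels if lab not in coords.index]
    if missing or len(coords) != len(net.labels):
        raise ValueError(
            f"coordinate table does not match node labels (missing {missing})"
        )
    degrees = net.degrees()
    node_path = stem.with_suffix(".node")
    edge_path = stem.with_suffix(".edge")
    with open(node_path, "w") as fh:
        for lab, k in zip(net.labels, degrees):
            row = coords.loc[lab]
            fh.write(
                f"{row['x']:g}\t{row['y']:g}\t{row['z']:g}\t"
                f"{node_color}\t{max(int(k), 1)}\t{lab}\n"
            )
    np.savetxt(edge_path, net.adjacency.astype(int), fmt="%d", delimiter="\t")
    return node_path, edge_path


@dataclass
class PipelineConfig:
    """Serializable end-to-end pipeline configuration."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    case: str = "win-win"
    filter_low: float = 0.01
    filter_high: float = 0.3
    t_min: float = 0.275
    t_max: float = 0.625
    t_step: float = 0.025
    null_n: int = 100
    seed: int = 0
    output_dir: str = "nirsnet_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["group_coupling"] = dict(d["simulation"]["group_coupling"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if not isinstance(sim, SimulationConfig):
            for key in ("community_partition", "channel_noise_range"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            if "noise_bands" in sim:
                sim["noise_bands"] = tuple(tuple(b) for b in sim["noise_bands"])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def write_provenance(out_dir: str | Path, config: PipelineConfig, seed: int) -> Path:
    """Record the exact configuration, seed and package version of a run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "provenance.json"
    path.write_text(
        json.dumps(
            {"config": config.to_dict(), "seed": seed, "version": __version__},
            indent=1,
        )
    )
    return path
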