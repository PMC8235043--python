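"""File formats and scenario configuration.

Formats (all plain text):

* gaze CSV:      ``timestamp_ms,x_px,y_px,valid``
* fixation CSV:  ``start_ms,end_ms,x_px,y_px``
* events JSONL:  one event per line with keys
                 ``aoi,label,start_ms,end_ms,probability,source``
* AOI tracks JSON: ``{"video": {...}, "tracks": [{"aoi", "kind",
                 "keyframes": [{"frame", "vertices"}]}]}``

Writers emit a provenance header (a ``#`` comment line for CSV, a
``{"_provenance": ...}`` first line for JSONL) which readers skip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .core import AOITrack, AttentionEvent, FixationEvent, GazeSample, Region, VideoMeta
from .ic import LabelMergeMap

__all__ = [
    "ScenarioConfig",
    "read_gaze",
    "write_gaze",
    "read_fixations",
    "write_fixations",
    "read_events",
    "write_events",
    "read_tracks",
    "write_tracks",
    "load_scenario_config",
    "list_scenarios",
    "merge_map_for",
]

PathLike = Union[str, Path]

_GAZE_COLUMNS = ["timestamp_ms", "x_px", "y_px", "valid"]
_FIX_COLUMNS = ["start_ms", "end_ms", "x_px", "y_px"]


def _provenance(extra: Optional[Mapping[str, object]] = None) -> Dict[str, object]:
    from . import __version__

    info: Dict[str, object] = {"tool": "gazeaoi", "version": __version__}
    if extra:
        info.update(extra)
        digest = hashlib.sha256(json.dumps(extra, sort_keys=True, default=str).encode())
        info["config_hash"] = digest.hexdigest()[:12]
    return info


# ---------------------------------------------------------------------------
# gaze & fixation CSV


def write_gaze(path: PathLike, samples: Sequence[GazeSample],
               extra: Optional[Mapping[str, object]] = None) -> None:
    df = pd.DataFrame(
        [(s.timestamp, s.x, s.y, int(s.valid)) for s in samples], columns=_GAZE_COLUMNS
    )
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(_provenance(extra))}\n")
        df.to_csv(fh, index=False)


def read_gaze(path: PathLike) -> List[GazeSample]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing gaze columns {missing}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            samples.append(
                GazeSample(float(row.timestamp_ms), float(row.x_px), float(row.y_px),
                           bool(int(row.valid)))
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed gaze row at line {i + 2}: {exc}") from exc
    return samples


def write_fixations(path: PathLike, fixations: Sequence[FixationEvent],
                    extra: Optional[Mapping[str, object]] = None) -> None:
    df = pd.DataFrame(
        [(f.start, f.end, f.x, f.y) for f in fixations], columns=_FIX_COLUMNS
    )
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(_provenance(extra))}\n")
        df.to_csv(fh, index=False)


def read_fixations(path: PathLike) -> List[FixationEvent]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing fixation columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(FixationEvent(float(row.start_ms), float(row.end_ms),
                                     float(row.x_px), float(row.y_px)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed fixation row at line {i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# events JSONL


def write_events(path: PathLike, events: Sequence[AttentionEvent],
                 extra: Optional[Mapping[str, object]] = None) -> None:
    """Write events as JSON Lines, sorted by (start, end, aoi)."""
    ordered = sorted(events, key=lambda e: (e.start, e.end, e.aoi or ""))
    with open(path, "w") as fh:
        fh.write(json.dumps({"_provenance": _provenance(extra)}) + "\n")
        for e in ordered:
            fh.write(
                json.dumps(
                    {
                        "aoi": e.aoi,
                        "label": e.label,
                        "start_ms": e.start,
                        "end_ms": e.end,
                        "probability": e.probability,
                        "source": e.source,
                    }
                )
                + "\n"
            )


def read_events(path: PathLike) -> List[AttentionEvent]:
    events: List[AttentionEvent] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "_provenance" in obj:
                continue
            if obj["end_ms"] <= obj["start_ms"]:
                raise ValueError(
                    f"{path}:{lineno}: rejected event with end_ms <= start_ms "
                    f"({obj['end_ms']} <= {obj['start_ms']})"
                )
            events.append(
                AttentionEvent(
                    aoi=obj.get("aoi"),
                    label=obj["label"],
                    start=float(obj["start_ms"]),
                    end=float(obj["end_ms"]),
                    probability=float(obj.get("probability", 1.0)),
                    source=obj.get("source", "ground_truth"),
                )
            )
    return events


def partition_events(events: Sequence[AttentionEvent]) -> Dict[Optional[str], List[AttentionEvent]]:
    """Group events per AOI, each group time-ordered."""
    by_aoi: Dict[Optional[str], List[AttentionEvent]] = {}
    for e in events:
        by_aoi.setdefault(e.aoi, []).append(e)
    for group in by_aoi.values():
        group.sort(key=lambda e: e.start)
    return by_aoi


# ---------------------------------------------------------------------------
# AOI tracks JSON


def write_tracks(path: PathLike, meta: VideoMeta, tracks: Sequence[AOITrack]) -> None:
    doc = {
        "video": {
            "width": meta.width,
            "height": meta.height,
            "fps": meta.fps,
            "n_frames": meta.n_frames,
        },
        "tracks": [
            {
                "aoi": t.aoi_name,
                "kind": t.keyframes[0][1].kind if t.keyframes else "rectangle",
                "keyframes": [
                    {"frame": f, "vertices": [list(v) for v in r.vertices]}
                    for f, r in t.keyframes
                ],
            }
            for t in tracks
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_tracks(path: PathLike) -> Tuple[VideoMeta, List[AOITrack]]:
    doc = json.loads(Path(path).read_text())
    v = doc["video"]
    meta = VideoMeta(int(v["width"]), int(v["height"]), float(v["fps"]), int(v["n_frames"]))
    tracks = [
        AOITrack(
            aoi_name=t["aoi"],
            keyframes=tuple(
                (int(kf["frame"]), Region(t["kind"], tuple(tuple(p) for p in kf["vertices"])))
                for kf in t["keyframes"]
            ),
        )
        for t in doc["tracks"]
    ]
    return meta, tracks


# ---------------------------------------------------------------------------
# scenario configuration


@dataclass(frozen=True)
class ScenarioConfig:
    """Label-to-AOI mapping for one scenario and one method (IC or OD)."""

    scenario: str
    method: str
    label_to_aoi: Mapping[str, str]
    unmapped_aois: Tuple[str, ...]
    aois: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.method not in ("IC", "OD"):
            raise ValueError("method must be 'IC' or 'OD'")

    @property
    def label_groups(self) -> Dict[str, List[str]]:
        """AOI -> list of labels that map to it."""
        groups: Dict[str, List[str]] = {}
        for label, aoi in self.label_to_aoi.items():
            groups.setdefault(aoi, []).append(label)
        return groups


def _load_catalog(path: Optional[PathLike] = None) -> Dict:
    if path is not None:
        text = Path(path).read_text()
    else:
        text = resources.files("gazeaoi.data").joinpath("scenarios.yaml").read_text()
    return yaml.safe_load(text)["scenarios"]


def list_scenarios(path: Optional[PathLike] = None) -> List[str]:
    return sorted(_load_catalog(path))


def load_scenario_config(
    name: str, method: str, path: Optional[PathLike] = None
) -> ScenarioConfig:
    """Load a packaged (or external) scenario's label-to-AOI mapping.

    Raises a ``KeyError`` listing the available scenario names when
    ``name`` is unknown.
    """
    catalog = _load_catalog(path)
    if name not in catalog:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(catalog))}"
        )
    method = method.upper()
    entry = catalog[name]
    section = entry[method.lower()]
    label_to_aoi = dict(section.get("labels") or {})
    aois = tuple(entry["aois"])
    for aoi in label_to_aoi.values():
        if aoi not in aois:
            raise ValueError(f"{name}/{method}: label maps to unknown AOI {aoi!r}")
    return ScenarioConfig(
        scenario=name,
        method=method,
        label_to_aoi=label_to_aoi,
        unmapped_aois=tuple(section.get("unmapped") or ()),
        aois=aois,
    )


def merge_map_for(config: ScenarioConfig) -> LabelMergeMap:
    """Label merge table for the IC method: all labels of one AOI merge into
    the group's first label."""
    return LabelMergeMap.from_groups(list(config.label_groups.values()))
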