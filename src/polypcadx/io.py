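"""Readers and writers: PNG images, COCO-style annotations, study tables,
session logs and metric reports.

Conventions: bounding boxes are COCO ``[x, y, w, h]`` (0-based, half-open);
CSV is UTF-8, comma-separated, header required; session logs are JSON lines
(one record per capture).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .dxstats import PolypRecord
from .localization import BoundingBox

RECORD_COLUMNS = ["polyp_id", "patient_id", "size_mm", "segment", "morphology",
                  "endoscopist_dx", "endoscopist_confidence",
                  "cadx_dx", "cadx_tier", "histology"]


def write_png(path: str, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path, format="PNG")


def read_png(path: str) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_coco(path: str, coco: Mapping) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(coco, fh, indent=1)


def read_coco(path: str) -> dict:
    with open(path, encoding="utf-8") as fh:
        coco = json.load(fh)
    for ann in coco.get("annotations", []):
        x, y, w, h = ann["bbox"]
        BoundingBox(int(x), int(y), int(w), int(h))  # validate convention
    return coco


def box_from_coco(bbox: Sequence[float]) -> BoundingBox:
    x, y, w, h = bbox
    return BoundingBox(int(x), int(y), int(w), int(h))


def write_table(path: str, rows: Iterable[Mapping]) -> None:
    pd.DataFrame(list(rows)).to_csv(path, index=False, encoding="utf-8")


def read_records(path: str) -> list[PolypRecord]:
    """Read the study table (one row per polyp; empty cells mean 'absent',
    e.g. a CADx failure has no cadx_dx)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study table is missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(PolypRecord(
            polyp_id=d["polyp_id"], patient_id=d["patient_id"],
            size_mm=int(d["size_mm"]), segment=d["segment"],
            morphology=d["morphology"],
            endoscopist_dx=d["endoscopist_dx"] or None,
            endoscopist_confidence=d["endoscopist_confidence"] or None,
            cadx_dx=d["cadx_dx"] or None, cadx_tier=d["cadx_tier"] or None,
            histology=d["histology"]))
    return out


def write_records(path: str, records: Iterable[PolypRecord]) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        rows.append({c: ("" if d[c] is None else d[c]) for c in RECORD_COLUMNS})
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False, encoding="utf-8")


def append_session_log(fh, polyp_id: str, capture_index: int, outcome) -> None:
    """Append one capture record to an open JSON-lines log."""
    rec = {"polyp_id": polyp_id, "capture": capture_index,
           "signal": outcome.signal, "reason": outcome.reason,
           "scores": None if outcome.scores is None else dict(outcome.scores.scores)}
    fh.write(json.dumps(rec) + "\n")


def provenance(config: Mapping, seed: int | None) -> dict:
    """Config hash + seed block embedded in every written artifact."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"config_sha256": hashlib.sha256(blob).hexdigest(), "seed": seed}
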