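"""Domain types and I/O for paired-modality coronary pullback data.

A *frame* is one annotated cross-section of a coronary artery: lumen and
vessel (EEM / outer-wall) areas plus a circumferential map of tissue flags.
Frames from one (subject, vessel, modality) pullback form a *segment of
interest*; NIRS-IVUS and CTA frames annotated at matched longitudinal
positions form a *matched dataset*, the input to every downstream analysis.

Coordinate conventions
----------------------
* Longitudinal positions are millimetres from the proximal end of the
  segment of interest, increasing proximal -> distal (pullback direction).
  Positions are authoritative; spacing may be non-uniform.
* The circumference is discretised into a fixed number of angular bins
  (default 360 bins of 1 degree), bin 0 at a fixed reference angle.
  Circumferential registration between modalities is assumed given.
* Tissue flags are multi-label: a bin may simultaneously carry LIPID (from
  the NIRS chemogram) and CA (from the IVUS calcium arc); lipid and calcium
  burden indices are computed on independent masks.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Tissue",
    "Modality",
    "Frame",
    "SegmentRecord",
    "MatchedDataset",
    "SpreadoutPlot",
    "Violation",
    "validate_dataset",
    "read_frame_table",
    "write_frame_table",
    "read_frame_json",
    "write_frame_json",
    "frames_to_dataframe",
    "dataframe_to_frames",
    "build_matched_dataset",
    "encode_arcs",
    "decode_arcs",
]

#: Default angular resolution: 360 bins of 1 degree.
DEFAULT_N_BINS = 360

#: Tolerance (mm^2) for the "sum of tissue areas <= plaque area" invariant.
TISSUE_AREA_TOL = 1e-6


class Tissue(enum.IntFlag):
    """Multi-label tissue flags carried per angular bin."""

    NONE = 0
    LIPID = 1
    CA = 2
    FT = 4
    FF = 8


class Modality(str, enum.Enum):
    NIRS_IVUS = "NIRS_IVUS"
    CTA = "CTA"


@dataclass
class Frame:
    """One matched cross-section with areas and circumferential tissue bins.

    Parameters
    ----------
    subject_id, vessel_id
        Opaque identifiers.
    modality
        Imaging modality the annotation comes from.
    position
        Longitudinal distance from the proximal end of the segment, mm.
    lumen_area, vessel_area
        Cross-sectional areas in mm^2; ``vessel_area`` is the EEM area on
        IVUS and the outer vessel-wall area on CTA.
    tissue_bins
        uint8 vector of :class:`Tissue` bitmasks, one per angular bin.
    tissue_areas
        Optional per-tissue areas in mm^2 (CTA Hounsfield-unit based
        composition; keys like ``"CA"``, ``"NC"``, ``"FT"``, ``"FF"``).
    """

    subject_id: str
    vessel_id: str
    modality: Modality
    position: float
    lumen_area: float
    vessel_area: float
    tissue_bins: np.ndarray = field(
        default_factory=lambda: np.zeros(DEFAULT_N_BINS, dtype=np.uint8)
    )
    tissue_areas: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.tissue_bins = np.asarray(self.tissue_bins, dtype=np.uint8)

    @property
    def plaque_area(self) -> float:
        """Plaque (atheroma) area: vessel minus lumen, mm^2."""
        return self.vessel_area - self.lumen_area

    @property
    def plaque_burden(self) -> float:
        """Plaque burden, % of vessel area occupied by plaque."""
        return 100.0 * self.plaque_area / self.vessel_area

    def key(self) -> tuple[str, str, str, float]:
        return (self.subject_id, self.vessel_id, self.modality.value, self.position)


@dataclass
class SegmentRecord:
    """Ordered frames of one (subject, vessel, modality) segment of interest."""

    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("SegmentRecord requires at least one frame")

    @property
    def subject_id(self) -> str:
        return self.frames[0].subject_id

    @property
    def vessel_id(self) -> str:
        return self.frames[0].vessel_id

    @property
    def modality(self) -> Modality:
        return self.frames[0].modality

    @property
    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.frames], dtype=float)

    @property
    def lumen_areas(self) -> np.ndarray:
        return np.array([f.lumen_area for f in self.frames], dtype=float)

    @property
    def vessel_areas(self) -> np.ndarray:
        return np.array([f.vessel_area for f in self.frames], dtype=float)

    @property
    def plaque_burdens(self) -> np.ndarray:
        return 100.0 * (1.0 - self.lumen_areas / self.vessel_areas)

    @property
    def length(self) -> float:
        """Segment length, mm (last position minus first)."""
        pos = self.positions
        return float(pos[-1] - pos[0])

    @property
    def n_bins(self) -> int:
        return len(self.frames[0].tissue_bins)

    def subsegment(self, start: int, end: int) -> "SegmentRecord":
        """Frames ``start..end`` inclusive as a new record."""
        return SegmentRecord(self.frames[start : end + 1])

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SpreadoutPlot:
    """Angular-bin x longitudinal-frame tissue matrix.

    ``grid[i, j]`` is the :class:`Tissue` bitmask of angular bin ``i`` in
    frame ``j``; ``positions[j]`` is frame ``j``'s longitudinal position in
    mm. The X-axis of the rendered plot is longitudinal, the Y-axis
    circumferential.
    """

    grid: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("spread-out grid must be 2-D (bins x frames)")
        if self.grid.shape[1] != self.positions.size:
            raise ValueError("column count must equal the number of positions")

    @property
    def n_bins(self) -> int:
        return self.grid.shape[0]

    @property
    def n_frames(self) -> int:
        return self.grid.shape[1]

    @property
    def length(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass
class MatchedDataset:
    """Paired NIRS-IVUS / CTA frames, grouped into segments of interest."""

    pairs: list[tuple[Frame, Frame]]

    def __post_init__(self) -> None:
        for nirs, cta in self.pairs:
            if nirs.modality is not Modality.NIRS_IVUS or cta.modality is not Modality.CTA:
                raise ValueError("each pair must be (NIRS_IVUS frame, CTA frame)")

    def segment_keys(self) -> list[tuple[str, str]]:
        seen: dict[tuple[str, str], None] = {}
        for nirs, _ in self.pairs:
            seen.setdefault((nirs.subject_id, nirs.vessel_id), None)
        return list(seen)

    def segments(self) -> Iterator[tuple[tuple[str, str], SegmentRecord, SegmentRecord]]:
        """Yield ((subject, vessel), nirs_segment, cta_segment) per segment."""
        groups: dict[tuple[str, str], list[tuple[Frame, Frame]]] = {}
        for nirs, cta in self.pairs:
            groups.setdefault((nirs.subject_id, nirs.vessel_id), []).append((nirs, cta))
        for key, pair_list in groups.items():
            pair_list = sorted(pair_list, key=lambda p: p[0].position)
            yield key, SegmentRecord([p[0] for p in pair_list]), SegmentRecord(
                [p[1] for p in pair_list]
            )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    frame_key: tuple | None
    field: str
    rule: str
    message: str


def _validate_frame(frame: Frame, n_bins: int | None) -> list[Violation]:
    out: list[Violation] = []
    key = frame.key()
    if frame.lumen_area < 0:
        out.append(Violation(key, "lumen_area", "nonnegative", "lumen_area < 0"))
    if frame.vessel_area < frame.lumen_area:
        out.append(
            Violation(
                key,
                "vessel_area",
                "vessel_ge_lumen",
                f"vessel_area {frame.vessel_area} < lumen_area {frame.lumen_area}",
            )
        )
    if n_bins is not None and len(frame.tissue_bins) != n_bins:
        out.append(
            Violation(
                key,
                "tissue_bins",
                "uniform_bin_resolution",
                f"{len(frame.tissue_bins)} bins, expected {n_bins}",
            )
        )
    if frame.tissue_areas:
        total = sum(frame.tissue_areas.values())
        if total > frame.plaque_area + TISSUE_AREA_TOL:
            out.append(
                Violation(
                    key,
                    "tissue_areas",
                    "tissue_le_plaque",
                    f"sum of tissue areas {total:.4f} exceeds plaque area "
                    f"{frame.plaque_area:.4f}",
                )
            )
    return out


def validate_dataset(dataset: MatchedDataset) -> list[Violation]:
    """Check every type invariant; empty list means the dataset is valid.

    Pure reporting: the dataset is never mutated and repeated calls return
    identical reports.
    """
    out: list[Violation] = []
    n_bins = len(dataset.pairs[0][0].tissue_bins) if dataset.pairs else None
    for nirs, cta in dataset.pairs:
        out.extend(_validate_frame(nirs, n_bins))
        out.extend(_validate_frame(cta, n_bins))
        if (nirs.subject_id, nirs.vessel_id) != (cta.subject_id, cta.vessel_id):
            out.append(
                Violation(
                    nirs.key(), "vessel_id", "pair_same_vessel",
                    "paired frames belong to different vessels",
                )
            )
    for _, nirs_seg, cta_seg in dataset.segments():
        for seg in (nirs_seg, cta_seg):
            pos = seg.positions
            if np.any(np.diff(pos) <= 0):
                out.append(
                    Violation(
                        seg.frames[0].key(), "position", "strictly_increasing",
                        f"positions not strictly increasing in segment "
                        f"({seg.subject_id}, {seg.vessel_id}, {seg.modality.value})",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Arc run-length encoding for the CSV frame table
# ---------------------------------------------------------------------------

def encode_arcs(mask: np.ndarray, n_bins: int | None = None) -> str:
    """Encode a boolean bin mask as semicolon-separated "start:stop" degree
    ranges (half-open, [start, stop))."""
    mask = np.asarray(mask, dtype=bool)
    n = n_bins or mask.size
    deg_per_bin = 360.0 / n
    runs = []
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    stops = np.flatnonzero(padded[:-1] & ~padded[1:])
    for a, b in zip(starts, stops):
        lo, hi = a * deg_per_bin, b * deg_per_bin
        runs.append(f"{lo:g}:{hi:g}")
    return ";".join(runs)


def decode_arcs(text: str, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Inverse of :func:`encode_arcs`."""
    mask = np.zeros(n_bins, dtype=bool)
    if not text or (isinstance(text, float) and np.isnan(text)):
        return mask
    deg_per_bin = 360.0 / n_bins
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        lo_s, hi_s = token.split(":")
        lo = int(round(float(lo_s) / deg_per_bin))
        hi = int(round(float(hi_s) / deg_per_bin))
        mask[lo:hi] = True
    return mask


# ---------------------------------------------------------------------------
# Frame-table CSV / JSON
# ---------------------------------------------------------------------------

_ARC_COLUMNS = {
    "lipid_bins": Tissue.LIPID,
    "ca_bins": Tissue.CA,
    "ft_bins": Tissue.FT,
    "ff_bins": Tissue.FF,
}
_AREA_COLUMNS = {
    "nc_area_mm2": "NC",
    "lipid_area_mm2": "LIPID",
    "ca_area_mm2": "CA",
    "ft_area_mm2": "FT",
    "ff_area_mm2": "FF",
}


def frames_to_dataframe(frames: Iterable[Frame]) -> pd.DataFrame:
    rows = []
    for f in frames:
        row: dict[str, object] = {
            "subject_id": f.subject_id,
            "vessel_id": f.vessel_id,
            "modality": f.modality.value,
            "position_mm": f.position,
            "lumen_area_mm2": f.lumen_area,
            "vessel_area_mm2": f.vessel_area,
        }
        n = len(f.tissue_bins)
        for col, flag in _ARC_COLUMNS.items():
            row[col] = encode_arcs((f.tissue_bins & int(flag)) > 0, n)
        if f.tissue_areas:
            for col, tissue in _AREA_COLUMNS.items():
                if tissue in f.tissue_areas:
                    row[col] = f.tissue_areas[tissue]
        rows.append(row)
    return pd.DataFrame(rows)


def dataframe_to_frames(df: pd.DataFrame, n_bins: int = DEFAULT_N_BINS) -> list[Frame]:
    frames = []
    for rec in df.to_dict("records"):
        bins = np.zeros(n_bins, dtype=np.uint8)
        for col, flag in _ARC_COLUMNS.items():
            if col in rec and not pd.isna(rec[col]):
                bins[decode_arcs(rec[col], n_bins)] |= int(flag)
        areas = {
            tissue: float(rec[col])
            for col, tissue in _AREA_COLUMNS.items()
            if col in rec and not pd.isna(rec.get(col))
        }
        frames.append(
            Frame(
                subject_id=str(rec["subject_id"]),
                vessel_id=str(rec["vessel_id"]),
                modality=Modality(rec["modality"]),
                position=float(rec["position_mm"]),
                lumen_area=float(rec["lumen_area_mm2"]),
                vessel_area=float(rec["vessel_area_mm2"]),
                tissue_bins=bins,
                tissue_areas=areas or None,
            )
        )
    return frames


def write_frame_table(frames: Iterable[Frame], path: str | Path) -> None:
    """Write the canonical UTF-8 CSV frame table (header row mandatory).

    Floats are written with ``repr`` precision so that a read/write
    round-trip reproduces the table bit-identically.
    """
    df = frames_to_dataframe(frames)
    df.to_csv(path, index=False, encoding="utf-8")


def read_frame_table(path: str | Path, n_bins: int = DEFAULT_N_BINS) -> list[Frame]:
    df = pd.read_csv(
        path,
        encoding="utf-8",
        dtype={"subject_id": str, "vessel_id": str},
        float_precision="round_trip",
    )
    return dataframe_to_frames(df, n_bins=n_bins)


def _frame_to_json_obj(f: Frame) -> dict:
    n = len(f.tissue_bins)
    obj: dict[str, object] = {
        "position_mm": f.position,
        "lumen_area_mm2": f.lumen_area,
        "vessel_area_mm2": f.vessel_area,
        "arcs": {
            name: encode_arcs((f.tissue_bins & int(flag)) > 0, n)
            for name, flag in _ARC_COLUMNS.items()
        },
    }
    if f.tissue_areas:
        obj["tissue_areas_mm2"] = f.tissue_areas
    return obj


def write_frame_json(frames: Iterable[Frame], path: str | Path,
                     n_bins: int = DEFAULT_N_BINS) -> None:
    """Nested per-segment JSON mirror of the frame-table schema."""
    segments: dict[tuple[str, str, str], list[Frame]] = {}
    for f in frames:
        segments.setdefault((f.subject_id, f.vessel_id, f.modality.value), []).append(f)
    doc = {
        "n_bins": n_bins,
        "segments": [
            {
                "subject_id": s,
                "vessel_id": v,
                "modality": m,
                "frames": [_frame_to_json_obj(f) for f in sorted(fs, key=lambda f: f.position)],
            }
            for (s, v, m), fs in segments.items()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_frame_json(path: str | Path) -> list[Frame]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    n_bins = int(doc.get("n_bins", DEFAULT_N_BINS))
    frames: list[Frame] = []
    for seg in doc["segments"]:
        for fo in seg["frames"]:
            bins = np.zeros(n_bins, dtype=np.uint8)
            for name, flag in _ARC_COLUMNS.items():
                bins[decode_arcs(fo["arcs"].get(name, ""), n_bins)] |= int(flag)
            frames.append(
                Frame(
                    subject_id=seg["subject_id"],
                    vessel_id=seg["vessel_id"],
                    modality=Modality(seg["modality"]),
                    position=float(fo["position_mm"]),
                    lumen_area=float(fo["lumen_area_mm2"]),
                    vessel_area=float(fo["vessel_area_mm2"]),
                    tissue_bins=bins,
                    tissue_areas=fo.get("tissue_areas_mm2"),
                )
            )
    return frames


def build_matched_dataset(frames: Sequence[Frame],
                          position_tol: float = 1e-6) -> MatchedDataset:
    """Pair NIRS-IVUS and CTA frames of equal (subject, vessel, position).

    The frames are assumed pre-matched (co-registration is upstream of this
    package); this merely zips the two modality tables and refuses frames
    without a counterpart.
    """
    by_key: dict[tuple[str, str], dict[str, list[Frame]]] = {}
    for f in frames:
        by_key.setdefault((f.subject_id, f.vessel_id), {}).setdefault(
            f.modality.value, []
        ).append(f)
    pairs: list[tuple[Frame, Frame]] = []
    for key, groups in by_key.items():
        nirs = sorted(groups.get(Modality.NIRS_IVUS.value, []), key=lambda f: f.position)
        cta = sorted(groups.get(Modality.CTA.value, []), key=lambda f: f.position)
        if len(nirs) != len(cta):
            raise ValueError(
                f"segment {key}: {len(nirs)} NIRS-IVUS frames vs {len(cta)} CTA frames"
            )
        for a, b in zip(nirs, cta):
            if abs(a.position - b.position) > position_tol:
                raise ValueError(
                    f"segment {key}: unmatched positions {a.position} vs {b.position}"
                )
            pairs.append((a, b))
    return MatchedDataset(pairs)
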