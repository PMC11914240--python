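"""Lesion detection and lesion-level metrics.

A lesion on NIRS-IVUS is a run of at least three consecutive end-diastolic
frames with plaque burden (PB) >= 40%. Two qualifying runs belong to the
same lesion unless separated by a sub-threshold gap of at least 5 mm; gaps
shorter than that are absorbed into a single merged lesion, and 1-2-frame
qualifying runs survive only by being merged into such a lesion. Lesions
detected on NIRS-IVUS are transferred pair-for-pair to the matched CTA
frames, where lesion metrics are recomputed regardless of CTA plaque
burden (the lesion definition is anchored on the reference modality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import MatchedDataset, SegmentRecord, Tissue
from .plaque_metrics import (
    build_spreadout,
    burden_index,
    max_lcbi_4mm,
    mean_ca_area,
    InsufficientDataError,
)

__all__ = [
    "LesionPolicy",
    "LesionSpan",
    "LesionGeometry",
    "Lesion",
    "detect_lesions",
    "lesion_geometry",
    "lesion_composition",
    "map_lesions_to_counterpart",
    "analyze_lesions",
]


@dataclass(frozen=True)
class LesionPolicy:
    """Configurable lesion detection / reference conventions.

    pb_threshold
        Plaque-burden cut-off (%) defining significant atheroma.
    min_frames
        Minimum consecutive qualifying frames for a stand-alone lesion.
    merge_gap_mm
        Sub-threshold gaps shorter than this merge adjacent runs
        (a gap of exactly this length separates).
    reference_flank_mm
        How far proximal/distal of the lesion to search for the
        least-diseased (minimum-PB) reference frame.
    reference_anchor
        "min_pb" (least-diseased flank frame, the default convention) —
        kept as an option hook for alternative anchors.
    """

    pb_threshold: float = 40.0
    min_frames: int = 3
    merge_gap_mm: float = 5.0
    reference_flank_mm: float = 5.0
    reference_anchor: str = "min_pb"


@dataclass(frozen=True)
class LesionSpan:
    """Inclusive frame-index span of one lesion within its segment."""

    start: int
    end: int

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


@dataclass(frozen=True)
class LesionGeometry:
    mla: float  # minimum lumen area, mm^2
    max_pb: float  # maximum plaque burden, %
    ref_lumen_area: float  # mm^2, nan when no reference frame exists
    ref_vessel_area: float  # mm^2, nan when no reference frame exists
    remodelling_index: float  # vessel area at MLA frame / ref vessel area
    one_sided_reference: bool
    reference_missing: bool


@dataclass
class Lesion:
    """A detected lesion with its derived metrics."""

    span: LesionSpan
    length: float  # mm
    geometry: LesionGeometry
    lcbi: float
    cabi: float
    max_lcbi_4mm: float
    mean_ca_area: float
    subject_id: str = ""
    vessel_id: str = ""
    modality: str = ""


def _qualifying_runs(pb: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs (inclusive index spans) of frames with PB >= threshold."""
    above = pb >= threshold
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    stops = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def detect_lesions(segment: SegmentRecord,
                   policy: LesionPolicy = LesionPolicy()) -> list[LesionSpan]:
    """Detect lesion spans from the segment's plaque-burden profile.

    Gap length is measured between the last frame position of the earlier
    run and the first frame position of the later run; runs merge iff the
    gap is strictly below ``merge_gap_mm``. A merged chain is a lesion iff
    it contains at least one run of ``min_frames`` consecutive qualifying
    frames; shorter runs survive only by being absorbed into such a chain.
    """
    pb = segment.plaque_burdens
    pos = segment.positions
    runs = _qualifying_runs(pb, policy.pb_threshold)
    if not runs:
        return []
    # chain adjacent runs whose separating gap is < merge_gap_mm
    chains: list[list[tuple[int, int]]] = [[runs[0]]]
    for run in runs[1:]:
        prev = chains[-1][-1]
        gap = pos[run[0]] - pos[prev[1]]
        if gap < policy.merge_gap_mm:
            chains[-1].append(run)
        else:
            chains.append([run])
    spans = []
    for chain in chains:
        if any(b - a + 1 >= policy.min_frames for a, b in chain):
            spans.append(LesionSpan(chain[0][0], chain[-1][1]))
    return spans


def lesion_geometry(span: LesionSpan, segment: SegmentRecord,
                    all_spans: list[LesionSpan] | None = None,
                    policy: LesionPolicy = LesionPolicy()) -> LesionGeometry:
    """MLA, max PB, reference areas and remodelling index for one lesion.

    The reference on each side is the least-diseased (minimum-PB) frame
    within ``reference_flank_mm`` of the lesion edge, excluding frames
    inside any detected lesion; the reference areas average the available
    sides and the remodelling index divides the vessel area at the MLA
    frame by the reference vessel area.
    """
    all_spans = all_spans if all_spans is not None else [span]
    pos = segment.positions
    lumen = segment.lumen_areas
    vessel = segment.vessel_areas
    pb = segment.plaque_burdens
    idx = span.indices()
    mla_local = int(np.argmin(lumen[idx]))
    mla_frame = idx[mla_local]
    mla = float(lumen[mla_frame])
    max_pb = float(np.max(pb[idx]))

    in_lesion = np.zeros(len(segment), dtype=bool)
    for s in all_spans:
        in_lesion[s.start : s.end + 1] = True

    def flank_reference(side: str) -> int | None:
        if side == "proximal":
            cand = np.flatnonzero(
                (pos >= pos[span.start] - policy.reference_flank_mm)
                & (pos < pos[span.start])
                & ~in_lesion
            )
        else:
            cand = np.flatnonzero(
                (pos > pos[span.end])
                & (pos <= pos[span.end] + policy.reference_flank_mm)
                & ~in_lesion
            )
        if cand.size == 0:
            return None
        return int(cand[np.argmin(pb[cand])])

    refs = [r for r in (flank_reference("proximal"), flank_reference("distal")) if r is not None]
    if refs:
        ref_lumen = float(np.mean(lumen[refs]))
        ref_vessel = float(np.mean(vessel[refs]))
        ri = float(vessel[mla_frame] / ref_vessel)
        return LesionGeometry(
            mla=mla, max_pb=max_pb,
            ref_lumen_area=ref_lumen, ref_vessel_area=ref_vessel,
            remodelling_index=ri,
            one_sided_reference=len(refs) == 1, reference_missing=False,
        )
    return LesionGeometry(
        mla=mla, max_pb=max_pb,
        ref_lumen_area=float("nan"), ref_vessel_area=float("nan"),
        remodelling_index=float("nan"),
        one_sided_reference=False, reference_missing=True,
    )


def lesion_composition(span: LesionSpan, segment: SegmentRecord,
                       ca_fallback_from_bins: bool = True
                       ) -> tuple[float, float, float, float]:
    """LCBI, CaBI, maxLCBI_4mm and mean Ca area of the lesion sub-segment."""
    sub = segment.subsegment(span.start, span.end)
    plot = build_spreadout(sub)
    lcbi = burden_index(plot, Tissue.LIPID)
    cabi = burden_index(plot, Tissue.CA)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mx = max_lcbi_4mm(plot)
    try:
        ca = mean_ca_area(sub, fallback_from_bins=ca_fallback_from_bins)
    except InsufficientDataError:
        ca = float("nan")
    return lcbi, cabi, mx, ca


def map_lesions_to_counterpart(spans: list[LesionSpan],
                               nirs_segment: SegmentRecord,
                               cta_segment: SegmentRecord) -> list[LesionSpan]:
    """Transfer NIRS-IVUS lesion spans to the paired CTA frames.

    Frames are paired index-for-index within the matched segment; the CTA
    lesion metrics are then computed on the transferred span regardless of
    CTA plaque burden.
    """
    n = len(cta_segment)
    for s in spans:
        if s.end >= n or s.start < 0:
            raise ValueError(
                f"lesion span {s.start}..{s.end} has no paired CTA frame "
                f"(CTA segment has {n} frames)"
            )
    return [LesionSpan(s.start, s.end) for s in spans]


def _build_lesion(span: LesionSpan, segment: SegmentRecord,
                  all_spans: list[LesionSpan], policy: LesionPolicy) -> Lesion:
    geo = lesion_geometry(span, segment, all_spans, policy)
    lcbi, cabi, mx, ca = lesion_composition(span, segment)
    pos = segment.positions
    return Lesion(
        span=span,
        length=float(pos[span.end] - pos[span.start]),
        geometry=geo,
        lcbi=lcbi, cabi=cabi, max_lcbi_4mm=mx, mean_ca_area=ca,
        subject_id=segment.subject_id,
        vessel_id=segment.vessel_id,
        modality=segment.modality.value,
    )


def analyze_lesions(dataset: MatchedDataset,
                    policy: LesionPolicy = LesionPolicy()
                    ) -> list[tuple[Lesion, Lesion]]:
    """Detect lesions on NIRS-IVUS, map to CTA, compute metrics on both.

    Returns one (nirs_lesion, cta_lesion) pair per detected lesion.
    """
    out: list[tuple[Lesion, Lesion]] = []
    for _, nirs_seg, cta_seg in dataset.segments():
        spans = detect_lesions(nirs_seg, policy)
        if not spans:
            continue
        cta_spans = map_lesions_to_counterpart(spans, nirs_seg, cta_seg)
        for s, cs in zip(spans, cta_spans):
            out.append(
                (
                    _build_lesion(s, nirs_seg, spans, policy),
                    _build_lesion(cs, cta_seg, cta_spans, policy),
                )
            )
    return out
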