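"""Segmentation masks over encoded images.

Every pixel of an encoded image is assigned one of seven classes: the five
basic SV component types (DEL, INS, INV, DUP, invDUP), wild-type reference
(REF, used inside ACT track regions that show no variant), and Background
(everything outside the tracks, e.g. the sketched structure and flanks).

``make_truth_mask`` builds the ground-truth mask for a simulated locus: each
implanted component paints a rectangle whose x-extent is its breakpoint span
and whose extent across the track (height in horizontal tracks, width in the
vertical insertion tracks) is ``round(AF * track_height)`` — the same
AF <-> pixel-span convention the decoder inverts.  ``oracle_segment`` is the
deterministic stand-in for the neural network used to test the decoding
pipeline in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .encoding import EncodedImage, ImageGeometry

BACKGROUND, DEL, INS, INV, DUP, INVDUP, REF = range(7)
CLASS_NAMES = ("Background", "DEL", "INS", "INV", "DUP", "INVDUP", "REF")
NAME_TO_CLASS = {n: i for i, n in enumerate(CLASS_NAMES)}
N_CLASSES = 7
#: SV component classes (excludes Background and REF)
SV_CLASSES = (DEL, INS, INV, DUP, INVDUP)
#: classes represented in the vertical insertion tracks
INSERTION_CLASSES = (INS, DUP, INVDUP)
#: classes represented in the horizontal (reference-anchored) tracks
HORIZONTAL_CLASSES = (DEL, INV)


@dataclass
class SegmentationMask:
    labels: np.ndarray  # (S, S) uint8 in [0, 6]
    scores: Optional[np.ndarray] = None  # (7, S, S) float, optional

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2 or self.labels.shape[0] != self.labels.shape[1]:
            raise ValueError("mask must be a square 2D label array")
        if self.labels.max(initial=0) >= N_CLASSES:
            raise ValueError("mask contains labels outside the fixed class set")

    @property
    def size(self) -> int:
        return self.labels.shape[0]


@dataclass
class TruthComponent:
    """One implanted SV component of one genome, as visible at a locus."""

    type: str        # DEL / INS / INV / DUP / INVDUP
    ref_start: int   # 0-based half-open; for insertion-like types the
    ref_end: int     # anchor point (start == insertion point)
    af: float        # realised carrier fraction at the locus

    def __post_init__(self):
        if self.type not in NAME_TO_CLASS or self.type in ("Background", "REF"):
            raise ValueError(f"unknown component type {self.type!r}")
        if not 0.0 <= self.af <= 1.0:
            raise ValueError("allele fraction outside [0, 1]")


def _nearest_insertion_track(geometry: ImageGeometry, ref_pos: int,
                             tol: int = 1000):
    best, best_d = None, tol + 1
    for tr in geometry.insertion_tracks:
        d = abs(tr.ref_pos - ref_pos)
        if d < best_d:
            best, best_d = tr, d
    return best


def make_truth_mask(image: EncodedImage,
                    case_truth: List[TruthComponent],
                    control_truth: List[TruthComponent]) -> SegmentationMask:
    """Ground-truth mask for a simulated locus.

    Track regions with no variant are REF; each component paints its class
    over its breakpoint x-span with an AF-proportional extent, anchored at
    the outer edge of the track (where the rendered coverage deficit or
    aberrant-colour stack sits).  A component lying entirely outside the
    image window raises ``ValueError``.
    """
    geom = image.geometry
    S, T = geom.image_size, geom.track_height
    labels = np.zeros((S, S), dtype=np.uint8)

    r0, r1, c0, c1 = geom.control_track_region
    labels[r0:r1, c0:c1] = REF
    r0, r1, c0, c1 = geom.case_track_region
    labels[r0:r1, c0:c1] = REF
    for tr in geom.insertion_tracks:
        a0, a1 = tr.case_cols(S, T)
        b0, b1 = tr.control_cols(S, T)
        y1 = min(max(tr.y1, tr.y0 + 2), S)
        labels[tr.y0:y1, a0:a1] = REF
        labels[tr.y0:y1, b0:b1] = REF

    for track, comps in (("case", case_truth), ("control", control_truth)):
        for comp in comps:
            _paint_component(labels, geom, comp, track)
    return SegmentationMask(labels=labels)


def _paint_component(labels, geom: ImageGeometry, comp: TruthComponent,
                     track: str):
    S, T = geom.image_size, geom.track_height
    cls = NAME_TO_CLASS[comp.type]
    if comp.ref_end < geom.win_start or comp.ref_start >= geom.win_end:
        raise ValueError(
            f"component {comp.type} {comp.ref_start}-{comp.ref_end} outside "
            f"window {geom.win_start}-{geom.win_end}")
    extent = int(round(comp.af * T))
    if extent < 1:
        return  # below the representable AF floor
    if comp.type in ("DEL", "INV"):
        x0 = geom.x_of(max(comp.ref_start, geom.win_start))
        x1 = max(geom.x_of(min(comp.ref_end, geom.win_end)), x0 + 1)
        if track == "case":
            labels[S - extent:S, x0:x1] = cls
        else:
            labels[0:extent, x0:x1] = cls
    else:  # insertion-like: paint into the matching vertical track
        tr = _nearest_insertion_track(geom, comp.ref_start)
        if tr is None:
            return  # image carries no gap able to represent this component
        y1 = min(max(tr.y1, tr.y0 + 2), S)
        if track == "case":
            c0, c1 = tr.x, min(S, tr.x + extent)
        else:
            c0, c1 = max(0, tr.x - extent), tr.x
        labels[tr.y0:y1, c0:c1] = cls


def oracle_segment(image: EncodedImage,
                   case_truth: List[TruthComponent],
                   control_truth: List[TruthComponent]) -> SegmentationMask:
    """Deterministic oracle segmenter (alias of :func:`make_truth_mask`):
    isolates decoder correctness from network capacity in pipeline tests."""
    return make_truth_mask(image, case_truth, control_truth)
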