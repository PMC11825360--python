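"""Genome-to-genome comparison images.

A candidate locus is rendered into one square RGB image that a segmentation
network (or an oracle) can decode.  Two ingredients:

* **Structure sketching** — the representative read's symbol series becomes a
  similarity plot: reference window on the x axis, read/feature sequence on
  the y axis.  M symbols draw diagonal segments, V symbols anti-diagonal
  segments, mapped I symbols segments over their source reference span, and
  unmapped I symbols leave vertical gaps.

* **Content rendering** — augmented coverage tracks (ACTs).  An ACT is an RGB
  stacked barplot of per-position alignment counts split by mapping condition
  (forward / reversed / duplicated / reverse-duplicated), each condition with
  its own palette colour.  The control genome's ACT fills a fixed-height track
  at the top of the image, the case genome's ACT the track at the bottom; at
  insertion-induced vertical gaps, extra vertical tracks are placed left
  (control) and right (case) of the gap and filled from read-level counts of
  insertion-carrying reads.

The vertical extent of any SV evidence in a track, divided by the track
height, is the allele fraction — which is why track height fixes the minimum
detectable AF (1/25, 1/50, 1/100 for image sizes 256, 512, 1024).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from skimage.draw import line as _line

from .signatures import (DEFAULT_MIN_MAPQ, DEFAULT_MIN_SV_SIZE, SymbolSeries,
                         extract_series, resolve_unmapped_insertion)
from .loci import CandidateLocus

# ---------------------------------------------------------------------------
# fixed palette and geometry tables

#: forward-mapped coverage colour; the other conditions subtract 100 from the
#: second channel (reversed), third channel (duplicated), or both.
ACT_PALETTE = {
    "forward": (135, 206, 255),
    "reversed": (135, 106, 255),
    "duplicated": (135, 206, 155),
    "reverse_duplicated": (135, 106, 155),
}
STACK_ORDER = ("forward", "reversed", "duplicated", "reverse_duplicated")
TRACK_HEIGHTS = {256: 25, 512: 50, 1024: 100}
SKELETON_COLOR = (200, 200, 200)
BACKGROUND_COLOR = (0, 0, 0)
DEFAULT_IMAGE_SIZE = 512
PAD_FRACTION = 0.2
MIN_PAD = 300


def act_color(condition: str):
    """RGB triple for a mapping condition (exact integers)."""
    try:
        return ACT_PALETTE[condition]
    except KeyError:
        raise ValueError(f"unknown mapping condition {condition!r}") from None


def min_detectable_af(image_size: int) -> float:
    return 1.0 / TRACK_HEIGHTS[image_size]


# ---------------------------------------------------------------------------
# geometry


@dataclass
class InsertionTrack:
    """Vertical ACT tracks flanking one insertion-induced gap."""

    ref_pos: int      # insertion anchor on the reference
    x: int            # pixel column of the gap
    y0: int           # pixel rows spanned by the gap (read axis)
    y1: int
    kind_hint: str = "INS"  # INS / DUP / INVDUP from mapped-I orientation

    def case_cols(self, image_size, track_height):
        return self.x, min(image_size, self.x + track_height)

    def control_cols(self, image_size, track_height):
        return max(0, self.x - track_height), self.x


@dataclass
class ImageGeometry:
    """Pixel <-> coordinate mapping for one encoded image."""

    image_size: int
    chrom: str
    win_start: int
    win_end: int
    read_axis: tuple = (0, 1)  # (r0, r1) feature-sequence interval shown
    insertion_tracks: List[InsertionTrack] = field(default_factory=list)

    def __post_init__(self):
        if self.image_size not in TRACK_HEIGHTS:
            raise ValueError(
                f"image_size must be one of {sorted(TRACK_HEIGHTS)}")

    @property
    def track_height(self) -> int:
        return TRACK_HEIGHTS[self.image_size]

    @property
    def min_detectable_af(self) -> float:
        return 1.0 / self.track_height

    @property
    def bp_per_pixel(self) -> float:
        return (self.win_end - self.win_start) / self.image_size

    def x_of(self, pos: int) -> int:
        w = self.win_end - self.win_start
        x = int((pos - self.win_start) * self.image_size / w)
        return min(max(x, 0), self.image_size - 1)

    def pos_of(self, x: float) -> int:
        w = self.win_end - self.win_start
        return self.win_start + int(round(x * w / self.image_size))

    def y_of(self, read_pos: float) -> int:
        r0, r1 = self.read_axis
        span = max(r1 - r0, 1)
        y = int((read_pos - r0) * self.image_size / span)
        return min(max(y, 0), self.image_size - 1)

    def read_bp_per_pixel(self) -> float:
        r0, r1 = self.read_axis
        return max(r1 - r0, 1) / self.image_size

    @property
    def control_track_region(self):
        """(row0, row1, col0, col1) of the horizontal control track."""
        return (0, self.track_height, 0, self.image_size)

    @property
    def case_track_region(self):
        s = self.image_size
        return (s - self.track_height, s, 0, s)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        d = {
            "image_size": self.image_size, "chrom": self.chrom,
            "win_start": self.win_start, "win_end": self.win_end,
            "read_axis": list(self.read_axis),
            "insertion_tracks": [
                {"ref_pos": t.ref_pos, "x": t.x, "y0": t.y0, "y1": t.y1,
                 "kind_hint": t.kind_hint}
                for t in self.insertion_tracks],
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ImageGeometry":
        d = json.loads(s)
        tracks = [InsertionTrack(**t) for t in d.pop("insertion_tracks")]
        d["read_axis"] = tuple(d["read_axis"])
        return cls(insertion_tracks=tracks, **d)


# ---------------------------------------------------------------------------
# structure sketching


@dataclass
class SketchElement:
    kind: str            # 'M', 'V', 'I' (unmapped), 'DUPSEG' (mapped I)
    read_start: int
    read_end: int
    ref_start: Optional[int] = None   # None for unmapped I
    ref_end: Optional[int] = None
    strand: str = "+"
    aberrant: bool = False


def _clip_mapped(sym, win_start, win_end):
    """Clip a mapped symbol's ref span to the window, scaling its read span
    proportionally. Returns (ref_s, ref_e, read_s, read_e) or None."""
    rs, re_ = sym.ref_start, sym.ref_end
    if re_ <= win_start or rs >= win_end:
        return None
    span = re_ - rs
    lo = max(rs, win_start)
    hi = min(re_, win_end)
    f0 = (lo - rs) / span
    f1 = (hi - rs) / span
    rl = sym.read_end - sym.read_start
    if sym.kind == "V":  # read runs against reference direction
        q0 = sym.read_start + int((1 - f1) * rl)
        q1 = sym.read_start + int((1 - f0) * rl)
    else:
        q0 = sym.read_start + int(f0 * rl)
        q1 = sym.read_start + int(f1 * rl)
    return lo, hi, q0, max(q1, q0 + 1)


def sketch_structure(series: SymbolSeries, win_start: int, win_end: int,
                     chrom: str) -> List[SketchElement]:
    """Sketch elements of one representative read inside a window.

    Segments and gaps not derived from plain M symbols carry aberrant flags.
    """
    if not series.symbols:
        raise ValueError("cannot sketch an empty symbol series")
    elems: List[SketchElement] = []
    syms = series.symbols
    for i, s in enumerate(syms):
        if s.kind in ("M", "V"):
            clipped = _clip_mapped(s, win_start, win_end)
            if clipped is None:
                continue
            lo, hi, q0, q1 = clipped
            elems.append(SketchElement(
                kind=s.kind, read_start=q0, read_end=q1,
                ref_start=lo, ref_end=hi,
                strand="-" if s.kind == "V" else "+",
                aberrant=(s.kind == "V")))
        else:  # I
            anchor = None
            for j in range(i - 1, -1, -1):
                if syms[j].ref_end is not None:
                    anchor = syms[j].ref_end
                    break
            if anchor is None:
                for j in range(i + 1, len(syms)):
                    if syms[j].ref_start is not None:
                        anchor = syms[j].ref_start
                        break
            if anchor is None or not (win_start <= anchor < win_end):
                continue
            if s.mapped_flag and s.source_ref_span is not None:
                schrom, ss, se, strand = s.source_ref_span
                if schrom == chrom and ss < win_end and se > win_start:
                    elems.append(SketchElement(
                        kind="DUPSEG", read_start=s.read_start,
                        read_end=s.read_end,
                        ref_start=max(ss, win_start),
                        ref_end=min(se, win_end),
                        strand=strand, aberrant=True))
                    continue
            elems.append(SketchElement(
                kind="I", read_start=s.read_start, read_end=s.read_end,
                ref_start=anchor, ref_end=anchor, aberrant=True))
    if not elems:
        raise ValueError("representative read does not overlap the window")
    return elems


# ---------------------------------------------------------------------------
# mapping-condition counts


@dataclass
class MappingConditionCounts:
    """Per-position counts over a window, one row per mapping condition, in
    :data:`STACK_ORDER`; plus the per-genome normalisation constant."""

    counts: np.ndarray  # (4, window_length) int
    norm: float         # median per-bp total coverage (>= 1)

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def compute_condition_counts(bam, chrom, win_start, win_end,
                             min_mapq: int = DEFAULT_MIN_MAPQ) -> MappingConditionCounts:
    """Count alignments per reference position split by mapping condition.

    Duplicated status is per alignment: an alignment is duplicated when its
    reference span is encompassed by another alignment of the same read.
    """
    w = win_end - win_start
    counts = np.zeros((4, w), dtype=np.int32)
    groups = {}
    for a in bam.fetch(chrom, max(0, win_start), win_end):
        if a.is_unmapped or a.is_secondary or a.mapping_quality < min_mapq:
            continue
        groups.setdefault(a.query_name, []).append(a)
    for alns in groups.values():
        spans = [(a.reference_start, a.reference_end) for a in alns]
        for i, a in enumerate(alns):
            s, e = spans[i]
            dup = any(j != i and spans[j][0] <= s and spans[j][1] >= e
                      and (spans[j][1] - spans[j][0]) > (e - s)
                      for j in range(len(alns)))
            cond = (2 if dup else 0) + (1 if a.is_reverse else 0)
            # per-base coverage over gapless blocks: deletion gaps inside an
            # alignment must not count as covered
            for bs, be in a.get_blocks():
                lo = max(bs, win_start) - win_start
                hi = min(be, win_end) - win_start
                if hi > lo:
                    counts[cond, lo:hi] += 1
    total = counts.sum(axis=0)
    # flank coverage, not whole-window median: a variant may span over half
    # the window, and the 20%-per-side padding keeps the top 15% of
    # positions inside the flanks
    norm = float(max(np.percentile(total, 85), 1.0))
    return MappingConditionCounts(counts=counts, norm=norm)


def count_insertion_carriers(series_list, ref_pos: int,
                             tol: int = 500,
                             min_size: int = DEFAULT_MIN_SV_SIZE):
    """(carriers, total) read-level counts at an insertion anchor.

    A read carries the insertion if one of its I symbols is anchored within
    ``tol`` of ``ref_pos``; the denominator is every read whose mapped extent
    covers ``ref_pos``.
    """
    carriers = total = 0
    for series in series_list:
        ext = series.ref_extent
        if ext is None or not (ext[1] <= ref_pos <= ext[2]):
            continue
        total += 1
        hit = False
        syms = series.symbols
        for i, s in enumerate(syms):
            if s.kind != "I" or s.seq_length < min_size:
                continue
            anchor = None
            for j in range(i - 1, -1, -1):
                if syms[j].ref_end is not None:
                    anchor = syms[j].ref_end
                    break
            if anchor is None:
                for j in range(i + 1, len(syms)):
                    if syms[j].ref_start is not None:
                        anchor = syms[j].ref_start
                        break
            if anchor is not None and abs(anchor - ref_pos) <= tol:
                hit = True
                break
        if hit:
            carriers += 1
    return carriers, total


# ---------------------------------------------------------------------------
# rendering


@dataclass
class EncodedImage:
    pixels: np.ndarray  # (S, S, 3) uint8
    geometry: ImageGeometry
    skeleton: List[SketchElement] = field(default_factory=list)
    low_confidence: bool = False
    case_name: str = "case"
    control_name: str = "control"
    case_norm: float = 0.0     # per-genome ACT normalisation constants
    control_norm: float = 0.0  # (flank coverage estimates)


def _bin_counts(counts: np.ndarray, image_size: int) -> np.ndarray:
    """Resample (4, W) bp counts to (4, S) pixel columns (mean over the bp
    range of each column; nearest-bp sampling when the window is narrower
    than the image)."""
    w = counts.shape[1]
    if w < image_size:
        idx = np.minimum(((np.arange(image_size) + 0.5) * w
                          / image_size).astype(int), w - 1)
        return counts[:, idx].astype(np.float64)
    edges = (np.arange(image_size + 1) * w / image_size).astype(int)
    csum = np.concatenate([np.zeros((counts.shape[0], 1)),
                           np.cumsum(counts, axis=1)], axis=1)
    widths = np.maximum(np.diff(edges), 1)
    return (csum[:, edges[1:]] - csum[:, edges[:-1]]) / widths


def render_act(counts: MappingConditionCounts, geometry: ImageGeometry,
               track: str, pixels: np.ndarray) -> None:
    """Paint one horizontal ACT into ``pixels`` in place.

    Bars are anchored at the track edge nearest the sketch (the inner edge)
    and grow outward, stacked in :data:`STACK_ORDER`; a coverage deficit
    therefore appears at the outer edge of the track.
    """
    S, T = geometry.image_size, geometry.track_height
    binned = _bin_counts(counts.counts, S)
    heights = np.rint(binned * (T / counts.norm)).astype(int)
    for x in range(S):
        h = heights[:, x]
        filled = 0
        for ci, cond in enumerate(STACK_ORDER):
            n = min(h[ci], T - filled)
            if n <= 0:
                continue
            color = ACT_PALETTE[cond]
            if track == "control":
                # inner edge = bottom row of the top track
                r1 = T - filled
                pixels[r1 - n:r1, x] = color
            else:
                r0 = S - T + filled
                pixels[r0:r0 + n, x] = color
            filled += n


def paint_vertical_bar(pixels, geometry, track: InsertionTrack, side: str,
                       width: int) -> None:
    """Fill ``width`` columns of a vertical insertion ACT next to the gap."""
    S, T = geometry.image_size, geometry.track_height
    width = min(width, T)
    if width <= 0:
        return
    y0, y1 = track.y0, min(max(track.y1, track.y0 + 2), S)
    if side == "case":
        c0, c1 = track.x, min(S, track.x + width)
    else:
        c0, c1 = max(0, track.x - width), track.x
    pixels[y0:y1, c0:c1] = ACT_PALETTE["forward"]


def _render_insertion_tracks(geometry, pixels, case_series, control_series,
                             case_norm, control_norm, min_sv_size):
    T = geometry.track_height
    for tr in geometry.insertion_tracks:
        for side, series_list, norm in (
                ("case", case_series, case_norm),
                ("control", control_series, control_norm)):
            carriers, _total = count_insertion_carriers(
                series_list, tr.ref_pos, min_size=min_sv_size)
            paint_vertical_bar(pixels, geometry, tr, side,
                               int(round(T * carriers / norm)))


def _draw_skeleton(elems, geometry, pixels):
    for e in elems:
        y0 = geometry.y_of(e.read_start)
        y1 = geometry.y_of(e.read_end)
        if e.kind == "I":
            continue  # vertical gap: nothing drawn
        if e.kind == "V":
            x0, x1 = geometry.x_of(e.ref_end), geometry.x_of(e.ref_start)
        elif e.kind == "DUPSEG" and e.strand == "-":
            x0, x1 = geometry.x_of(e.ref_end), geometry.x_of(e.ref_start)
        else:
            x0, x1 = geometry.x_of(e.ref_start), geometry.x_of(e.ref_end)
        rr, cc = _line(y0, x0, y1, x1)
        pixels[rr, cc] = SKELETON_COLOR
        # 2 px thick so the structure survives the network's stem pooling
        rr2 = np.clip(rr + 1, 0, pixels.shape[0] - 1)
        pixels[rr2, cc] = SKELETON_COLOR


def build_geometry(locus: CandidateLocus, series: SymbolSeries,
                   image_size: int = DEFAULT_IMAGE_SIZE,
                   pad_fraction: float = PAD_FRACTION,
                   min_pad: int = MIN_PAD):
    """Window, read axis and insertion tracks for one locus + representative
    read."""
    L = locus.ref_end - locus.ref_start
    pad = max(int(round(pad_fraction * L)), min_pad)
    win_start = max(0, locus.ref_start - pad)
    win_end = locus.ref_end + pad
    elems = sketch_structure(series, win_start, win_end, locus.chrom)
    r0 = min(e.read_start for e in elems)
    r1 = max(e.read_end for e in elems)
    geom = ImageGeometry(image_size=image_size, chrom=locus.chrom,
                         win_start=win_start, win_end=win_end,
                         read_axis=(r0, r1))
    for e in elems:
        if e.kind == "I" or e.kind == "DUPSEG":
            anchor = e.ref_start if e.kind == "I" else None
            if anchor is None:
                # anchor of a mapped I: gap x position comes from the read
                # path, i.e. where the diagonal is interrupted
                anchor = _dupseg_anchor(series, e, win_start, win_end)
            if anchor is None:
                continue
            hint = "INS"
            if e.kind == "DUPSEG":
                hint = "INVDUP" if e.strand == "-" else "DUP"
            geom.insertion_tracks.append(InsertionTrack(
                ref_pos=anchor, x=geom.x_of(anchor),
                y0=geom.y_of(e.read_start), y1=geom.y_of(e.read_end),
                kind_hint=hint))
    return geom, elems


def _dupseg_anchor(series, elem, win_start, win_end):
    syms = series.symbols
    for i, s in enumerate(syms):
        if s.kind == "I" and s.read_start == elem.read_start:
            for j in range(i - 1, -1, -1):
                if syms[j].ref_end is not None:
                    a = syms[j].ref_end
                    return a if win_start <= a < win_end else None
    return None


def choose_representative(locus: CandidateLocus) -> SymbolSeries:
    """Spanning read of the dominant cluster with the widest mapped extent."""
    cl = locus.dominant_cluster()
    best, best_w = None, -1
    for r in cl.reads:
        ext = r.ref_extent
        if ext is None:
            continue
        w = min(ext[2], locus.ref_end) - max(ext[1], locus.ref_start) \
            + (ext[2] - ext[1])
        if w > best_w:
            best, best_w = r, w
    if best is None:
        raise ValueError("locus has no mapped supporting read")
    return best


def encode_pair(locus: CandidateLocus, case_bam, control_bam,
                image_size: int = DEFAULT_IMAGE_SIZE,
                ref_fasta=None,
                min_mapq: int = DEFAULT_MIN_MAPQ,
                min_sv_size: int = DEFAULT_MIN_SV_SIZE,
                representative: Optional[SymbolSeries] = None,
                case_name: str = "case",
                control_name: str = "control") -> EncodedImage:
    """Encode one locus of the case genome against one control genome."""
    rep = representative or choose_representative(locus)
    if ref_fasta is not None:
        rep = resolve_series_insertions(rep, ref_fasta, min_sv_size)
    geom, elems = build_geometry(locus, rep, image_size)
    case_counts = compute_condition_counts(
        case_bam, geom.chrom, geom.win_start, geom.win_end, min_mapq)
    if case_counts.total.max() == 0:
        raise ValueError(
            f"no case coverage at locus {geom.chrom}:{geom.win_start}-{geom.win_end}")
    control_counts = compute_condition_counts(
        control_bam, geom.chrom, geom.win_start, geom.win_end, min_mapq)
    low_conf = control_counts.total.max() == 0

    S = image_size
    pixels = np.zeros((S, S, 3), dtype=np.uint8)
    pixels[:, :] = BACKGROUND_COLOR
    _draw_skeleton(elems, geom, pixels)
    render_act(case_counts, geom, "case", pixels)
    if not low_conf:
        render_act(control_counts, geom, "control", pixels)
    if geom.insertion_tracks:
        case_series = extract_series(case_bam, geom.chrom, geom.win_start,
                                     geom.win_end, min_sv_size, min_mapq)
        control_series = extract_series(control_bam, geom.chrom,
                                        geom.win_start, geom.win_end,
                                        min_sv_size, min_mapq)
        _render_insertion_tracks(geom, pixels, case_series, control_series,
                                 case_counts.norm,
                                 max(control_counts.norm, 1.0), min_sv_size)
    return EncodedImage(pixels=pixels, geometry=geom, skeleton=elems,
                        low_confidence=low_conf, case_name=case_name,
                        control_name=control_name,
                        case_norm=case_counts.norm,
                        control_norm=control_counts.norm)


def encode_one_to_n(locus: CandidateLocus, case_bam, control_bams,
                    **kwargs) -> List[EncodedImage]:
    """One-to-N mode: one image per (case, control_i) pair, identical case
    content in each."""
    if not control_bams:
        raise ValueError("at least one control genome is required")
    rep = kwargs.pop("representative", None) or choose_representative(locus)
    return [encode_pair(locus, case_bam, cb, representative=rep, **kwargs)
            for cb in control_bams]


def resolve_series_insertions(series: SymbolSeries, ref_fasta,
                              min_sv_size: int = DEFAULT_MIN_SV_SIZE,
                              window_factor: int = 10,
                              max_window: int = 20000) -> SymbolSeries:
    """Attempt mapped-I resolution for every unmapped I symbol of a series."""
    new_syms = []
    syms = series.symbols
    for i, s in enumerate(syms):
        if s.kind == "I" and not s.mapped_flag and s.seq:
            anchor = None
            chrom = None
            for j in list(range(i - 1, -1, -1)) + list(range(i + 1, len(syms))):
                if syms[j].ref_start is not None:
                    anchor = syms[j].ref_end if j < i else syms[j].ref_start
                    chrom = syms[j].chrom
                    break
            if anchor is not None:
                half = min(window_factor * s.seq_length, max_window)
                ws = max(0, anchor - half)
                wseq = ref_fasta.fetch(chrom, ws, anchor + half).upper()
                s = resolve_unmapped_insertion(s, wseq, ws, chrom)
        new_syms.append(s)
    return SymbolSeries(read_name=series.read_name, symbols=new_syms)


def save_png(image: EncodedImage, path) -> None:
    """Debug dump (bit-exact for fixed inputs); geometry goes to a JSON
    sidecar."""
    from PIL import Image as _PILImage
    _PILImage.fromarray(image.pixels).save(str(path))
    with open(str(path) + ".json", "w") as fh:
        fh.write(image.geometry.to_json())
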