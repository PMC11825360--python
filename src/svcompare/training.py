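"""Training-set fabrication for the segmentation network.

Training images are produced straight through the production renderer
(`render_act`, skeleton drawing, vertical insertion bars) but from sampled
per-position depth fields rather than BAM files, which makes generating
hundreds of labelled examples a matter of seconds.  Depth fields are sums of
random read intervals, so coverage noise has the long-range correlation of
real long-read pileups; carrier reads are position-stratified so the
rendered evidence matches the nominal allele fraction to within one read.

The mix deliberately covers the comparison categories the decoder must
distinguish downstream: controls that share the variant (germline), carry it
at a different fraction (new allele), or lack it entirely (new component),
plus low-AF somatic-style loci rendered at image size 1024.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .encoding import (BACKGROUND_COLOR, MappingConditionCounts,
                       TRACK_HEIGHTS, EncodedImage, _draw_skeleton,
                       build_geometry, paint_vertical_bar, render_act)
from .loci import CandidateLocus
from .masks import TruthComponent
from .signatures import ReadSymbol, SymbolSeries
from .simulate import ComponentSpec, make_components, _SSV_TYPES, _CSV_TYPES
from .unet import TrainingExample

_CHROM = "sim"


def series_from_components(comps: Sequence[ComponentSpec], read_lo: int,
                           read_hi: int, chrom: str = _CHROM) -> SymbolSeries:
    """Symbol series of a perfect carrier read spanning [read_lo, read_hi)."""
    syms: List[ReadSymbol] = []
    q = 0
    cursor = read_lo

    def add_m(lo, hi):
        nonlocal q
        if hi > lo:
            syms.append(ReadSymbol("M", q, q + (hi - lo), "synthetic",
                                   chrom=chrom, ref_start=lo, ref_end=hi))
            q += hi - lo

    for c in sorted(comps, key=lambda c: (c.start, c.end)):
        add_m(cursor, c.start)
        cursor = max(cursor, c.start)
        if c.type == "DEL":
            cursor = c.end
        elif c.type == "INV":
            n = c.end - c.start
            syms.append(ReadSymbol("V", q, q + n, "synthetic", chrom=chrom,
                                   ref_start=c.start, ref_end=c.end))
            q += n
            cursor = c.end
        elif c.type == "INS":
            n = len(c.seq) if c.seq else 500
            syms.append(ReadSymbol("I", q, q + n, "synthetic"))
            q += n
        elif c.type in ("DUP", "INVDUP"):
            add_m(cursor, c.end)
            n = c.end - c.start
            strand = "+" if c.type == "DUP" else "-"
            syms.append(ReadSymbol(
                "I", q, q + n, "synthetic", mapped_flag=True,
                source_ref_span=(chrom, c.start, c.end, strand)))
            q += n
            cursor = c.end
    add_m(cursor, read_hi)
    return SymbolSeries(read_name="synthetic", symbols=syms)


def _depth(starts: np.ndarray, read_len: int, w: int) -> np.ndarray:
    d = np.zeros(w + 1, dtype=np.int32)
    lo = np.clip(starts, 0, w)
    hi = np.clip(starts + read_len, 0, w)
    np.add.at(d, lo, 1)
    np.add.at(d, hi, -1)
    return np.cumsum(d[:-1])


def _track_counts(rng, w, cov, read_len, events):
    """(counts, anchor carrier depths) for one genome over a window.

    ``events``: list of (ComponentSpec, af) in window coordinates.
    """
    n = max(int(rng.poisson(cov * (w + read_len) / read_len)), 4)
    starts = np.sort(rng.integers(-read_len, w, size=n))
    counts = np.zeros((4, w), dtype=np.int32)
    counts[0] = _depth(starts, read_len, w)
    bars = []
    for comp, af in events:
        if af <= 0:
            continue
        k = int(round(af * n))
        if k <= 0:
            continue
        stride = n / k
        idx = np.clip((np.arange(k) * stride
                       + float(rng.uniform(0, stride))).astype(int), 0, n - 1)
        cd = _depth(starts[idx], read_len, w)
        if comp.type == "DEL":
            a, b = np.clip([comp.start, comp.end], 0, w)
            counts[0, a:b] -= cd[a:b]
        elif comp.type == "INV":
            a, b = np.clip([comp.start, comp.end], 0, w)
            counts[0, a:b] -= cd[a:b]
            counts[1, a:b] += cd[a:b]
        else:
            anchor = int(np.clip(comp.signal_span[0], 0, w - 1))
            bars.append((comp.type, anchor, int(cd[anchor])))
    counts[0] = np.maximum(counts[0], 0)
    # flank coverage estimate (see compute_condition_counts)
    norm = float(max(np.percentile(counts.sum(axis=0), 85), 1.0))
    return MappingConditionCounts(counts=counts, norm=norm), bars


_ALL_TYPES = list(_SSV_TYPES) + list(_CSV_TYPES)


def synthesize_example(rng, image_size: int,
                       read_len: int = 8000) -> TrainingExample:
    """One labelled locus image sampled from the stated training mix."""
    T = TRACK_HEIGHTS[image_size]
    vtype = _ALL_TYPES[int(rng.integers(len(_ALL_TYPES)))]
    base = 30000
    comps = make_components(vtype, base, rng, size_range=(300, 1200))

    somatic_style = image_size >= 1024 and rng.random() < 0.7
    if somatic_style:
        # half the somatic examples sit right at the sensitivity limit
        af_case = (float(rng.uniform(0.01, 0.04)) if rng.random() < 0.5
                   else float(rng.uniform(0.04, 0.12)))
        cov_case = int(rng.integers(150, 300))
        cov_ctrl = int(rng.integers(20, 45))
    else:
        af_case = (float(rng.choice([0.5, 1.0])) if rng.random() < 0.6
                   else float(rng.uniform(max(2.0 / T, 0.08), 1.0)))
        cov_case = int(rng.integers(25, 70))
        cov_ctrl = int(rng.integers(25, 70))
    u = rng.random()
    if u < 0.45 or somatic_style:
        af_ctrl = 0.0          # new component
    elif u < 0.8:
        af_ctrl = af_case      # germline
    else:                      # new allele
        af_ctrl = 1.0 if af_case <= 0.6 else 0.5

    span_lo = min(c.signal_span[0] for c in comps)
    span_hi = max(c.signal_span[1] for c in comps)
    margin = (span_hi - span_lo) + 3000
    series = series_from_components(comps, span_lo - margin, span_hi + margin)
    locus = CandidateLocus(chrom=_CHROM, ref_start=span_lo, ref_end=span_hi)
    geom, elems = build_geometry(locus, series, image_size)
    w = geom.win_end - geom.win_start

    def to_window(c: ComponentSpec) -> ComponentSpec:
        return ComponentSpec(c.type, c.start - geom.win_start,
                             c.end - geom.win_start, seq=c.seq)

    events_case = [(to_window(c), af_case) for c in comps]
    events_ctrl = [(to_window(c), af_ctrl) for c in comps]
    case_counts, case_bars = _track_counts(rng, w, cov_case, read_len,
                                           events_case)
    ctrl_counts, ctrl_bars = _track_counts(rng, w, cov_ctrl, read_len,
                                           events_ctrl)

    pixels = np.zeros((image_size, image_size, 3), dtype=np.uint8)
    pixels[:, :] = BACKGROUND_COLOR
    _draw_skeleton(elems, geom, pixels)
    render_act(case_counts, geom, "case", pixels)
    render_act(ctrl_counts, geom, "control", pixels)
    for side, bars, norm in (("case", case_bars, case_counts.norm),
                             ("control", ctrl_bars, ctrl_counts.norm)):
        for _btype, anchor, cd in bars:
            ref_anchor = anchor + geom.win_start
            tr = min(geom.insertion_tracks,
                     key=lambda t: abs(t.ref_pos - ref_anchor),
                     default=None)
            if tr is not None and abs(tr.ref_pos - ref_anchor) < 300:
                paint_vertical_bar(pixels, geom, tr, side,
                                   int(round(T * cd / norm)))

    image = EncodedImage(pixels=pixels, geometry=geom, skeleton=elems)
    case_truth = [TruthComponent(c.type, *c.signal_span, af=af_case)
                  if c.type != "DEL" and c.type != "INV"
                  else TruthComponent(c.type, c.start, c.end, af=af_case)
                  for c in comps]
    ctrl_truth = ([TruthComponent(t.type, t.ref_start, t.ref_end, af=af_ctrl)
                   for t in case_truth] if af_ctrl > 0 else [])
    from .masks import make_truth_mask
    mask = make_truth_mask(image, case_truth, ctrl_truth)
    return TrainingExample(image=image, truth_mask=mask,
                           metadata={"type": vtype, "af_case": af_case,
                                     "af_control": af_ctrl,
                                     "image_size": image_size})


def simulate_training_examples(n: int, seed: int = 0,
                               image_sizes: Sequence[int] = (256, 256, 256,
                                                             1024, 1024),
                               read_len: int = 8000) -> List[TrainingExample]:
    """Deterministic labelled training set with the given size mix."""
    rng = np.random.default_rng(seed)
    return [synthesize_example(rng, image_sizes[i % len(image_sizes)],
                               read_len) for i in range(n)]
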