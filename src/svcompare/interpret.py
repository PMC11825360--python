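"""Decoding segmentation masks into SV calls and genome-to-genome categories.

A mask region's horizontal span is the breakpoint span of an SV component;
its span across the track (vertical in the horizontal tracks, horizontal in
the vertical insertion tracks) divided by the track height is the allele
fraction.  Case-track components are joined in read order into the final
(possibly complex) SV type; each component is then contrasted with the
control track of the same image:

* **Germline** — present in the control with the same AF;
* **New allele** — present with a different AF;
* **New component** — absent from the control;
* **New breakpoint** — present but with a different breakpoint span.

A de novo SV is a call whose components are New component against *every*
parental control; a somatic SV is New component against the matched normal,
subject to support and AF floors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, footprint_rectangle

from .encoding import ACT_PALETTE, ImageGeometry
from .masks import (CLASS_NAMES, HORIZONTAL_CLASSES, INSERTION_CLASSES,
                    NAME_TO_CLASS, SegmentationMask)

GERMLINE = "Germline"
NEW_COMPONENT = "New component"
NEW_BREAKPOINT = "New breakpoint"
NEW_ALLELE = "New allele"
CATEGORIES = (GERMLINE, NEW_COMPONENT, NEW_BREAKPOINT, NEW_ALLELE)

DEFAULT_HET_FLOOR = 0.25
DEFAULT_HOM_FLOOR = 0.75


@dataclass
class SVComponent:
    component_type: str
    chrom: str
    ref_start: int
    ref_end: int
    allele_fraction: float
    track: str  # 'case' or 'control'
    pixel_support: int = 0
    insertion_length: Optional[int] = None  # INS/DUP/invDUP only

    @property
    def is_insertion_like(self) -> bool:
        return NAME_TO_CLASS[self.component_type] in INSERTION_CLASSES


@dataclass
class ComparisonEntry:
    """Case component contrasted with one control genome."""

    category: str
    genotype_case: str
    genotype_control: str
    control_name: str = "control"
    matched: Optional[SVComponent] = None


@dataclass
class SVCall:
    chrom: str
    ref_start: int
    ref_end: int
    joined_type: str
    components: List[SVComponent]
    comparisons: Dict[str, List[ComparisonEntry]] = field(default_factory=dict)
    genotype_case: str = "./."
    genotypes_control: Dict[str, str] = field(default_factory=dict)
    support: int = 0
    allele_fraction: float = 0.0
    signature: str = ""
    filter: str = "PASS"
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# mask decoding


def mask_to_components(mask: SegmentationMask, geometry: ImageGeometry,
                       min_area: int = 3, min_width: int = 4) -> List[SVComponent]:
    """Connected mask regions of each SV class, per track, as components.

    DEL/INV are decoded from the horizontal (reference-anchored) tracks;
    INS/DUP/invDUP from the vertical insertion tracks.  AF is clipped to
    [1/track_height, 1].
    """
    if mask.size != geometry.image_size:
        raise ValueError("mask size does not match geometry")
    T = geometry.track_height
    S = geometry.image_size
    labels = mask.labels
    out: List[SVComponent] = []

    for track, (r0, r1, c0, c1) in (("control", geometry.control_track_region),
                                    ("case", geometry.case_track_region)):
        sub = labels[r0:r1, c0:c1]
        for cls in HORIZONTAL_CLASSES:
            binary = sub == cls
            if not binary.any():
                continue
            # wide horizontal closing: one deficit band fragmented by
            # skeleton crossings or prediction noise stays one component
            binary = closing(binary, footprint_rectangle((3, 9)))
            lab = cc_label(binary, connectivity=2)
            for rg in regionprops(lab):
                if rg.area < min_area:
                    continue
                minr, minc, maxr, maxc = rg.bbox
                if maxc - minc < min_width:
                    continue  # narrower than any representable SV span
                if maxr - minr <= 2 and maxc - minc < 60:
                    continue  # ragged bar-top sliver, not a low-AF band
                af = _clip_af((maxr - minr) / T, T)
                out.append(SVComponent(
                    component_type=CLASS_NAMES[cls], chrom=geometry.chrom,
                    ref_start=geometry.pos_of(minc),
                    ref_end=geometry.pos_of(maxc),
                    allele_fraction=af, track=track,
                    pixel_support=int(rg.area)))

    read_scale = geometry.read_bp_per_pixel()
    for tr in geometry.insertion_tracks:
        y1 = min(max(tr.y1, tr.y0 + 2), S)
        ins_len = max(int(round((y1 - tr.y0) * read_scale)), 1)
        for track in ("control", "case"):
            cc0, cc1 = (tr.control_cols(S, T) if track == "control"
                        else tr.case_cols(S, T))
            sub = labels[tr.y0:y1, cc0:cc1]
            # any insertion-class pixels are insertion evidence; the class
            # label itself comes from the mapped-I realignment orientation
            # recorded in the geometry (deterministic alignment evidence),
            # falling back to the majority predicted class
            binary = np.isin(sub, INSERTION_CLASSES)
            if binary.sum() < min_area:
                continue
            rows = np.flatnonzero(binary.any(axis=1))
            cols = np.flatnonzero(binary.any(axis=0))
            if rows.size < 2:
                continue  # noise sliver along the gap
            # one gap is one insertion event per genome: all insertion-class
            # pixels in this track side form a single component
            af = _clip_af((cols.max() - cols.min() + 1) / T, T)
            if tr.kind_hint in NAME_TO_CLASS:
                ctype = tr.kind_hint
            else:
                votes = [(int((sub == c).sum()), CLASS_NAMES[c])
                         for c in INSERTION_CLASSES]
                ctype = max(votes)[1]
            out.append(SVComponent(
                component_type=ctype, chrom=geometry.chrom,
                ref_start=tr.ref_pos, ref_end=tr.ref_pos + 1,
                allele_fraction=af, track=track,
                pixel_support=int(binary.sum()),
                insertion_length=ins_len))
    out.sort(key=lambda c: (c.track, c.ref_start, c.component_type))
    return out


def _clip_af(af: float, track_height: int) -> float:
    return float(min(max(af, 1.0 / track_height), 1.0))


def skeleton_support_intervals(skeleton, min_gap: int = 50):
    """(deletion_gaps, inversion_spans) reference intervals evidenced by the
    sketched structure of the representative case read."""
    mapped = sorted((e for e in skeleton if e.kind in ("M", "V")),
                    key=lambda e: e.read_start)
    gaps = [(a.ref_end, b.ref_start) for a, b in zip(mapped, mapped[1:])
            if b.ref_start - a.ref_end >= min_gap]
    invs = [(e.ref_start, e.ref_end) for e in mapped if e.kind == "V"]
    return gaps, invs


def filter_by_skeleton(components: List[SVComponent], skeleton,
                       tol: int = 500) -> List[SVComponent]:
    """Keep case-track DEL/INV components only where the case read structure
    shows corroborating evidence (suppresses segmentation hallucinations on
    coverage wander); insertion-like components are already anchored to
    skeleton-derived gaps."""
    gaps, invs = skeleton_support_intervals(skeleton)
    out = []
    by_evidence = {}  # (type, evidence index) -> merged component
    for c in components:
        if c.track == "case" and c.component_type in ("DEL", "INV"):
            evidence = gaps if c.component_type == "DEL" else invs
            hit = None
            for i, (lo, hi) in enumerate(evidence):
                if c.ref_start < hi + tol and c.ref_end > lo - tol:
                    hit = i
                    break
            if hit is None:
                continue
            key = (c.component_type, hit)
            prev = by_evidence.get(key)
            if prev is None:
                by_evidence[key] = c
                out.append(c)
            else:
                # fragments of one deficit band: merge, keeping the tallest
                # fragment's AF estimate
                prev.ref_start = min(prev.ref_start, c.ref_start)
                prev.ref_end = max(prev.ref_end, c.ref_end)
                prev.allele_fraction = max(prev.allele_fraction,
                                           c.allele_fraction)
                prev.pixel_support += c.pixel_support
        else:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# genotyping and comparison


def measure_af_from_image(comp: SVComponent, image) -> float:
    """Re-measure a component's allele fraction from the rendered ACT.

    The mask fixes presence, type and span; the rendered stacked bars encode
    the carrier fraction exactly (deficit height for DEL, reversed-colour
    stack for INV, bar width for insertion-like components), so reading the
    quantity off the image removes the network's mask-extent noise.  Returns
    the raw measured fraction, which may be 0 when the image shows no
    evidence at all.
    """
    geom = image.geometry
    S, T = geom.image_size, geom.track_height
    px = image.pixels
    if comp.track == "control":
        rows = slice(0, T)
    else:
        rows = slice(S - T, S)
    palette = np.array(list(ACT_PALETTE.values()), dtype=np.int16)

    def act_pixels(region):  # bool mask of palette-coloured pixels
        d = np.abs(region[:, :, None, :].astype(np.int16)
                   - palette[None, None, :, :]).sum(axis=3)
        return (d == 0).any(axis=2)

    if comp.is_insertion_like:
        tr = min(geom.insertion_tracks,
                 key=lambda t: abs(t.ref_pos - comp.ref_start), default=None)
        if tr is None:
            return comp.allele_fraction
        c0, c1 = (tr.control_cols(S, T) if comp.track == "control"
                  else tr.case_cols(S, T))
        # exclude rows shared with the horizontal ACT tracks, whose bars
        # would masquerade as insertion-bar columns
        y0 = max(tr.y0, T)
        y1 = min(max(tr.y1, tr.y0 + 2), S - T)
        if y1 <= y0:
            return comp.allele_fraction
        region = px[y0:y1, c0:c1]
        cols = act_pixels(region).any(axis=0)
        return int(cols.sum()) / T

    x0 = geom.x_of(comp.ref_start)
    x1 = max(geom.x_of(comp.ref_end), x0 + 1)
    # central portion only: breakpoint columns are blurred by binning
    q = max((x1 - x0) // 4, 1)
    region = px[rows, x0 + q:max(x1 - q, x0 + q + 1)]
    if comp.component_type == "INV":
        rev = ((region[:, :, 0] == 135) & (region[:, :, 1] == 106))
        height = rev.sum(axis=0)
    else:  # DEL: deficit relative to the full track height
        height = T - act_pixels(region).sum(axis=0)
    return float(np.median(height)) / T


def snap_to_skeleton(components: List[SVComponent], skeleton) -> None:
    """Replace case DEL/INV spans with the breakpoints of their
    corroborating skeleton evidence: the sketch comes from the
    representative read's alignments, so its gaps and anti-diagonal spans
    are base-pair precise where a mask region is only pixel precise."""
    gaps, invs = skeleton_support_intervals(skeleton)
    for c in components:
        if c.track != "case" or c.component_type not in ("DEL", "INV"):
            continue
        evidence = gaps if c.component_type == "DEL" else invs
        best, best_ov = None, 0
        for lo, hi in evidence:
            ov = min(hi, c.ref_end) - max(lo, c.ref_start)
            if ov > best_ov:
                best, best_ov = (lo, hi), ov
        if best is not None:
            c.ref_start, c.ref_end = best


def af_to_genotype(af: float, het_floor: float = DEFAULT_HET_FLOOR,
                   hom_floor: float = DEFAULT_HOM_FLOOR) -> str:
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele fraction {af} outside [0, 1]")
    if af < het_floor:
        return "0/0"
    if af < hom_floor:
        return "0/1"
    return "1/1"


def breakpoint_tolerance(geometry: ImageGeometry) -> int:
    """max(50 bp, 2 pixels of quantisation) per endpoint."""
    return max(50, int(round(2 * geometry.bp_per_pixel)))


def af_tolerance(geometry: ImageGeometry) -> float:
    """One-pixel AF noise must not trigger New allele."""
    return max(0.1, 2.0 / geometry.track_height)


def compare_component(case_c: SVComponent,
                      control_components: List[SVComponent],
                      bp_tol: int, af_tol: float,
                      control_name: str = "control",
                      het_floor: float = DEFAULT_HET_FLOOR,
                      hom_floor: float = DEFAULT_HOM_FLOOR) -> ComparisonEntry:
    """Category of one case component against one control genome.

    Precedence: New component > New breakpoint > New allele > Germline.
    """
    gt_case = af_to_genotype(case_c.allele_fraction, het_floor, hom_floor)
    match = None
    for ctrl in control_components:
        if ctrl.track != "control" or ctrl.component_type != case_c.component_type:
            continue
        if case_c.is_insertion_like:
            near = abs(ctrl.ref_start - case_c.ref_start) <= max(bp_tol, 500)
        else:
            near = (ctrl.ref_start < case_c.ref_end + bp_tol
                    and ctrl.ref_end > case_c.ref_start - bp_tol)
        if near and (match is None
                     or abs(ctrl.ref_start - case_c.ref_start)
                     < abs(match.ref_start - case_c.ref_start)):
            match = ctrl
    if match is None:
        return ComparisonEntry(NEW_COMPONENT, gt_case, "0/0", control_name)
    gt_ctrl = af_to_genotype(match.allele_fraction, het_floor, hom_floor)
    if (abs(match.ref_start - case_c.ref_start) > bp_tol
            or abs(match.ref_end - case_c.ref_end) > bp_tol):
        return ComparisonEntry(NEW_BREAKPOINT, gt_case, gt_ctrl,
                               control_name, match)
    if abs(match.allele_fraction - case_c.allele_fraction) > af_tol:
        return ComparisonEntry(NEW_ALLELE, gt_case, gt_ctrl,
                               control_name, match)
    return ComparisonEntry(GERMLINE, gt_case, gt_ctrl, control_name, match)


def join_components(components: List[SVComponent]) -> str:
    """'+'-joined component types in read order (reference order, insertions
    before deletions at a shared breakpoint)."""
    if not components:
        raise ValueError("no components to join")
    ordered = sorted(components,
                     key=lambda c: (c.ref_start, not c.is_insertion_like,
                                    c.component_type))
    return "+".join(c.component_type for c in ordered)


def call_de_novo(call: SVCall, min_controls: int = 2) -> bool:
    """True iff every case component is New component against every control."""
    if len(call.comparisons) < min_controls:
        raise ValueError(
            f"de novo extraction requires >= {min_controls} control genomes, "
            f"got {len(call.comparisons)}")
    return all(entry.category == NEW_COMPONENT
               for entries in call.comparisons.values()
               for entry in entries)


def call_somatic(call: SVCall, min_support: int = 2,
                 min_af: float = 0.01) -> bool:
    """True iff all components are New component vs the matched normal and
    the support / AF floors are met."""
    if not call.comparisons:
        return False
    if call.support < min_support:
        return False
    if not call.components:
        return False
    if min(c.allele_fraction for c in call.components) < min_af:
        return False
    return all(entry.category == NEW_COMPONENT
               for entries in call.comparisons.values()
               for entry in entries)


# ---------------------------------------------------------------------------
# trio / twin metrics


def _alleles(gt: str):
    sep = "/" if "/" in gt else "|"
    a, b = gt.split(sep)
    return a, b


def is_mendelian_consistent(child: str, father: str, mother: str) -> bool:
    """Can the child's two alleles be drawn one from each parent?"""
    ca, cb = _alleles(child)
    fa = set(_alleles(father))
    mo = set(_alleles(mother))
    return (ca in fa and cb in mo) or (cb in fa and ca in mo)


def mendelian_consistency(records) -> float:
    """Fraction of (child, father, mother) genotype records consistent with
    Mendelian inheritance."""
    records = list(records)
    if not records:
        raise ValueError("no trio records")
    ok = sum(is_mendelian_consistent(c, f, m) for c, f, m in records)
    return ok / len(records)


def twin_discordancy(records) -> float:
    """Fraction of (twin1, twin2) genotype records that differ."""
    records = list(records)
    if not records:
        raise ValueError("no twin records")
    diff = sum(g1 != g2 for g1, g2 in records)
    return diff / len(records)


def _refine_control_components(ctrl_comps, img, skeleton):
    """Deterministic cleanup of network-decoded control-track components.

    A control DEL/INV shared with the case must sit on the case read's own
    skeleton evidence (a control-only variant is never encoded, since loci
    come from the case genome), and its rendered deficit must exceed the
    bar-top noise floor; insertion bars are crisp, so rendered evidence of
    any width suffices.
    """
    T = img.geometry.track_height
    # the deficit noise floor is about one read of the control's coverage
    read_af = 1.0 / max(getattr(img, "control_norm", 0.0), 1.0)
    gaps, invs = skeleton_support_intervals(skeleton)
    kept = []
    for c in ctrl_comps:
        if c.component_type in ("DEL", "INV"):
            evidence = gaps if c.component_type == "DEL" else invs
            best, best_ov = None, 0
            for lo, hi in evidence:
                ov = min(hi, c.ref_end) - max(lo, c.ref_start)
                if ov > best_ov:
                    best, best_ov = (lo, hi), ov
            if best is None:
                continue
            c.ref_start, c.ref_end = best
            raw = measure_af_from_image(c, img)
            if raw < max(2.5 / T, 1.75 * read_af):
                continue  # within rendering noise: no real control evidence
        else:
            raw = measure_af_from_image(c, img)
            if raw < 0.5 / T:
                continue
        c.allele_fraction = _clip_af(raw, T)
        kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# call assembly


def build_call(images, masks, locus, support: int,
               signature: str = "",
               control_names: Optional[List[str]] = None,
               het_floor: float = DEFAULT_HET_FLOOR,
               hom_floor: float = DEFAULT_HOM_FLOOR,
               refine_af: bool = False) -> Optional[SVCall]:
    """Assemble an SVCall from the one-to-N images of one locus.

    Case components are decoded from the first image (case content is
    identical across the N images); each image contributes its control-track
    comparison.  Returns None when the case track decodes to no component.
    """
    if not images:
        raise ValueError("no images for locus")
    control_names = control_names or [f"control{i}" for i in range(len(images))]
    geom = images[0].geometry
    comps0 = mask_to_components(masks[0], geom)
    comps0 = filter_by_skeleton(comps0, images[0].skeleton)
    case_comps = [c for c in comps0 if c.track == "case"]
    if not case_comps:
        return None
    if refine_af:
        snap_to_skeleton(case_comps, images[0].skeleton)
        for c in case_comps:
            c.allele_fraction = _clip_af(
                measure_af_from_image(c, images[0]), geom.track_height)
    bp_tol = breakpoint_tolerance(geom)
    af_tol = af_tolerance(geom)

    comparisons: Dict[str, List[ComparisonEntry]] = {}
    genotypes_control: Dict[str, str] = {}
    for img, msk, name in zip(images, masks, control_names):
        ctrl_comps = [c for c in mask_to_components(msk, img.geometry)
                      if c.track == "control"]
        if refine_af:
            ctrl_comps = _refine_control_components(ctrl_comps, img,
                                                    images[0].skeleton)
        entries = [compare_component(cc, ctrl_comps, bp_tol, af_tol, name,
                                     het_floor, hom_floor)
                   for cc in case_comps]
        comparisons[name] = entries
        ctrl_afs = [e.matched.allele_fraction for e in entries
                    if e.matched is not None]
        genotypes_control[name] = af_to_genotype(
            float(np.median(ctrl_afs)) if ctrl_afs else 0.0,
            het_floor, hom_floor)

    call_af = float(np.median([c.allele_fraction for c in case_comps]))
    start = min(c.ref_start for c in case_comps)
    end = max(c.ref_end for c in case_comps)
    return SVCall(
        chrom=geom.chrom, ref_start=start, ref_end=end,
        joined_type=join_components(case_comps),
        components=case_comps, comparisons=comparisons,
        genotype_case=af_to_genotype(call_af, het_floor, hom_floor),
        genotypes_control=genotypes_control,
        support=support, allele_fraction=call_af, signature=signature,
        low_confidence=any(img.low_confidence for img in images))
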