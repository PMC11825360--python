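"""End-to-end comparative calling: scan -> cluster -> encode -> segment ->
decode."""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence

import pysam

from .encoding import (DEFAULT_IMAGE_SIZE, encode_pair,
                       resolve_series_insertions)
from .interpret import SVCall, build_call, call_de_novo, call_somatic
from .loci import (DEFAULT_MIN_SUPPORT, SOMATIC_MIN_SUPPORT,
                   SignatureCluster, discover_loci)
from .signatures import DEFAULT_MIN_MAPQ, DEFAULT_MIN_SV_SIZE, extract_series


class ModelSegmenter:
    """Adapter presenting a trained model through the segmenter protocol
    ``segmenter(image, case_name, control_name) -> SegmentationMask``."""

    #: network masks carry extent noise; AFs are re-measured from the ACTs
    exact_af = False

    def __init__(self, model):
        self.model = model

    def __call__(self, image, case_name=None, control_name=None):
        return self.model.segment(image)


def _cluster_representative(cluster: SignatureCluster):
    best, best_w = None, -1
    for r in cluster.reads:
        ext = r.ref_extent
        if ext is None:
            continue
        w = ext[2] - ext[1]
        if w > best_w:
            best, best_w = r, w
    return best


def _dedup(calls: List[SVCall]) -> List[SVCall]:
    """Collapse same-type calls with overlapping spans (one event captured by
    two signature clusters), keeping the best-supported one."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.ref_start, -c.support))
    out: List[SVCall] = []
    for c in calls:
        dup = False
        for kept in out:
            if (kept.chrom == c.chrom and kept.joined_type == c.joined_type
                    and c.ref_start <= kept.ref_end + 500
                    and c.ref_end >= kept.ref_start - 500):
                dup = True
                break
        if not dup:
            out.append(c)
    return out


def run_comparative_calling(
        case_bam_path, control_bam_paths: Sequence, ref_fasta_path,
        segmenter: Callable,
        case_name: str = "case",
        control_names: Optional[Sequence[str]] = None,
        mode: str = "pair",
        image_size: int = DEFAULT_IMAGE_SIZE,
        min_support: Optional[int] = None,
        min_mapq: int = DEFAULT_MIN_MAPQ,
        min_sv_size: int = DEFAULT_MIN_SV_SIZE,
        chromosomes: Optional[Sequence[str]] = None) -> List[SVCall]:
    """Run the full comparative discovery pipeline.

    ``segmenter`` is any callable following the segmenter protocol — a
    :class:`ModelSegmenter` around a trained network, or an oracle in tests.
    ``mode`` picks the support floor: 10 for germline/de novo discovery,
    2 for somatic.
    """
    if min_support is None:
        min_support = (SOMATIC_MIN_SUPPORT if mode == "somatic"
                       else DEFAULT_MIN_SUPPORT)
    control_names = list(control_names
                         or [f"control{i}" for i in range(len(control_bam_paths))])
    case_bam = pysam.AlignmentFile(str(case_bam_path))
    control_bams = [pysam.AlignmentFile(str(p)) for p in control_bam_paths]
    ref = pysam.FastaFile(str(ref_fasta_path))

    calls: List[SVCall] = []
    chroms = chromosomes or case_bam.references
    for chrom in chroms:
        clen = case_bam.get_reference_length(chrom)
        series = extract_series(case_bam, chrom, 0, clen, min_sv_size,
                                min_mapq)
        loci = discover_loci(series, min_support=min_support)
        for locus in loci:
            for cluster in locus.clusters:
                if cluster.support < min_support:
                    continue
                rep = _cluster_representative(cluster)
                if rep is None:
                    continue
                rep = resolve_series_insertions(rep, ref, min_sv_size)
                try:
                    images = [encode_pair(locus, case_bam, cb,
                                          image_size=image_size, ref_fasta=None,
                                          min_mapq=min_mapq,
                                          min_sv_size=min_sv_size,
                                          representative=rep,
                                          case_name=case_name,
                                          control_name=cn)
                              for cb, cn in zip(control_bams, control_names)]
                except ValueError:
                    continue
                masks = [segmenter(img, case_name, img.control_name)
                         for img in images]
                call = build_call(images, masks, locus,
                                  support=cluster.support,
                                  signature=cluster.signature,
                                  control_names=control_names,
                                  refine_af=not getattr(segmenter, "exact_af",
                                                        False))
                if call is not None:
                    calls.append(call)
    case_bam.close()
    for cb in control_bams:
        cb.close()
    ref.close()
    return _dedup(calls)


def select_de_novo(calls: List[SVCall]) -> List[SVCall]:
    """Calls whose components are New component against every control."""
    return [c for c in calls if len(c.comparisons) >= 2 and call_de_novo(c)]


def select_somatic(calls: List[SVCall], min_support: int = 2,
                   min_af: float = 0.01) -> List[SVCall]:
    return [c for c in calls if call_somatic(c, min_support, min_af)]
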