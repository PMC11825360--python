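"""Candidate SV locus discovery.

Aberrant symbol series (anything other than a plain ``"M"`` read) are grouped
by signature and clustered by the reference positions of their aberration
breakpoints.  A cluster whose number of *spanning* supporting reads reaches
the minimum support becomes a candidate locus.  Nearby loci are merged so one
event captured by two signatures (e.g. ``MM`` and ``MIM`` at an
insertion-deletion locus) is reported once; the merged locus keeps its
per-signature clusters so multi-allelic sites (an SSV allele plus a CSV
allele) stay distinguishable downstream.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import List

from .signatures import SymbolSeries, DEFAULT_MIN_SV_SIZE

DEFAULT_MIN_SUPPORT = 10  # germline / de novo mode
SOMATIC_MIN_SUPPORT = 2
DEFAULT_POSITION_TOLERANCE = 500
DEFAULT_MERGE_DISTANCE = 1000
SPAN_MARGIN = 100


def aberrant_breakpoints(series: SymbolSeries, min_gap: int = DEFAULT_MIN_SV_SIZE):
    """Reference breakpoints of the aberrations in one read.

    Returns (breakpoints, (chrom, span_start, span_end)) or (None, None) for a
    normal read.  Breakpoints come from V symbol boundaries, I symbol anchor
    points, and reference gaps/overlaps between consecutive mapped symbols.
    """
    bps = []
    chrom = None
    syms = series.symbols
    for i, s in enumerate(syms):
        if s.kind == "V":
            chrom = chrom or s.chrom
            bps.extend([s.ref_start, s.ref_end])
        elif s.kind == "I":
            anchor = None
            for j in range(i - 1, -1, -1):
                if syms[j].ref_end is not None:
                    anchor = syms[j].ref_end
                    chrom = chrom or syms[j].chrom
                    break
            if anchor is None:
                for j in range(i + 1, len(syms)):
                    if syms[j].ref_start is not None:
                        anchor = syms[j].ref_start
                        chrom = chrom or syms[j].chrom
                        break
            if anchor is not None:
                bps.append(anchor)
    mapped = [s for s in syms if s.kind in ("M", "V")]
    for a, b in zip(mapped, mapped[1:]):
        gap = b.ref_start - a.ref_end
        if abs(gap) >= min_gap:
            bps.extend([a.ref_end, b.ref_start])
            chrom = chrom or a.chrom
    if not bps:
        return None, None
    bps = sorted(bps)
    return bps, (chrom, min(bps), max(bps))


@dataclass
class SignatureCluster:
    """Reads sharing one signature and one aberration placement."""

    signature: str
    reads: List[SymbolSeries]
    breakpoints: List[int]  # per-position medians across members
    chrom: str = ""
    ref_start: int = 0
    ref_end: int = 0
    support: int = 0  # spanning supporting reads

    @property
    def read_names(self):
        return [r.read_name for r in self.reads]


@dataclass
class CandidateLocus:
    chrom: str
    ref_start: int
    ref_end: int
    clusters: List[SignatureCluster] = field(default_factory=list)

    @property
    def supporting_reads(self):
        seen, out = set(), []
        for c in self.clusters:
            for n in c.read_names:
                if n not in seen:
                    seen.add(n)
                    out.append(n)
        return out

    @property
    def support(self) -> int:
        return len(self.supporting_reads)

    @property
    def consensus_signature(self) -> str:
        best = max(self.clusters, key=lambda c: c.support)
        return best.signature

    def dominant_cluster(self) -> SignatureCluster:
        return max(self.clusters, key=lambda c: c.support)


def _spanning(series: SymbolSeries, chrom, start, end, margin=SPAN_MARGIN) -> bool:
    ext = series.ref_extent
    if ext is None or ext[0] != chrom:
        return False
    return ext[1] <= start - margin and ext[2] >= end + margin


def cluster_series(series, min_support: int = DEFAULT_MIN_SUPPORT,
                   position_tolerance: int = DEFAULT_POSITION_TOLERANCE,
                   min_gap: int = DEFAULT_MIN_SV_SIZE,
                   span_margin: int = SPAN_MARGIN) -> List[CandidateLocus]:
    """Cluster aberrant series into candidate loci (one cluster per locus;
    run :func:`merge_adjacent_loci` afterwards to coalesce neighbours).

    Reads with signature ``"M"`` never contribute.  Within one signature,
    single-linkage clustering links reads whose corresponding breakpoints all
    agree within ``position_tolerance``.  Support counts only reads whose
    mapped extent spans the clustered aberration plus ``span_margin``.
    """
    by_sig = {}
    for s in series:
        if not s.is_aberrant:
            continue
        bps, span = aberrant_breakpoints(s, min_gap)
        if bps is None:
            continue
        by_sig.setdefault((s.signature, len(bps)), []).append((s, bps, span))

    loci = []
    for (sig, _nbp), members in by_sig.items():
        members.sort(key=lambda m: m[1][0])
        cluster = []
        for m in members:
            if cluster and any(abs(a - b) > position_tolerance
                               for a, b in zip(m[1], cluster[-1][1])):
                loci.extend(_finish_cluster(sig, cluster, min_support, span_margin))
                cluster = []
            cluster.append(m)
        loci.extend(_finish_cluster(sig, cluster, min_support, span_margin))
    loci.sort(key=lambda l: (l.chrom, l.ref_start, l.ref_end))
    return loci


def _finish_cluster(sig, members, min_support, span_margin):
    if not members:
        return []
    chrom = next((m[2][0] for m in members if m[2][0]), None)
    if chrom is None:
        return []
    bps = [int(statistics.median(v)) for v in zip(*(m[1] for m in members))]
    start, end = min(bps), max(bps)
    end = max(end, start + 1)
    reads = [m[0] for m in members]
    support = sum(_spanning(r, chrom, start, end, span_margin) for r in reads)
    if support < min_support:
        return []
    cl = SignatureCluster(signature=sig, reads=reads, breakpoints=bps,
                          chrom=chrom, ref_start=start, ref_end=end,
                          support=support)
    return [CandidateLocus(chrom=chrom, ref_start=start, ref_end=end,
                           clusters=[cl])]


def merge_adjacent_loci(loci, merge_distance: int = DEFAULT_MERGE_DISTANCE):
    """Merge loci whose windows overlap or lie within ``merge_distance``
    (boundary inclusive); supporting read sets are unioned via cluster lists."""
    loci = sorted(loci, key=lambda l: (l.chrom, l.ref_start, l.ref_end))
    out = []
    for loc in loci:
        if (out and out[-1].chrom == loc.chrom
                and loc.ref_start - out[-1].ref_end <= merge_distance):
            prev = out[-1]
            prev.ref_end = max(prev.ref_end, loc.ref_end)
            prev.ref_start = min(prev.ref_start, loc.ref_start)
            prev.clusters.extend(loc.clusters)
        else:
            out.append(CandidateLocus(chrom=loc.chrom, ref_start=loc.ref_start,
                                      ref_end=loc.ref_end,
                                      clusters=list(loc.clusters)))
    return out


def discover_loci(series, min_support: int = DEFAULT_MIN_SUPPORT,
                  position_tolerance: int = DEFAULT_POSITION_TOLERANCE,
                  merge_distance: int = DEFAULT_MERGE_DISTANCE):
    """cluster + merge in one call."""
    return merge_adjacent_loci(
        cluster_series(series, min_support, position_tolerance),
        merge_distance)


def loci_to_bed(loci) -> str:
    """Debug export."""
    lines = []
    for l in loci:
        lines.append(f"{l.chrom}\t{l.ref_start}\t{l.ref_end}\t"
                     f"{l.consensus_signature}\t{l.support}")
    return "\n".join(lines) + ("\n" if lines else "")
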