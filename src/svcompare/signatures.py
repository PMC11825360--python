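"""Per-read alignment signatures.

Every read is summarised as an ordered series of symbols over the alphabet
{M, V, I}: ``M`` for a forward-mapped segment, ``V`` for a reverse-mapped
segment, and ``I`` for sequence present in the read but absent from the
reference (either an intra-alignment CIGAR insertion or an unmapped stretch
between split alignments).  The series is a model-free 1D summary of how the
read maps — no SV-type-specific pattern matching happens at this stage.

A read whose series is exactly ``"M"`` is a normal read; anything else is
aberrant and becomes input to locus discovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Seq import reverse_complement

# CIGAR operation codes (pysam numeric encoding)
_CMATCH, _CINS, _CDEL, _CREF_SKIP, _CSOFT, _CHARD = 0, 1, 2, 3, 4, 5
_CEQUAL, _CDIFF = 7, 8
_ALN_MATCH_OPS = {_CMATCH, _CEQUAL, _CDIFF}

DEFAULT_MIN_SV_SIZE = 50
DEFAULT_MIN_MAPQ = 20
#: read-coordinate overlap between adjacent symbols tolerated before the
#: series is considered malformed
CLIP_TOLERANCE = 50


@dataclass
class ReadSymbol:
    """One symbol of a read's alignment signature."""

    kind: str  # 'M', 'V' or 'I'
    read_start: int  # forward-read coordinates, 0-based half-open
    read_end: int
    read_name: str
    chrom: Optional[str] = None
    ref_start: Optional[int] = None  # absent for unmapped I
    ref_end: Optional[int] = None
    mapped_flag: bool = False  # I only: inserted sequence realigns elsewhere
    source_ref_span: Optional[tuple] = None  # (chrom, start, end, strand) for mapped I
    seq: Optional[str] = None  # inserted sequence, when recoverable

    @property
    def seq_length(self) -> int:
        return self.read_end - self.read_start

    def __post_init__(self):
        if self.kind not in ("M", "V", "I"):
            raise ValueError(f"unknown symbol kind {self.kind!r}")
        if self.read_end <= self.read_start:
            raise ValueError("empty read span in symbol")
        if self.kind in ("M", "V") and self.ref_start is None:
            raise ValueError(f"{self.kind} symbol requires a reference span")


@dataclass
class SymbolSeries:
    """Ordered symbol series of one read."""

    read_name: str
    symbols: list = field(default_factory=list)

    @property
    def signature(self) -> str:
        return "".join(s.kind for s in self.symbols)

    @property
    def is_aberrant(self) -> bool:
        return self.signature != "M"

    @property
    def ref_extent(self) -> Optional[tuple]:
        """(chrom, start, end) covered by the mapped symbols of this read."""
        mapped = [s for s in self.symbols if s.ref_start is not None and s.kind != "I"]
        if not mapped:
            return None
        chrom = mapped[0].chrom
        return (chrom,
                min(s.ref_start for s in mapped),
                max(s.ref_end for s in mapped))


class SignatureError(ValueError):
    pass


def _record_symbols(aln, min_sv_size):
    """Symbols contributed by a single alignment record.

    Coordinates are first computed in the record's stored orientation (counting
    hard clips as consumed read bases) and converted to forward-read
    coordinates at the end.
    """
    cig = aln.cigartuples
    if cig is None:
        return []
    read_len = aln.infer_read_length()
    # account for a leading hard clip not present in query_sequence
    seq_offset = cig[0][1] if cig and cig[0][0] == _CHARD else 0

    blocks = []  # (ref_s, ref_e, q_s, q_e) aligned sub-blocks, record orientation
    inserts = []  # (q_s, q_e) insertion ops
    rpos = aln.reference_start
    qpos = 0  # clips are consumed inside the loop
    blk_ref_s, blk_q_s = rpos, qpos
    open_block = False
    for op, n in cig:
        if op in _ALN_MATCH_OPS:
            if not open_block:
                blk_ref_s, blk_q_s = rpos, qpos
                open_block = True
            rpos += n
            qpos += n
        elif op == _CINS:
            if n >= min_sv_size:
                if open_block:
                    blocks.append((blk_ref_s, rpos, blk_q_s, qpos))
                    open_block = False
                inserts.append((qpos, qpos + n))
            qpos += n
        elif op in (_CDEL, _CREF_SKIP):
            if n >= min_sv_size:
                if open_block:
                    blocks.append((blk_ref_s, rpos, blk_q_s, qpos))
                    open_block = False
            rpos += n
        elif op in (_CSOFT, _CHARD):
            if open_block:
                blocks.append((blk_ref_s, rpos, blk_q_s, qpos))
                open_block = False
            qpos += n
        # padding ops ignored
    if open_block:
        blocks.append((blk_ref_s, rpos, blk_q_s, qpos))

    reverse = aln.is_reverse
    kind = "V" if reverse else "M"
    chrom = aln.reference_name
    qseq = aln.query_sequence

    def fwd_span(q_s, q_e):
        if reverse:
            return read_len - q_e, read_len - q_s
        return q_s, q_e

    out = []
    for ref_s, ref_e, q_s, q_e in blocks:
        fs, fe = fwd_span(q_s, q_e)
        out.append(ReadSymbol(kind, fs, fe, aln.query_name,
                              chrom=chrom, ref_start=ref_s, ref_end=ref_e))
    for q_s, q_e in inserts:
        seq = None
        if qseq is not None:
            seq = qseq[q_s - seq_offset:q_e - seq_offset]
            if reverse and seq:
                seq = reverse_complement(seq)
        fs, fe = fwd_span(q_s, q_e)
        out.append(ReadSymbol("I", fs, fe, aln.query_name, seq=seq))
    return out


def read_to_symbols(alignments, min_sv_size: int = DEFAULT_MIN_SV_SIZE) -> SymbolSeries:
    """Convert all alignments of one read into its :class:`SymbolSeries`.

    ``alignments`` must contain the primary record and any supplementary
    records of a single read (secondary records are ignored by the caller).
    Raises :class:`SignatureError` if no primary record is present, or if the
    records disagree on the read length.
    """
    alns = [a for a in alignments if not a.is_unmapped and not a.is_secondary]
    if not alns:
        raise SignatureError("no usable alignment records")
    names = {a.query_name for a in alns}
    if len(names) != 1:
        raise SignatureError(f"records from multiple reads: {sorted(names)}")
    primary = [a for a in alns if not a.is_supplementary]
    if not primary:
        raise SignatureError(f"no primary alignment for read {alns[0].query_name}")
    lengths = {a.infer_read_length() for a in alns}
    if len(lengths) != 1:
        raise SignatureError(
            f"inconsistent read lengths across records of {alns[0].query_name}: "
            f"{sorted(lengths)}")
    read_len = lengths.pop()
    name = alns[0].query_name

    # forward-oriented full read sequence, for slicing inter-alignment gaps
    fwd_seq = None
    p = primary[0]
    if p.query_sequence is not None and len(p.query_sequence) == read_len:
        fwd_seq = (reverse_complement(p.query_sequence)
                   if p.is_reverse else p.query_sequence)

    symbols = []
    for a in alns:
        symbols.extend(_record_symbols(a, min_sv_size))
    symbols.sort(key=lambda s: (s.read_start, s.read_end))

    # unmapped stretches between split alignments become unmapped I symbols
    filled = []
    for sym in symbols:
        if filled:
            gap = sym.read_start - filled[-1].read_end
            if gap >= min_sv_size:
                gs, ge = filled[-1].read_end, sym.read_start
                seq = fwd_seq[gs:ge] if fwd_seq else None
                filled.append(ReadSymbol("I", gs, ge, name, seq=seq))
            elif gap < -CLIP_TOLERANCE:
                # overlapping alignments on the read beyond tolerance: trim
                sym = dataclasses.replace(sym, read_start=filled[-1].read_end)
        filled.append(sym)

    # collapse trivial fragmentation: adjacent M (or V) symbols from the same
    # record chain with no reference gap
    return SymbolSeries(read_name=name, symbols=filled)


def fetch_read_groups(bam, chrom, start, end, min_mapq: int = DEFAULT_MIN_MAPQ):
    """Group alignments in a window by read name (primary + supplementary).

    Secondary alignments and records below the mapping-quality floor are
    dropped, matching the external-interface contract of this module.
    """
    groups = {}
    for a in bam.fetch(chrom, max(0, start), end):
        if a.is_unmapped or a.is_secondary:
            continue
        if a.mapping_quality < min_mapq:
            continue
        groups.setdefault(a.query_name, []).append(a)
    return groups


def extract_series(bam, chrom, start, end,
                   min_sv_size: int = DEFAULT_MIN_SV_SIZE,
                   min_mapq: int = DEFAULT_MIN_MAPQ) -> list:
    """Symbol series for every read touching a window. Reads without a primary
    record in the window (clipped fetch) are skipped with no error."""
    out = []
    for name, alns in fetch_read_groups(bam, chrom, start, end, min_mapq).items():
        try:
            out.append(read_to_symbols(alns, min_sv_size))
        except SignatureError:
            continue
    return out


# ---------------------------------------------------------------------------
# mapped-I resolution


def _identity_of(alignment) -> tuple:
    """(identity, aligned_query_length) of a Bio.Align alignment."""
    a, b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    aligned = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    if aligned == 0:
        return 0.0, 0
    qlen = sum(1 for y in b if y != "-")
    return matches / aligned, qlen


def resolve_unmapped_insertion(symbol: ReadSymbol,
                               reference_window: str,
                               window_ref_start: int,
                               chrom: str,
                               min_identity: float = 0.8,
                               min_cov: float = 0.8) -> ReadSymbol:
    """Try to realign an unmapped inserted sequence to the local reference.

    If the inserted sequence aligns (locally, >= ``min_identity`` identity over
    >= ``min_cov`` of its length) to the window in forward orientation the
    symbol becomes a mapped I with a forward source span (duplication
    evidence); a reverse-complement hit gives a reverse source span
    (inverted-duplication evidence).  Otherwise the symbol is returned
    unchanged.
    """
    if symbol.kind != "I" or symbol.mapped_flag:
        return symbol
    if not symbol.seq:
        raise ValueError("cannot realign an insertion with no sequence")
    # fast path: an exact copy (error-free duplication) is a substring
    for strand, query in (("+", symbol.seq),
                          ("-", reverse_complement(symbol.seq))):
        at = reference_window.find(query)
        if at >= 0:
            return dataclasses.replace(
                symbol, mapped_flag=True,
                source_ref_span=(chrom, window_ref_start + at,
                                 window_ref_start + at + len(query), strand))
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1

    best = None  # (score, strand, alignment)
    for strand, query in (("+", symbol.seq),
                          ("-", reverse_complement(symbol.seq))):
        try:
            alns = aligner.align(reference_window, query)
            aln = alns[0] if len(alns) else None
        except (ValueError, OverflowError):
            aln = None
        if aln is not None and (best is None or aln.score > best[0]):
            best = (aln.score, strand, aln)
    if best is None:
        return symbol
    _, strand, aln = best
    ident, qlen = _identity_of(aln)
    if ident < min_identity or qlen < min_cov * len(symbol.seq):
        return symbol
    tgt = aln.aligned[0]
    src_start = int(tgt[0][0]) + window_ref_start
    src_end = int(tgt[-1][1]) + window_ref_start
    return dataclasses.replace(
        symbol, mapped_flag=True,
        source_ref_span=(chrom, src_start, src_end, strand))
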