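"""Offline simulator and evaluation helpers.

Everything the pipeline consumes can be fabricated here with no external
aligner or download: synthetic references, haplotypes with implanted simple
and complex SVs, and coordinate-sorted BAMs whose CIGARs and split records
are computed analytically from the known haplotype-to-reference mapping
(deletion -> D op, insertion/duplication -> I op, inversion ->
forward/reverse/forward split records).  Sequencing noise is modelled as
independent substitutions and single-base indels at profile-dependent rates.

Scenario builders assemble trio / twin / tumor-normal genome sets with known
genotypes, using a K-haplotype representation: a genome is K equally weighted
haplotypes and a variant with allele fraction f lives on round(f*K) of them,
so K=2 gives diploid genotypes and K=100 gives subclonal tumor fractions
down to 0.01.  Scenario read sets use exact-proportion haplotype interleaving
so that carrier counts at every locus are deterministic; plain
``synthesize_alignments`` defaults to binomial sampling.

Scoring (precision/recall/F1 with breakpoint + reciprocal-overlap matching,
CSV subcomponent accuracy, trio genotype accuracy) lives here too.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .masks import TruthComponent, make_truth_mask

#: (substitution rate, single-base indel rate)
ERROR_PROFILES = {
    "perfect": (0.0, 0.0),
    "hifi_like": (0.005, 0.005),
    "ont_like": (0.03, 0.04),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP[_a] = _b


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def simulate_reference(length: int, seed: int, gc: float = 0.5) -> str:
    """Deterministic random reference sequence with the requested GC."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def write_fasta(path, name: str, seq: str) -> str:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")
    pysam.faidx(str(path))
    return str(path)


# ---------------------------------------------------------------------------
# variants and haplotypes


@dataclass
class ComponentSpec:
    """One SV component on the reference. For INS, start == end and ``seq``
    holds the inserted sequence; DUP/INVDUP duplicate [start, end) in tandem."""

    type: str
    start: int
    end: int
    seq: Optional[str] = None

    @property
    def signal_span(self) -> Tuple[int, int]:
        """Where the component's evidence sits on the reference."""
        if self.type == "INS":
            return self.start, self.start + 1
        if self.type in ("DUP", "INVDUP"):
            return self.end, self.end + 1
        return self.start, self.end


@dataclass
class TruthVariant:
    variant_id: str
    chrom: str
    components: List[ComponentSpec]
    genotypes: Dict[str, str] = field(default_factory=dict)
    hap_sets: Dict[str, tuple] = field(default_factory=dict)
    stratum: str = ""

    @property
    def span(self) -> Tuple[int, int]:
        los, his = zip(*(c.signal_span for c in self.components))
        return min(los), max(his)


@dataclass
class _Block:
    kind: str  # 'ref' | 'ins'
    ref_start: int = 0
    ref_end: int = 0
    strand: str = "+"
    seq: Optional[np.ndarray] = None  # ins only

    @property
    def length(self) -> int:
        if self.kind == "ins":
            return len(self.seq)
        return self.ref_end - self.ref_start


class Haplotype:
    """A haplotype as an ordered list of reference/insertion blocks."""

    def __init__(self, blocks: List[_Block]):
        self.blocks = blocks
        self.starts = np.cumsum([0] + [b.length for b in blocks])
        self.length = int(self.starts[-1])

    def pieces(self, s: int, e: int):
        """Decompose haplotype interval [s, e) into read-order pieces:
        ('ref', lo, hi, strand) or ('ins', seq_array)."""
        out = []
        i = int(np.searchsorted(self.starts, s, side="right")) - 1
        while i < len(self.blocks) and self.starts[i] < e:
            b = self.blocks[i]
            h0 = int(self.starts[i])
            a = max(s, h0) - h0
            z = min(e, h0 + b.length) - h0
            if z > a:
                if b.kind == "ins":
                    out.append(("ins", b.seq[a:z]))
                elif b.strand == "+":
                    out.append(("ref", b.ref_start + a, b.ref_start + z, "+"))
                else:
                    out.append(("ref", b.ref_end - z, b.ref_end - a, "-"))
            i += 1
        return out


def build_haplotype(ref_len: int, ref_arr: np.ndarray,
                    components: Sequence[ComponentSpec]) -> Haplotype:
    """Apply non-overlapping components to the reference."""
    comps = sorted(components, key=lambda c: (c.start, c.end))
    blocks: List[_Block] = []
    cursor = 0
    for c in comps:
        if c.start < cursor:
            raise ValueError(
                f"overlapping components at {c.start} (cursor {cursor})")
        if c.start > cursor:
            blocks.append(_Block("ref", cursor, c.start, "+"))
        if c.type == "DEL":
            cursor = c.end
        elif c.type == "INV":
            blocks.append(_Block("ref", c.start, c.end, "-"))
            cursor = c.end
        elif c.type == "INS":
            seq = np.frombuffer(c.seq.encode(), dtype=np.uint8)
            blocks.append(_Block("ins", seq=seq))
            cursor = c.start
        elif c.type in ("DUP", "INVDUP"):
            blocks.append(_Block("ref", c.start, c.end, "+"))
            copy = ref_arr[c.start:c.end]
            if c.type == "INVDUP":
                copy = _revcomp(copy)
            blocks.append(_Block("ins", seq=copy.copy()))
            cursor = c.end
        else:
            raise ValueError(f"unknown component type {c.type!r}")
    if cursor < ref_len:
        blocks.append(_Block("ref", cursor, ref_len, "+"))
    return Haplotype(blocks)


# ---------------------------------------------------------------------------
# read synthesis


def _piece_to_ops(ref_arr, lo, hi, strand, rng, sub_rate, indel_rate):
    n = hi - lo
    base = ref_arr[lo:hi]
    if strand == "-":
        base = _revcomp(base)
    if sub_rate <= 0 and indel_rate <= 0:
        return [("M", n)], base
    ops, segs = [], []
    k_ind = rng.binomial(n, indel_rate) if indel_rate > 0 else 0
    if k_ind:
        pos = np.sort(rng.integers(0, n, size=k_ind))
        kinds = rng.integers(0, 2, size=k_ind)
    else:
        pos, kinds = (), ()
    prev = 0
    for p, kind in zip(pos, kinds):
        p = int(p)
        if p < prev:
            continue
        if p > prev:
            ops.append(("M", p - prev))
            segs.append(base[prev:p])
        if kind == 0:  # single-base deletion error
            ops.append(("D", 1))
            prev = p + 1
        else:  # single-base insertion error
            ops.append(("I", 1))
            segs.append(rng.choice(_BASES, size=1))
            prev = p
    if prev < n:
        ops.append(("M", n - prev))
        segs.append(base[prev:])
    seq = np.concatenate(segs) if segs else np.empty(0, np.uint8)
    if sub_rate > 0 and len(seq):
        k_sub = rng.binomial(len(seq), sub_rate)
        if k_sub:
            seq = seq.copy()
            at = rng.integers(0, len(seq), size=k_sub)
            seq[at] = rng.choice(_BASES, size=k_sub)
    return ops, seq


def _trim_unit(u):
    ops = u["ops"]
    while ops and ops[0][0] != "M":
        op, n = ops.pop(0)
        if op == "I":
            u["q0"] += n
        elif u["strand"] == "+":
            u["ref_lo"] += n
        else:
            u["ref_hi"] -= n
    while ops and ops[-1][0] != "M":
        op, n = ops.pop()
        if op == "I":
            u["q1"] -= n
        elif u["strand"] == "+":
            u["ref_hi"] -= n
        else:
            u["ref_lo"] += n
    merged = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1][1] += n
        elif n > 0:
            merged.append([op, n])
    u["ops"] = merged


def _make_read(hap: Haplotype, ref_arr, start, length, rng, sub_rate,
               indel_rate):
    """Materialise one read: (sequence array, alignment units)."""
    pieces = hap.pieces(start, min(start + length, hap.length))
    q = 0
    seq_parts = []
    units = []
    cur = None
    pending_ins = 0

    def close():
        nonlocal cur
        if cur is not None:
            _trim_unit(cur)
            if sum(n for op, n in cur["ops"] if op == "M") >= 30:
                units.append(cur)
        cur = None

    for piece in pieces:
        if piece[0] == "ins":
            seq_parts.append(piece[1])
            pending_ins += len(piece[1])
            q += len(piece[1])
            continue
        _, lo, hi, strand = piece
        ops, seq_arr = _piece_to_ops(ref_arr, lo, hi, strand, rng,
                                     sub_rate, indel_rate)
        seq_parts.append(seq_arr)
        compatible = (cur is not None and cur["strand"] == strand
                      and ((strand == "+" and lo >= cur["ref_hi"])
                           or (strand == "-" and hi <= cur["ref_lo"])))
        if compatible:
            gap = (lo - cur["ref_hi"]) if strand == "+" else (cur["ref_lo"] - hi)
            if pending_ins:
                cur["ops"].append(("I", pending_ins))
            if gap > 0:
                cur["ops"].append(("D", gap))
            cur["ops"].extend(ops)
            cur["ref_lo"] = min(cur["ref_lo"], lo)
            cur["ref_hi"] = max(cur["ref_hi"], hi)
        else:
            close()
            cur = {"strand": strand, "q0": q, "ops": list(ops),
                   "ref_lo": lo, "ref_hi": hi}
        pending_ins = 0
        q += len(seq_arr)
        cur["q1"] = q
    close()
    seq = (np.concatenate(seq_parts) if seq_parts
           else np.empty(0, np.uint8))
    return seq, units


_OPC = {"M": 0, "I": 1, "D": 2}


def _unit_records(header, name, seq_fwd, units):
    """pysam records of one read (primary = longest aligned unit)."""
    L = len(seq_fwd)
    if not units:
        return []
    aligned = [sum(n for op, n in u["ops"] if op == "M") for u in units]
    primary = int(np.argmax(aligned))
    fwd_str = seq_fwd.tobytes().decode()
    rev_str = _revcomp(seq_fwd).tobytes().decode()
    records = []
    for i, u in enumerate(units):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        flag = 0
        if u["strand"] == "+":
            cig = ([(4, u["q0"])] + [(_OPC[o], n) for o, n in u["ops"]]
                   + [(4, L - u["q1"])])
            a.query_sequence = fwd_str
        else:
            flag |= 16
            cig = ([(4, L - u["q1"])]
                   + [(_OPC[o], n) for o, n in reversed(u["ops"])]
                   + [(4, u["q0"])])
            a.query_sequence = rev_str
        if i != primary:
            flag |= 2048
        a.flag = flag
        a.reference_id = 0
        a.reference_start = int(u["ref_lo"])
        a.mapping_quality = 60
        a.cigartuples = [(op, n) for op, n in cig if n > 0]
        records.append(a)
    return records


def _hap_assignments(n, fractions, mode, rng):
    fractions = np.asarray(fractions, dtype=float)
    fractions = fractions / fractions.sum()
    if mode == "binomial":
        return rng.choice(len(fractions), size=n, p=fractions)
    counts = np.zeros(len(fractions))
    out = np.empty(n, dtype=int)
    for i in range(n):
        h = int(np.argmax(fractions * (i + 1) - counts))
        out[i] = h
        counts[h] += 1
    return out


@dataclass
class ReadMeta:
    name: str
    hap: int
    ext_lo: int
    ext_hi: int


def synthesize_alignments(ref_name: str, ref_seq: str,
                          haplotypes: Sequence[Haplotype],
                          coverage: float, out_bam,
                          read_length: int = 15000,
                          error_profile: str = "perfect",
                          fractions: Optional[Sequence[float]] = None,
                          af_mode: str = "binomial",
                          seed: int = 0) -> List[ReadMeta]:
    """Fabricate a sorted, indexed BAM; returns per-read metadata.

    ``af_mode='binomial'`` draws each read's haplotype independently (carrier
    fractions at a locus are then binomial around the nominal AF);
    ``'exact'`` interleaves haplotypes deterministically with evenly spaced
    read starts so local carrier fractions are exact to within one read.
    """
    rng = np.random.default_rng(seed)
    sub_rate, indel_rate = ERROR_PROFILES[error_profile]
    ref_arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    K = len(haplotypes)
    fracs = fractions if fractions is not None else [1.0 / K] * K
    n_reads = max(1, int(round(coverage * len(ref_seq) / read_length)))
    haps_of = _hap_assignments(n_reads, fracs, af_mode, rng)

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": len(ref_seq)}]})

    all_records = []
    meta = []
    for i in range(n_reads):
        h = int(haps_of[i])
        hap = haplotypes[h]
        max_start = max(hap.length - read_length, 0)
        if af_mode == "exact":
            spacing = max(max_start // max(n_reads - 1, 1), 1)
            start = min(int(round(i * max_start / max(n_reads - 1, 1)))
                        + int(rng.integers(0, spacing + 1)), max_start)
        else:
            start = int(rng.integers(0, max_start + 1))
        name = f"r{i:06d}_h{h}"
        seq, units = _make_read(hap, ref_arr, start, read_length, rng,
                                sub_rate, indel_rate)
        if not units or not len(seq):
            continue
        records = _unit_records(header, name, seq, units)
        all_records.extend(records)
        meta.append(ReadMeta(name, h,
                             min(u["ref_lo"] for u in units),
                             max(u["ref_hi"] for u in units)))
    all_records.sort(key=lambda a: a.reference_start)
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as fh:
        for a in all_records:
            fh.write(a)
    pysam.index(str(out_bam))
    return meta


# ---------------------------------------------------------------------------
# variant generators


_SSV_TYPES = ("DEL", "INS", "INV", "DUP", "INVDUP")
_CSV_TYPES = ("DEL+INV", "INS+DEL", "DEL+DUP", "INV+INVDUP", "DEL+INV+DUP")


def _rand_seq(rng, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def make_components(vtype: str, pos: int, rng,
                    size_range=(400, 1200)) -> List[ComponentSpec]:
    """Component layout of one (possibly complex) variant anchored at pos."""
    def size():
        return int(rng.integers(*size_range))

    if vtype == "DEL":
        return [ComponentSpec("DEL", pos, pos + size())]
    if vtype == "INS":
        return [ComponentSpec("INS", pos, pos, seq=_rand_seq(rng, size()))]
    if vtype == "INV":
        return [ComponentSpec("INV", pos, pos + size())]
    if vtype == "DUP":
        return [ComponentSpec("DUP", pos, pos + size())]
    if vtype == "INVDUP":
        return [ComponentSpec("INVDUP", pos, pos + size())]
    if vtype == "DEL+INV":
        s1, s2 = size(), size()
        return [ComponentSpec("INV", pos, pos + s1),
                ComponentSpec("DEL", pos + s1, pos + s1 + s2)]
    if vtype == "INS+DEL":
        s1, s2 = size(), size()
        return [ComponentSpec("INS", pos, pos, seq=_rand_seq(rng, s1)),
                ComponentSpec("DEL", pos + 60, pos + 60 + s2)]
    if vtype == "DEL+DUP":
        s1, s2 = size(), size()
        return [ComponentSpec("DUP", pos, pos + s1),
                ComponentSpec("DEL", pos + s1 + 60, pos + s1 + 60 + s2)]
    if vtype == "INV+INVDUP":
        s1, s2 = size(), size()
        return [ComponentSpec("INVDUP", pos, pos + s1),
                ComponentSpec("INV", pos + s1 + 60, pos + s1 + 60 + s2)]
    if vtype == "DEL+INV+DUP":
        s1, s2, s3 = size(), size(), size()
        return [ComponentSpec("DUP", pos, pos + s1),
                ComponentSpec("INV", pos + s1 + 60, pos + s1 + 60 + s2),
                ComponentSpec("DEL", pos + s1 + s2 + 120,
                              pos + s1 + s2 + 120 + s3)]
    raise ValueError(f"unknown variant type {vtype!r}")


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class Scenario:
    outdir: str
    ref_name: str
    ref_path: str
    ref_len: int
    bams: Dict[str, str] = field(default_factory=dict)
    read_meta: Dict[str, List[ReadMeta]] = field(default_factory=dict)
    ploidy: Dict[str, int] = field(default_factory=dict)  # haplotypes per genome
    truth: List[TruthVariant] = field(default_factory=list)
    case: str = "case"
    controls: List[str] = field(default_factory=list)
    read_length: int = 8000
    error_profile: str = "perfect"

    def open_bam(self, genome: str):
        return pysam.AlignmentFile(self.bams[genome], "rb")

    def open_ref(self):
        return pysam.FastaFile(self.ref_path)


def _genotype_haps(gt: str, K: int, offset: int = 0) -> tuple:
    n = {"0/0": 0, "0/1": K // 2, "1/1": K}[gt]
    return tuple((offset + j) % K for j in range(n))


def _build_genome_bam(scen: Scenario, genome: str, ref_seq: str,
                      variants: List[TruthVariant], K: int, coverage: float,
                      seed: int, af_mode: str = "exact") -> None:
    ref_arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    haps = []
    for h in range(K):
        comps = [c for tv in variants if h in tv.hap_sets.get(genome, ())
                 for c in tv.components]
        haps.append(build_haplotype(len(ref_seq), ref_arr, comps))
    bam = os.path.join(scen.outdir, f"{genome}.bam")
    meta = synthesize_alignments(
        scen.ref_name, ref_seq, haps, coverage, bam,
        read_length=scen.read_length, error_profile=scen.error_profile,
        af_mode=af_mode, seed=seed)
    scen.bams[genome] = bam
    scen.read_meta[genome] = meta
    scen.ploidy[genome] = K


def realized_af(scenario: Scenario, genome: str, tv: TruthVariant,
                margin: int = 150) -> float:
    """Carrier fraction among reads spanning the variant in this genome."""
    lo, hi = tv.span
    hapset = set(tv.hap_sets.get(genome, ()))
    spanning = carriers = 0
    for r in scenario.read_meta.get(genome, ()):
        if r.ext_lo <= lo - margin and r.ext_hi >= hi + margin:
            spanning += 1
            if r.hap in hapset:
                carriers += 1
    return carriers / spanning if spanning else 0.0


def nominal_af(scenario: Scenario, genome: str, tv: TruthVariant) -> float:
    """Haplotype-fraction allele frequency of a variant in one genome."""
    K = scenario.ploidy.get(genome, 2)
    return len(tv.hap_sets.get(genome, ())) / K


def truth_components_for(scenario: Scenario, genome: str, chrom: str,
                         win_start: int, win_end: int) -> List[TruthComponent]:
    """Truth components of one genome inside a window (for oracle masks).

    AFs are the nominal haplotype fractions: the oracle mask is the ideal
    mask the network is trained toward, so decoding tests measure pure
    quantisation error rather than read-sampling noise."""
    out = []
    for tv in scenario.truth:
        lo, hi = tv.span
        if tv.chrom != chrom or hi <= win_start or lo >= win_end:
            continue
        af = nominal_af(scenario, genome, tv)
        if af <= 0:
            continue
        for c in tv.components:
            s, e = c.signal_span
            if c.type in ("DEL", "INV"):
                out.append(TruthComponent(c.type, c.start, c.end, af))
            else:
                out.append(TruthComponent(c.type, s, s + 1, af))
    return out


class OracleSegmenter:
    """Deterministic segmenter backed by simulator ground truth."""

    #: oracle masks encode exact AFs; no image-based refinement needed
    exact_af = True

    def __init__(self, scenario: Scenario):
        self.scenario = scenario

    def __call__(self, image, case_name: str, control_name: str):
        g = image.geometry
        return make_truth_mask(
            image,
            truth_components_for(self.scenario, case_name, g.chrom,
                                 g.win_start, g.win_end),
            truth_components_for(self.scenario, control_name, g.chrom,
                                 g.win_start, g.win_end))


def _scenario_frame(outdir, n_loci, seed, spacing, read_length,
                    error_profile, ref_seed_offset=0):
    os.makedirs(str(outdir), exist_ok=True)
    ref_len = int((n_loci + 1) * spacing)
    ref_name = "chrS"
    ref_seq = simulate_reference(ref_len, seed + ref_seed_offset)
    ref_path = write_fasta(os.path.join(str(outdir), "ref.fa"),
                           ref_name, ref_seq)
    scen = Scenario(outdir=str(outdir), ref_name=ref_name, ref_path=ref_path,
                    ref_len=ref_len, read_length=read_length,
                    error_profile=error_profile)
    return scen, ref_seq


def build_scenario(kind: str, outdir, params: Optional[dict] = None,
                   seed: int = 0) -> Scenario:
    """Fabricate a complete benchmark scenario (BAMs + truth).

    Kinds: ``sv_panel`` (case vs variant-free control, SSV+CSV grid),
    ``trio_denovo``, ``trio_germline``, ``twin_quartet``, ``tumor_normal``.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed + 7)
    if kind == "sv_panel":
        return _build_sv_panel(outdir, p, seed, rng)
    if kind in ("trio_denovo", "trio_germline"):
        return _build_trio(outdir, p, seed, rng, kind == "trio_denovo")
    if kind == "twin_quartet":
        return _build_twins(outdir, p, seed, rng)
    if kind == "tumor_normal":
        return _build_tumor_normal(outdir, p, seed, rng)
    raise ValueError(f"unknown scenario kind {kind!r}")


def _place_variants(rng, kinds_afs, spacing, chrom, ploidy,
                    size_range=(400, 1200)):
    """One variant per tile of the reference, with per-genome hap sets.

    ``ploidy`` maps genome name -> number of haplotypes for that genome (2
    for diploids, larger for subclonal mixtures)."""
    truth = []
    offset = 0
    for i, (vtype, af_or_gts, stratum) in enumerate(kinds_afs):
        pos = int((i + 1) * spacing - spacing // 4
                  + rng.integers(0, spacing // 10))
        comps = make_components(vtype, pos, rng, size_range)
        tv = TruthVariant(variant_id=f"v{i:03d}", chrom=chrom,
                          components=comps, stratum=stratum)
        for genome, gt in af_or_gts.items():
            K = ploidy[genome]
            if isinstance(gt, str):
                tv.genotypes[genome] = gt
                tv.hap_sets[genome] = _genotype_haps(gt, K, offset % K)
            else:  # raw allele fraction (tumor subclones)
                n = max(int(round(gt * K)), 1) if gt > 0 else 0
                tv.hap_sets[genome] = tuple((offset + j) % K
                                            for j in range(n))
                tv.genotypes[genome] = ("0/0" if n == 0 else
                                        "1/1" if n == K else "0/1")
        offset += max((len(s) for s in tv.hap_sets.values()), default=1)
        truth.append(tv)
    return truth


def _build_sv_panel(outdir, p, seed, rng):
    types = p.get("types", list(_SSV_TYPES) + list(_CSV_TYPES))
    afs = p.get("afs", [0.1, 0.5, 1.0])
    n_loci = p.get("n_loci", 50)
    coverage = p.get("coverage", 160)
    read_length = p.get("read_length", 8000)
    K = p.get("n_haplotypes", 10)
    spacing = read_length + 4000
    scen, ref_seq = _scenario_frame(outdir, n_loci, seed, spacing,
                                    read_length,
                                    p.get("error_profile", "perfect"))
    kinds_afs = []
    for i in range(n_loci):
        vtype = types[i % len(types)]
        af = afs[(i // len(types)) % len(afs)]
        kinds_afs.append((vtype, {"case": af}, f"af={af}"))
    scen.truth = _place_variants(rng, kinds_afs, spacing, scen.ref_name,
                                 {"case": K, "control": K})
    scen.case, scen.controls = "case", ["control"]
    _build_genome_bam(scen, "case", ref_seq, scen.truth, K, coverage, seed + 1)
    _build_genome_bam(scen, "control", ref_seq, scen.truth, K,
                      p.get("control_coverage", 60), seed + 2)
    return scen


_TRIO_GT_PATTERNS = [  # (child, father, mother), Mendelian-consistent
    ("0/1", "0/1", "0/0"), ("0/1", "0/0", "0/1"), ("0/1", "1/1", "0/0"),
    ("0/1", "0/0", "1/1"), ("1/1", "0/1", "0/1"), ("1/1", "1/1", "0/1"),
    ("0/1", "0/1", "0/1"), ("1/1", "1/1", "1/1"),
]


def _build_trio(outdir, p, seed, rng, with_denovo):
    n_denovo = p.get("n_denovo", 5) if with_denovo else 0
    n_inherited = p.get("n_inherited", 15)
    types = p.get("types", list(_CSV_TYPES) + list(_SSV_TYPES))
    coverage = p.get("coverage", 40)
    read_length = p.get("read_length", 8000)
    spacing = read_length + 4000
    n_loci = n_denovo + n_inherited
    scen, ref_seq = _scenario_frame(outdir, n_loci, seed, spacing,
                                    read_length,
                                    p.get("error_profile", "perfect"))
    kinds_afs = []
    for i in range(n_loci):
        vtype = types[i % len(types)]
        if i < n_denovo:
            gts = {"child": "0/1", "father": "0/0", "mother": "0/0"}
            stratum = "denovo"
        else:
            c, f, m = _TRIO_GT_PATTERNS[int(rng.integers(len(_TRIO_GT_PATTERNS)))]
            gts = {"child": c, "father": f, "mother": m}
            stratum = "inherited"
        kinds_afs.append((vtype, gts, stratum))
    rng.shuffle(kinds_afs)
    scen.truth = _place_variants(rng, kinds_afs, spacing, scen.ref_name,
                                 {"child": 2, "father": 2, "mother": 2})
    scen.case, scen.controls = "child", ["father", "mother"]
    for g_i, genome in enumerate(["child", "father", "mother"]):
        _build_genome_bam(scen, genome, ref_seq, scen.truth, 2, coverage,
                          seed + 11 + g_i)
    return scen


def _build_twins(outdir, p, seed, rng):
    n_loci = p.get("n_loci", 15)
    types = p.get("types", list(_SSV_TYPES))
    coverage = p.get("coverage", 40)
    read_length = p.get("read_length", 8000)
    spacing = read_length + 4000
    scen, ref_seq = _scenario_frame(outdir, n_loci, seed, spacing,
                                    read_length,
                                    p.get("error_profile", "perfect"))
    kinds_afs = []
    for i in range(n_loci):
        c, f, m = _TRIO_GT_PATTERNS[int(rng.integers(len(_TRIO_GT_PATTERNS)))]
        gts = {"child1": c, "child2": c, "father": f, "mother": m}
        kinds_afs.append((types[i % len(types)], gts, "twin"))
    scen.truth = _place_variants(rng, kinds_afs, spacing, scen.ref_name,
                                 {"child1": 2, "child2": 2, "father": 2,
                                  "mother": 2})
    scen.case, scen.controls = "child1", ["father", "mother"]
    for g_i, genome in enumerate(["child1", "child2", "father", "mother"]):
        _build_genome_bam(scen, genome, ref_seq, scen.truth, 2, coverage,
                          seed + 23 + g_i)
    return scen


def _build_tumor_normal(outdir, p, seed, rng):
    af_grid = p.get("af_grid", [0.01, 0.02, 0.05, 0.10])
    n_per_af = p.get("n_per_af", 5)
    n_germline = p.get("n_germline", 4)
    types = p.get("types", list(_SSV_TYPES))
    csv_types = p.get("csv_types", [])
    tumor_cov = p.get("tumor_coverage", 300)
    normal_cov = p.get("normal_coverage", 30)
    read_length = p.get("read_length", 8000)
    K = p.get("n_haplotypes", 100)
    spacing = read_length + 4000
    all_types = list(types) + list(csv_types)
    kinds_afs = []
    i = 0
    for af in af_grid:
        for _ in range(n_per_af):
            kinds_afs.append((all_types[i % len(all_types)],
                              {"tumor": af, "normal": 0.0}, f"af={af}"))
            i += 1
    for _ in range(n_germline):
        gt = ["0/1", "1/1"][int(rng.integers(2))]
        kinds_afs.append((all_types[i % len(all_types)],
                          {"tumor": gt, "normal": gt}, "germline"))
        i += 1
    scen, ref_seq = _scenario_frame(outdir, len(kinds_afs), seed, spacing,
                                    read_length,
                                    p.get("error_profile", "hifi_like"))
    scen.truth = _place_variants(rng, kinds_afs, spacing, scen.ref_name,
                                 {"tumor": K, "normal": 2},
                                 size_range=p.get("size_range", (400, 1000)))
    scen.case, scen.controls = "tumor", ["normal"]
    _build_genome_bam(scen, "tumor", ref_seq, scen.truth, K, tumor_cov,
                      seed + 31)
    _build_genome_bam(scen, "normal", ref_seq, scen.truth, 2, normal_cov,
                      seed + 32)
    return scen


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ScoreResult:
    precision: float
    recall: float
    f1: float
    n_calls: int
    n_truth: int
    matches: List[tuple] = field(default_factory=list)  # (call, truth)
    false_negatives: List[TruthVariant] = field(default_factory=list)
    false_positives: List[object] = field(default_factory=list)
    per_stratum: Dict[str, tuple] = field(default_factory=dict)


def _truth_is_point(tv: TruthVariant) -> bool:
    lo, hi = tv.span
    return hi - lo <= 2


def _call_span(call) -> Tuple[str, int, int]:
    return call.chrom, call.ref_start, call.ref_end


def score_calls(calls, truth: List[TruthVariant], bp_tol: int = 500,
                reciprocal: float = 0.5) -> ScoreResult:
    """Region-based precision/recall/F1 against a truth set.

    A call matches a truth variant when their start positions agree within
    ``bp_tol`` and, for span events, reciprocal overlap reaches
    ``reciprocal``; matching is greedy one-to-one by distance.
    """
    unmatched_calls = list(calls)
    matches = []
    fns = []
    for tv in truth:
        lo, hi = tv.span
        best, best_d = None, None
        for call in unmatched_calls:
            chrom, cs, ce = _call_span(call)
            if chrom != tv.chrom:
                continue
            d = abs(cs - lo)
            if d > bp_tol:
                continue
            if not _truth_is_point(tv):
                ov = min(ce, hi) - max(cs, lo)
                if ov <= 0:
                    continue
                if ov < reciprocal * (hi - lo) or ov < reciprocal * (ce - cs):
                    continue
            if best is None or d < best_d:
                best, best_d = call, d
        if best is not None:
            matches.append((best, tv))
            unmatched_calls.remove(best)
        else:
            fns.append(tv)
    n_calls, n_truth = len(list(calls)), len(truth)
    tp = len(matches)
    precision = tp / n_calls if n_calls else 0.0
    recall = tp / n_truth if n_truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    per_stratum = {}
    for stratum in sorted({tv.stratum for tv in truth}):
        n_s = sum(tv.stratum == stratum for tv in truth)
        tp_s = sum(tv.stratum == stratum for _, tv in matches)
        per_stratum[stratum] = (tp_s, n_s)
    return ScoreResult(precision, recall, f1, n_calls, n_truth, matches,
                       fns, unmatched_calls, per_stratum)


def csv_subcomponent_accuracy(matches) -> float:
    """Fraction of matched call/truth pairs where every truth component type
    is present in the called components."""
    if not matches:
        return 0.0
    ok = 0
    for call, tv in matches:
        called = list(getattr(call, "joined_type", "").split("+"))
        good = True
        for c in tv.components:
            if c.type in called:
                called.remove(c.type)
            else:
                good = False
                break
        ok += good
    return ok / len(matches)


def trio_genotype_accuracy(calls, scenario: Scenario,
                           bp_tol: int = 500) -> float:
    """Fraction of truth loci whose matched call reproduces all three trio
    genotypes (unmatched truth counts as inaccurate)."""
    res = score_calls(calls, scenario.truth, bp_tol=bp_tol)
    ok = 0
    for call, tv in res.matches:
        if call.genotype_case != tv.genotypes.get(scenario.case):
            continue
        if all(call.genotypes_control.get(ctrl) == tv.genotypes.get(ctrl)
               for ctrl in scenario.controls):
            ok += 1
    return ok / len(scenario.truth) if scenario.truth else 0.0


def trio_records_from_calls(calls, scenario: Scenario):
    """(child, father, mother) genotype tuples of every call, for Mendelian
    consistency."""
    out = []
    for call in calls:
        out.append((call.genotype_case,
                    call.genotypes_control.get(scenario.controls[0], "0/0"),
                    call.genotypes_control.get(scenario.controls[1], "0/0")))
    return out
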