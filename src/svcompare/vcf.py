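"""Plain-text VCF 4.2 output (and a matching reader, used for scoring).

One record per call.  Single-component calls use the symbolic ALT of their
component (<DEL>, <INS>, <INV>, <DUP>, <INVDUP>); complex calls use <CSV>
with the joined type in INFO/JOINTYPE.  Per-component breakpoints and AFs go
to INFO/COMPONENTS, per-control comparison categories to INFO/CATEGORY.
Coordinates are converted to VCF's 1-based convention on output only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .interpret import SVCall

_HEADER = """\
##fileformat=VCFv4.2
##source=svcompare
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=INV,Description="Inversion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INVDUP,Description="Inverted duplication">
##ALT=<ID=CSV,Description="Complex SV with multiple components">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type (joined component types)">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=JOINTYPE,Number=1,Type=String,Description="Joined component types in read order">
##INFO=<ID=COMPONENTS,Number=.,Type=String,Description="type:start-end:af per component">
##INFO=<ID=CATEGORY,Number=.,Type=String,Description="control:category per control genome">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">
##INFO=<ID=AF,Number=1,Type=Float,Description="Case allele fraction">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _alt_of(call: SVCall) -> str:
    if len(call.components) == 1:
        return f"<{call.components[0].component_type}>"
    return "<CSV>"


def _svlen(call: SVCall) -> int:
    lens = []
    for c in call.components:
        if c.insertion_length is not None:
            lens.append(c.insertion_length)
        else:
            lens.append(c.ref_end - c.ref_start)
    return max(lens) if lens else 0


def write_vcf(calls: List[SVCall], path, case_name: str = "case",
              control_names: Optional[List[str]] = None,
              contigs: Optional[Dict[str, int]] = None) -> None:
    control_names = control_names or sorted(
        {n for c in calls for n in c.comparisons})
    lines = [_HEADER.rstrip("\n")]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    samples = [case_name] + list(control_names)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for i, call in enumerate(sorted(calls, key=lambda c: (c.chrom, c.ref_start))):
        comps = ",".join(
            f"{c.component_type}:{c.ref_start + 1}-{c.ref_end}:"
            f"{c.allele_fraction:.3f}" for c in call.components)
        cats = ",".join(
            f"{name}:{_categories_of(call, name)}"
            for name in control_names if name in call.comparisons)
        info = (f"SVTYPE={call.joined_type};END={call.ref_end};"
                f"SVLEN={_svlen(call)};JOINTYPE={call.joined_type};"
                f"COMPONENTS={comps};SUPPORT={call.support};"
                f"AF={call.allele_fraction:.3f}")
        if cats:
            info += f";CATEGORY={cats}"
        gts = [call.genotype_case] + [
            call.genotypes_control.get(n, "./.") for n in control_names]
        lines.append("\t".join([
            call.chrom, str(call.ref_start + 1), f"svc_{i}", "N",
            _alt_of(call), ".", call.filter, info, "GT", *gts]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _categories_of(call: SVCall, control: str) -> str:
    entries = call.comparisons[control]
    return "|".join(e.category.replace(" ", "_") for e in entries)


@dataclass
class VCFRecord:
    chrom: str
    start: int  # back to 0-based
    end: int
    id: str
    alt: str
    joined_type: str
    components: List[tuple] = field(default_factory=list)  # (type, s, e, af)
    categories: Dict[str, List[str]] = field(default_factory=dict)
    support: int = 0
    af: float = 0.0
    genotypes: Dict[str, str] = field(default_factory=dict)


def read_vcf(path) -> List[VCFRecord]:
    records = []
    samples: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            comps = []
            for c in info.get("COMPONENTS", "").split(","):
                if not c:
                    continue
                ctype, span, af = c.rsplit(":", 2)
                s, e = span.split("-")
                comps.append((ctype, int(s) - 1, int(e), float(af)))
            cats = {}
            for c in info.get("CATEGORY", "").split(","):
                if not c:
                    continue
                name, cat = c.split(":", 1)
                cats[name] = [x.replace("_", " ") for x in cat.split("|")]
            gts = dict(zip(samples, f[9:]))
            records.append(VCFRecord(
                chrom=f[0], start=int(f[1]) - 1, end=int(info.get("END", f[1])),
                id=f[2], alt=f[4],
                joined_type=info.get("JOINTYPE", info.get("SVTYPE", "")),
                components=comps, categories=cats,
                support=int(info.get("SUPPORT", 0)),
                af=float(info.get("AF", 0.0)), genotypes=gts))
    return records
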