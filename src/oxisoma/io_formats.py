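"""Readers and writers for every on-disk format the pipeline touches.

Coordinate conventions follow each format's own standard: pileup tables,
VCF and gene models are 1-based inclusive; :class:`RegionMask` is BED-style
0-based half-open.

The pileup dialect is a plain TSV (documented in the README) rather than
samtools' encoded pileup string, because read-pair orientation (F1R2/F2R1)
-- which the oxidative-damage artifact filter needs -- is not representable
in classic mpileup text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")
#: order of the four count cells carried per allele
CELLS = ("fwd_f1r2", "fwd_f2r1", "rev_f1r2", "rev_f2r1")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(base: str) -> str:
    """Complement of a single base (or string, position-wise)."""
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSequence:
    """A named uppercase DNA sequence restricted to A/C/G/T/N."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("reference sequence must be non-empty")
        if re.search(r"[^ACGTN]", self.bases):
            raise ValueError("reference alphabet restricted to A/C/G/T/N")

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.bases):
            raise IndexError(f"position {pos} outside reference of length {len(self.bases)}")
        return self.bases[pos - 1]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSequence":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        rec = records[0]
        return cls(name=rec.id, bases=str(rec.seq).upper())

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write([SeqRecord(Seq(self.bases), id=self.name, description="")], str(path), "fasta")


# ---------------------------------------------------------------------------
# Per-site read evidence
# ---------------------------------------------------------------------------


@dataclass
class SiteCounts:
    """Read evidence for one site in one tissue.

    ``counts`` maps each base to the four-cell breakdown
    (forward/F1R2, forward/F2R1, reverse/F1R2, reverse/F2R1).
    Base and mapping qualities are carried as per-allele / per-site means
    because the calling thresholds are applied as admission criteria.
    """

    chrom: str
    pos: int
    ref_base: str
    counts: dict[str, tuple[int, int, int, int]]
    mean_bq: dict[str, float]
    mean_mq: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based (got {self.pos})")
        if self.ref_base not in BASES:
            raise ValueError(f"unknown ref base {self.ref_base!r}")
        for base in BASES:
            cells = self.counts.setdefault(base, (0, 0, 0, 0))
            if len(cells) != 4 or any(c < 0 for c in cells):
                raise ValueError(f"invalid count cells for {base}: {cells}")
            self.mean_bq.setdefault(base, 0.0)

    @property
    def depth(self) -> int:
        return sum(sum(cells) for cells in self.counts.values())

    def allele_depth(self, base: str) -> int:
        return sum(self.counts[base])

    def vaf(self, base: str) -> float:
        d = self.depth
        return self.allele_depth(base) / d if d else 0.0

    def strand_split(self, base: str) -> tuple[int, int]:
        """(forward, reverse) read counts supporting ``base``."""
        f1, f2, r1, r2 = self.counts[base]
        return f1 + f2, r1 + r2

    def orientation_split(self, base: str) -> tuple[int, int]:
        """(F1R2, F2R1) read counts supporting ``base``."""
        f1, f2, r1, r2 = self.counts[base]
        return f1 + r1, f2 + r2


_PILEUP_HEADER = [
    "chrom", "pos", "ref",
    "A", "C", "G", "T",
    "bq_A", "bq_C", "bq_G", "bq_T",
    "mq",
]


def read_pileup_table(path: str | Path) -> list[SiteCounts]:
    """Read the documented pileup TSV dialect (one row per site per tissue)."""
    sites: list[SiteCounts] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PILEUP_HEADER:
            raise ValueError(f"{path}: unexpected pileup header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_PILEUP_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_PILEUP_HEADER)} fields, got {len(fields)}")
            try:
                pos = int(fields[1])
                counts = {}
                for i, base in enumerate(BASES):
                    cells = tuple(int(x) for x in fields[3 + i].split(","))
                    if len(cells) != 4:
                        raise ValueError("expected 4 comma-joined cells")
                    counts[base] = cells
                mean_bq = {base: float(fields[7 + i]) for i, base in enumerate(BASES)}
                mean_mq = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            try:
                sites.append(SiteCounts(fields[0], pos, fields[2], counts, mean_bq, mean_mq))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return sites


def write_pileup_table(sites: Iterable[SiteCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PILEUP_HEADER) + "\n")
        for s in sites:
            row = [s.chrom, str(s.pos), s.ref_base]
            row += [",".join(str(c) for c in s.counts[b]) for b in BASES]
            row += [f"{s.mean_bq[b]:g}" for b in BASES]
            row.append(f"{s.mean_mq:g}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Region masks (BED semantics)
# ---------------------------------------------------------------------------


class RegionMask:
    """Union of genomic intervals, 0-based half-open (BED convention)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (start < end required)")
            if start < 0:
                raise ValueError("negative interval start")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = [ivs[0]]
            for s, e in ivs[1:]:
                ls, le = merged[-1]
                if s <= le:
                    merged[-1] = (ls, max(le, e))
                else:
                    merged.append((s, e))
            self._merged[chrom] = merged

    def intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._merged):
            for s, e in self._merged[chrom]:
                yield chrom, s, e

    def __len__(self) -> int:
        return sum(len(v) for v in self._merged.values())

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position in the interval union."""
        import bisect

        ivs = self._merged.get(chrom)
        if not ivs:
            return False
        i = bisect.bisect_right([s for s, _ in ivs], pos0) - 1
        return i >= 0 and ivs[i][0] <= pos0 < ivs[i][1]

    def contains_site(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based site position."""
        return self.contains(chrom, pos - 1)

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionMask":
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: BED line needs >=3 fields")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.intervals():
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Gene models (GFF-lite)
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A single-transcript gene: genomic span plus ordered CDS segments.

    CDS segments are 1-based inclusive and listed 5'->3' in transcription
    order (genomically ascending on '+', descending on '-'); their total
    length must be a multiple of three.
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.gene_start > self.gene_end:
            raise ValueError(f"{self.gene_id}: gene_start > gene_end")
        spans = sorted((s, e) for s, e in self.cds)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS segments")
        expected = spans if self.strand == "+" else spans[::-1]
        if list(self.cds) != expected:
            raise ValueError(f"{self.gene_id}: CDS segments not in transcription order")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def length(self) -> int:
        """Genomic span in bp (the quantity used by the long-gene test)."""
        return self.gene_end - self.gene_start + 1

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.gene_start <= pos <= self.gene_end

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic ``pos`` within the spliced CDS, or None."""
        off = 0
        for s, e in self.cds:
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        return None

    def cds_sequence(self, reference: ReferenceSequence) -> str:
        parts = []
        for s, e in self.cds:
            seg = reference.bases[s - 1:e]
            if self.strand == "-":
                seg = reverse_complement(seg)
            parts.append(seg)
        return "".join(parts)


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Parse GFF-lite: tab-separated gene_id, chrom, strand, feature, start, end.

    ``gene`` rows define the genomic span (UTRs included); ``CDS`` rows add
    coding segments. A gene without an explicit ``gene`` row spans its CDS.
    """
    spans: dict[str, tuple[str, str, int, int]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields")
            gid, chrom, strand, feature, start, end = fields
            start, end = int(start), int(end)
            if feature == "gene":
                spans[gid] = (chrom, strand, start, end)
            elif feature == "CDS":
                cds.setdefault(gid, []).append((start, end))
                if gid not in spans:
                    spans[gid] = (chrom, strand, start, end)
                else:
                    c, s, a, b = spans[gid]
                    spans[gid] = (c, s, min(a, start), max(b, end))
            else:
                raise ValueError(f"{path}:{lineno}: unknown feature {feature!r}")
    genes = {}
    for gid, (chrom, strand, start, end) in spans.items():
        segs = sorted(cds.get(gid, []))
        if strand == "-":
            segs = segs[::-1]
        genes[gid] = GeneModel(gid, chrom, strand, start, end, segs)
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\tgene\t{g.gene_start}\t{g.gene_end}\n")
            for s, e in g.cds:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\tCDS\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {set name: member genes} (members de-duplicated)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields (name, description, members)")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = sorted(set(sets[name]))
            fh.write("\t".join([name, "na"] + members) + "\n")


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_FILTER_DEFS = {
    "strand_bias": "More than the allowed fraction of variant reads on one strand",
    "orientation_bias": "All variant reads in a single read-pair orientation (F1R2 or F2R1)",
    "identity_region": "Site falls in a region with high identity to another genomic region",
}


def write_vcf(calls: Sequence, path: str | Path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write paired calls as VCF 4.2 with SOMATIC_P/STATUS/VAF INFO keys.

    ``calls`` must be sorted by (chrom, pos); FILTER reflects artifact-filter
    flags (``PASS`` when none are set).
    """
    keys = [(c.chrom, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SOMATIC_P,Number=1,Type=Float,Description="One-sided Fisher exact somatic p-value">\n')
        fh.write('##INFO=<ID=STATUS,Number=1,Type=String,Description="Reference/Germline/Somatic/Undetermined">\n')
        fh.write('##INFO=<ID=VAF_T1,Number=1,Type=Float,Description="Variant allele frequency in tissue 1">\n')
        fh.write('##INFO=<ID=VAF_T2,Number=1,Type=Float,Description="Variant allele frequency in tissue 2">\n')
        for name, desc in _VCF_FILTER_DEFS.items():
            fh.write(f'##FILTER=<ID={name},Description="{desc}">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            alt = c.alt_base or "."
            filt = ";".join(sorted(c.filter_flags)) if c.filter_flags else "PASS"
            status = c.status.value if hasattr(c.status, "value") else str(c.status)
            info = (
                f"SOMATIC_P={c.somatic_p:.6g};STATUS={status};"
                f"VAF_T1={c.gt1.vaf:.6g};VAF_T2={c.gt2.vaf:.6g}"
            )
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref_base}\t{alt}\t.\t{filt}\t{info}\n")


@dataclass
class VcfCall:
    """Minimal record parsed back from this package's own VCF output."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str | None
    filter_flags: set[str]
    status: str
    somatic_p: float
    vaf_t1: float
    vaf_t2: float

    @property
    def key(self) -> tuple[str, int, str | None]:
        return (self.chrom, self.pos, self.alt_base)


def read_vcf_calls(path: str | Path) -> list[VcfCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, filt, info = line.rstrip("\n").split("\t")[:8]
            kv = dict(item.split("=", 1) for item in info.split(";") if "=" in item)
            flags = set() if filt in ("PASS", ".") else set(filt.split(";"))
            calls.append(
                VcfCall(
                    chrom=chrom,
                    pos=int(pos),
                    ref_base=ref,
                    alt_base=None if alt == "." else alt,
                    filter_flags=flags,
                    status=kv.get("STATUS", "Undetermined"),
                    somatic_p=float(kv.get("SOMATIC_P", "1")),
                    vaf_t1=float(kv.get("VAF_T1", "0")),
                    vaf_t2=float(kv.get("VAF_T2", "0")),
                )
            )
    return calls
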