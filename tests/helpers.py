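"""Shared constructors for hand-built pileup sites and call shims."""

from types import SimpleNamespace

from oxisoma.io_formats import BASES, SiteCounts


def split_cells(n: int) -> tuple[int, int, int, int]:
    """Spread n reads as evenly as possible over the four strand/orientation cells."""
    q, r = divmod(n, 4)
    return tuple(q + (1 if i < r else 0) for i in range(4))


def make_site(
    ref_base: str = "G",
    pos: int = 100,
    chrom: str = "chr1",
    mq: float = 60.0,
    bq: float = 37.0,
    **allele_counts,
):
    """Build a SiteCounts; allele counts are ints (balanced cells) or 4-tuples."""
    counts = {}
    for base in BASES:
        val = allele_counts.get(base, 0)
        counts[base] = tuple(val) if isinstance(val, (tuple, list)) else split_cells(val)
    bqs = {base: (bq if sum(counts[base]) else 0.0) for base in BASES}
    return SiteCounts(chrom, pos, ref_base, counts, bqs, mq)


def fourteen_record_validation_fixture():
    """14 evaluable amplicon records, 10 satisfying the conjunctive rule."""
    from oxisoma.validation_concordance import validate_site

    def rec(disc=(0.40, 0.05), val=(0.30, 0.10), reads=(150, 10)):
        return validate_site("s", disc[0], disc[1], val[0], val[1], reads[0], reads[1])

    records = [rec() for _ in range(10)]                 # pass
    records.append(rec(reads=(90, 10)))                  # too few reads
    records.append(rec(val=(0.15, 0.10)))                # below two-fold
    records.append(rec(disc=(0.05, 0.40)))               # direction flip
    records.append(rec(val=(0.0, 0.0), reads=(0, 0)))    # no variant signal
    return records


def call_shim(ref_base, alt_base, pos=100, chrom="chr1", vaf1=0.0, vaf2=0.0):
    """Lightweight stand-in for a paired call in spectrum/zygosity/context tests."""
    return SimpleNamespace(
        chrom=chrom,
        pos=pos,
        ref_base=ref_base,
        alt_base=alt_base,
        gt1=SimpleNamespace(vaf=vaf1),
        gt2=SimpleNamespace(vaf=vaf2),
    )
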