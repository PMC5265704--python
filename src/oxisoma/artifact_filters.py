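"""Post-calling exclusion filters for sequencing artifacts.

Three filters, applied independently and order-independently:

* strand bias   -- more than a configurable fraction (default 90%) of the
  variant-supporting reads on one strand;
* orientation bias -- *all* variant-supporting reads in a single read-pair
  orientation (F1R2 or F2R1), the hallmark of oxidative (8-oxo-dG)
  shearing-stress artifacts;
* identity region  -- the site falls in a region with >= 87% identity to
  another genomic region (mask normally user-supplied as BED;
  :func:`build_identity_mask` constructs one for small synthetic
  references).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import RegionMask, ReferenceSequence, SiteCounts


@dataclass(frozen=True)
class FilterOutcome:
    site_key: tuple[str, int, str | None]
    flags: frozenset[str]

    @property
    def kept(self) -> bool:
        return not self.flags


def strand_bias_filter(site: SiteCounts, alt_base: str, max_strand_bias: float = 0.90) -> bool:
    """True (pass) unless more than ``max_strand_bias`` of variant reads sit on one strand."""
    fwd, rev = site.strand_split(alt_base)
    total = fwd + rev
    if total == 0:
        raise ValueError("strand_bias_filter requires >=1 variant-supporting read")
    return max(fwd, rev) / total <= max_strand_bias


def orientation_bias_filter(site: SiteCounts, alt_base: str) -> bool:
    """True (pass) unless every variant-supporting read is F1R2, or every one F2R1."""
    f1r2, f2r1 = site.orientation_split(alt_base)
    if f1r2 + f2r1 == 0:
        raise ValueError("orientation_bias_filter requires >=1 variant-supporting read")
    return f1r2 > 0 and f2r1 > 0


def identity_mask_filter(site: SiteCounts, mask: RegionMask) -> bool:
    """True (pass) unless the site position intersects the mask union."""
    return not mask.contains_site(site.chrom, site.pos)


def apply_filters(
    call,
    mask: RegionMask | None = None,
    max_strand_bias: float = 0.90,
    read_bias: bool = True,
) -> FilterOutcome:
    """Evaluate all filters for one paired call and record flags on it.

    Read-bias filters (strand/orientation) are evaluated on the
    variant-carrying tissue -- the tissue with the higher VAF -- since that
    is where artifact support lives; they are skipped when the call has no
    variant reads there. The identity filter needs only the coordinate.
    """
    flags: set[str] = set()
    if read_bias and call.alt_base is not None:
        var_site = call.site1 if call.gt1.vaf >= call.gt2.vaf else call.site2
        if var_site.allele_depth(call.alt_base) > 0:
            if not strand_bias_filter(var_site, call.alt_base, max_strand_bias):
                flags.add("strand_bias")
            if not orientation_bias_filter(var_site, call.alt_base):
                flags.add("orientation_bias")
    if mask is not None and not identity_mask_filter(call.site1, mask):
        flags.add("identity_region")
    call.filter_flags = set(flags)
    return FilterOutcome(site_key=call.key, flags=frozenset(flags))


def build_identity_mask(
    reference: ReferenceSequence,
    window: int = 100,
    min_identity: float = 0.87,
) -> RegionMask:
    """Mask windows whose best ungapped match elsewhere reaches ``min_identity``.

    Every pair of non-overlapping windows at every ungapped offset is
    examined (shift enumeration with windowed match sums), so the result is
    exact, deterministic, and O(L^2) -- intended for the small synthetic
    references this package simulates, not a BLAST replacement.
    """
    if window < 20:
        raise ValueError("window must be >= 20")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    seq = reference.bases
    length = len(seq)
    if length < 2 * window:
        return RegionMask()
    x = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_windows = length - window + 1
    hit = np.zeros(n_windows, dtype=bool)
    min_matches = math.ceil(min_identity * window - 1e-9)
    for shift in range(window, length - window + 1):
        eq = (x[:-shift] == x[shift:]).astype(np.int32)
        csum = np.cumsum(eq)
        wsum = csum[window - 1:].copy()
        wsum[1:] -= csum[:-window]
        # wsum[i] = matches between windows starting at i and i+shift
        n_valid = length - shift - window + 1
        if n_valid <= 0:
            break
        idx = np.nonzero(wsum[:n_valid] >= min_matches)[0]
        if idx.size:
            hit[idx] = True
            hit[idx + shift] = True
    starts = np.nonzero(hit)[0]
    intervals = [(reference.name, int(s), int(s) + window) for s in starts]
    return RegionMask(intervals)
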