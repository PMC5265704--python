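"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths of the implementations they check:
the Fisher oracle enumerates tables via log-factorials, the ORA oracle sums
rational hypergeometric terms, BH follows the step-up definition, and the
annotation oracle re-translates whole transcripts.
"""

import math
from fractions import Fraction
from math import comb

from Bio.Seq import Seq

from oxisoma.io_formats import ReferenceSequence


def fisher_tail_oracle(counts1, counts2):
    """Enumerate every 2x2 table with the observed margins; sum the tissue-2 tail."""
    r1, v1 = counts1
    r2, v2 = counts2
    n1, n2 = r1 + v1, r2 + v2
    total, var_total = n1 + n2, v1 + v2
    lg = math.lgamma

    def log_prob(k):  # probability tissue 2 holds k variant reads
        if k > var_total or n2 - k > total - var_total or k < 0 or n2 - k < 0:
            return None
        return (
            lg(var_total + 1) - lg(k + 1) - lg(var_total - k + 1)
            + lg(total - var_total + 1) - lg(n2 - k + 1) - lg(total - var_total - (n2 - k) + 1)
            - (lg(total + 1) - lg(n2 + 1) - lg(total - n2 + 1))
        )

    tail = 0.0
    for k in range(v2, min(var_total, n2) + 1):
        lp = log_prob(k)
        if lp is not None:
            tail += math.exp(lp)
    return min(tail, 1.0)


def ora_tail_oracle(k, N, K, n):
    """Exact hypergeometric upper tail P(X >= k) in rational arithmetic."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(min(total, Fraction(1)))


def bh_oracle(pvalues):
    """Benjamini-Hochberg from the definition: step-up with cumulative minimum."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj


def transcript_oracle(pos, ref, alt, gene, reference):
    """Coding effect by re-translating the whole mutated transcript."""
    if not gene.contains(pos):
        return "noncoding"
    if gene.cds_offset(pos) is None:
        return "UTR"
    mutated = reference.bases[:pos - 1] + alt + reference.bases[pos:]
    mut_ref = ReferenceSequence(reference.name, mutated)
    before = str(Seq(gene.cds_sequence(reference)).translate())
    after = str(Seq(gene.cds_sequence(mut_ref)).translate())
    if before == after:
        return "synonymous"
    diffs = [(a, b) for a, b in zip(before, after) if a != b]
    assert len(diffs) == 1
    return "stopgain" if diffs[0][1] == "*" else "nonsynonymous"
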