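"""Synthetic paired-tissue pileup datasets with known ground truth.

The simulator operates at the pileup level (per-site read-count sampling),
which suffices to exercise every statistic in the pipeline; read-level
simulation and alignment are out of scope. For each site, per-tissue depth
is Poisson around the configured mean (default 100x, the exome depth the
analysis assumes), sequencing errors occur at 1e-3 per read, and read
strand and pair orientation are split binomially -- except at injected
artifact sites, whose variant reads all carry a single orientation, the
8-oxo-dG shearing-stress signature.

Injected variants follow the study conditions: germline variants share a
genotype across tissues with a transition-rich class mix (36% A:T>G:C,
38% G:C>A:T), somatic variants are dominated by G:C>T:A transversions
(87%) and heterozygous in one tissue (tissue 1 with probability 0.85 by
default) while the other tissue stays reference, and a duplicated decoy
segment exercises the identity-region mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    BASES,
    GeneModel,
    RegionMask,
    ReferenceSequence,
    SiteCounts,
    write_gene_models,
    write_gmt,
    write_pileup_table,
)
from .spectrum_context import SUBSTITUTION_CLASSES

#: for each substitution class, the alternate allele implied by each reference base
CLASS_ALT = {
    "A:T>G:C": {"A": "G", "T": "C"},
    "G:C>A:T": {"G": "A", "C": "T"},
    "G:C>T:A": {"G": "T", "C": "A"},
    "A:T>T:A": {"A": "T", "T": "A"},
    "A:T>C:G": {"A": "C", "T": "G"},
    "G:C>C:G": {"G": "C", "C": "G"},
}

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def _default_germline_weights() -> dict[str, float]:
    # transition-rich germline spectrum; the four minor classes share the rest
    return {
        "A:T>G:C": 0.36,
        "G:C>A:T": 0.38,
        "G:C>T:A": 0.065,
        "A:T>T:A": 0.065,
        "A:T>C:G": 0.065,
        "G:C>C:G": 0.065,
    }


def _default_somatic_weights() -> dict[str, float]:
    # G:C>T:A-dominant somatic spectrum
    return {
        "A:T>G:C": 0.026,
        "G:C>A:T": 0.026,
        "G:C>T:A": 0.87,
        "A:T>T:A": 0.026,
        "A:T>C:G": 0.026,
        "G:C>C:G": 0.026,
    }


@dataclass
class SimulationConfig:
    """All knobs of the paired-tissue simulator; defaults emulate the study conditions."""

    seed: int = 0
    genome_length: int = 60_000
    chrom: str = "simchr"
    n_pairs: int = 1
    mean_depth: float = 100.0

    n_germline: int = 500
    germline_class_weights: dict[str, float] = field(default_factory=_default_germline_weights)
    germline_hom_fraction: float = 0.33
    germline_het_vaf_concentration: float = 40.0  # Beta centred on 0.5
    germline_hom_vaf: float = 0.99

    n_somatic: int = 50
    somatic_class_weights: dict[str, float] = field(default_factory=_default_somatic_weights)
    somatic_het_tissue1_prob: float = 0.85
    somatic_vaf_mean: float = 0.35
    somatic_vaf_concentration: float = 60.0

    n_artifact: int = 25
    artifact_orientation: str = "F1R2"
    artifact_vaf_mean: float = 0.30
    artifact_vaf_concentration: float = 60.0
    artifact_ccg_fraction: float = 0.0  # fraction placed mid-CCG on the C strand

    error_rate: float = 1e-3
    mean_base_quality: float = 37.0
    mean_mapping_quality: float = 60.0

    duplicated_region: tuple[int, float] | None = (500, 1.0)  # (length, identity)

    n_genes: int = 30
    gene_set_size: int = 8

    def __post_init__(self) -> None:
        if self.genome_length < 5_000:
            raise ValueError("genome_length must be >= 5 kb")
        for name in ("germline_class_weights", "somatic_class_weights"):
            w = getattr(self, name)
            if set(w) != set(SUBSTITUTION_CLASSES):
                raise ValueError(f"{name} must cover the six substitution classes")
            if abs(sum(w.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
        if self.artifact_orientation not in ("F1R2", "F2R1"):
            raise ValueError("artifact_orientation must be F1R2 or F2R1")
        n_variants = self.n_germline + self.n_somatic + self.n_artifact
        if n_variants > self.genome_length // 3:
            raise ValueError("too many variants for the configured genome length")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "duplicated_region" in data and data["duplicated_region"] is not None:
            data["duplicated_region"] = tuple(data["duplicated_region"])
        return cls(**data)


@dataclass
class TruthRecord:
    """Ground truth for one injected variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    origin: str  # germline | somatic | artifact
    sub_class: str
    het_tissue: str  # t1 | t2 | both
    vaf_t1: float
    vaf_t2: float


@dataclass
class SimulatedReference:
    reference: ReferenceSequence
    decoy_mask: RegionMask
    genes: dict[str, GeneModel]
    gene_sets: dict[str, set[str]]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _to_string(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[arr].tobytes().decode()


def _make_gene(gid: str, chrom: str, start: int, end: int, rng: np.random.Generator) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    utr5 = int(rng.integers(30, 120))
    utr3 = int(rng.integers(30, 120))
    a, b = start + utr5, end - utr3
    if b - a + 1 < 90:
        a, b = start, end
    span = b - a + 1
    total_cds = max((span * 2 // 3) // 3 * 3, 30)
    n_exons = int(rng.integers(1, 4))
    if n_exons > 1 and span - total_cds < 2 * (n_exons - 1):
        n_exons = 1
    if n_exons == 1:
        segs = [(a, a + total_cds - 1)]
    else:
        cuts = np.sort(rng.choice(np.arange(10, total_cds - 10), size=n_exons - 1, replace=False))
        lens = np.diff(np.concatenate(([0], cuts, [total_cds])))
        gap = (span - total_cds) // (n_exons - 1)
        segs = []
        cur = a
        for i, ln in enumerate(lens):
            segs.append((cur, cur + int(ln) - 1))
            cur += int(ln) + gap
    if strand == "-":
        segs = segs[::-1]
    return GeneModel(gid, chrom, strand, start, end, segs)


def simulate_reference(config: SimulationConfig) -> SimulatedReference:
    """Uniform random reference, optional duplicated decoy, toy genes and gene sets.

    The decoy is a segment copied elsewhere in the genome at the configured
    identity (per-base mutation probability 1 - identity); both copies go
    into the decoy mask. Gene models tile the genome outside the decoy, and
    one "guidance-like" gene set is drawn from the longest third of the
    genes so length-biased enrichment is exercisable.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    arr = _random_sequence(rng, L)

    decoy_intervals: list[tuple[str, int, int]] = []
    if config.duplicated_region is not None:
        dlen, identity = config.duplicated_region
        if dlen * 4 > L:
            raise ValueError("duplicated segment too long for genome")
        src = L // 6
        dst = (L * 4) // 6
        copy = arr[src:src + dlen].copy()
        mutate = rng.random(dlen) >= identity
        if mutate.any():
            shift = rng.integers(1, 4, size=int(mutate.sum()))
            copy[mutate] = (copy[mutate] + shift) % 4
        arr[dst:dst + dlen] = copy
        decoy_intervals = [(config.chrom, src, src + dlen), (config.chrom, dst, dst + dlen)]

    reference = ReferenceSequence(config.chrom, _to_string(arr))
    decoy_mask = RegionMask(decoy_intervals)

    genes: dict[str, GeneModel] = {}
    cursor = 200
    i = 0
    while len(genes) < config.n_genes and cursor < L - 4_000:
        length = int(rng.integers(600, 3_800))
        start, end = cursor, cursor + length - 1
        hit_decoy = [e for _, s, e in decoy_intervals if not (end < s + 1 or start > e)]
        if hit_decoy:
            cursor = min(hit_decoy) + 200
            continue
        if end > L - 200:
            break
        i += 1
        gid = f"G{i:03d}"
        genes[gid] = _make_gene(gid, config.chrom, start, end, rng)
        cursor = end + int(rng.integers(200, 900))

    gene_sets: dict[str, set[str]] = {}
    if genes:
        by_len = sorted(genes.values(), key=lambda g: -g.length)
        long_pool = [g.gene_id for g in by_len[: max(len(by_len) // 3, 1)]]
        k = min(config.gene_set_size, len(long_pool))
        gene_sets["GUIDANCE_LIKE"] = set(rng.choice(long_pool, size=k, replace=False))
        all_ids = sorted(genes)
        for name in ("RANDOM_SET_A", "RANDOM_SET_B"):
            k = min(config.gene_set_size, len(all_ids))
            gene_sets[name] = set(rng.choice(all_ids, size=k, replace=False))
    return SimulatedReference(reference, decoy_mask, genes, gene_sets)


class _PositionPool:
    """Shuffled per-base pools of eligible positions; draws never repeat."""

    def __init__(self, reference: ReferenceSequence, mask: RegionMask, rng: np.random.Generator):
        L = len(reference)
        eligible = [
            p for p in range(2, L)  # skip edges so context ops always apply
            if not mask.contains_site(reference.name, p)
        ]
        order = rng.permutation(len(eligible))
        self.by_base: dict[str, list[int]] = {b: [] for b in BASES}
        for idx in order:
            pos = eligible[idx]
            self.by_base[reference.base(pos)].append(pos)

    def draw(self, bases: tuple[str, ...], predicate=None) -> tuple[int, str]:
        best = max(bases, key=lambda b: len(self.by_base[b]))
        pool = self.by_base[best]
        if predicate is None:
            if not pool:
                raise ValueError("position pool exhausted")
            return pool.pop(), best
        for i in range(len(pool) - 1, -1, -1):
            if predicate(pool[i]):
                return pool.pop(i), best
        raise ValueError("no eligible position satisfies the placement constraint")


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def plan_truth(config: SimulationConfig, simref: SimulatedReference,
               rng: np.random.Generator) -> list[TruthRecord]:
    """Choose positions, alleles and injected VAFs for every variant."""
    ref = simref.reference
    pool = _PositionPool(ref, simref.decoy_mask, rng)
    records: list[TruthRecord] = []

    classes = list(SUBSTITUTION_CLASSES)
    gw = np.array([config.germline_class_weights[c] for c in classes])
    sw = np.array([config.somatic_class_weights[c] for c in classes])

    for _ in range(config.n_germline):
        sub_class = classes[rng.choice(len(classes), p=gw)]
        pos, base = pool.draw(tuple(CLASS_ALT[sub_class]))
        alt = CLASS_ALT[sub_class][base]
        if rng.random() < config.germline_hom_fraction:
            v1 = v2 = config.germline_hom_vaf
        else:
            a, b = _beta_params(0.5, config.germline_het_vaf_concentration)
            v1, v2 = rng.beta(a, b), rng.beta(a, b)
        records.append(TruthRecord(ref.name, pos, base, alt, "germline", sub_class, "both", v1, v2))

    a, b = _beta_params(config.somatic_vaf_mean, config.somatic_vaf_concentration)
    for _ in range(config.n_somatic):
        sub_class = classes[rng.choice(len(classes), p=sw)]
        pos, base = pool.draw(tuple(CLASS_ALT[sub_class]))
        alt = CLASS_ALT[sub_class][base]
        het_tissue = "t1" if rng.random() < config.somatic_het_tissue1_prob else "t2"
        vaf = float(rng.beta(a, b))
        v1, v2 = (vaf, 0.0) if het_tissue == "t1" else (0.0, vaf)
        records.append(TruthRecord(ref.name, pos, base, alt, "somatic", sub_class, het_tissue, v1, v2))

    aa, ab = _beta_params(config.artifact_vaf_mean, config.artifact_vaf_concentration)

    def mid_ccg(pos: int) -> bool:
        return ref.base(pos - 1) == "C" and ref.base(pos + 1) == "G"

    for _ in range(config.n_artifact):
        want_ccg = rng.random() < config.artifact_ccg_fraction
        pos, base = pool.draw(("C",), predicate=mid_ccg if want_ccg else None)
        alt = "A"  # C>A on the C strand, the shearing-stress change
        het_tissue = "t1" if rng.random() < 0.5 else "t2"
        vaf = float(rng.beta(aa, ab))
        v1, v2 = (vaf, 0.0) if het_tissue == "t1" else (0.0, vaf)
        records.append(TruthRecord(ref.name, pos, base, alt, "artifact", "G:C>T:A", het_tissue, v1, v2))

    records.sort(key=lambda r: r.pos)
    return records


def _tissue_sites(
    config: SimulationConfig,
    reference: ReferenceSequence,
    truth: list[TruthRecord],
    tissue: int,
    rng: np.random.Generator,
) -> list[SiteCounts]:
    L = len(reference)
    ref_idx = np.frombuffer(reference.bases.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for b, i in _BASE_IDX.items():
        lut[ord(b)] = i
    ref_idx = lut[ref_idx]

    vaf = np.zeros(L)
    alt_idx = np.full(L, -1, dtype=np.int64)
    artifact = np.zeros(L, dtype=bool)
    for rec in truth:
        i = rec.pos - 1
        vaf[i] = rec.vaf_t1 if tissue == 1 else rec.vaf_t2
        alt_idx[i] = _BASE_IDX[rec.alt]
        artifact[i] = rec.origin == "artifact"

    depth = rng.poisson(config.mean_depth, L)
    var = rng.binomial(depth, vaf)
    rem = depth - var
    err = rng.binomial(rem, config.error_rate)
    refn = rem - err
    quarter = [0.25] * 4
    ref_cells = rng.multinomial(refn, quarter)
    var_cells = rng.multinomial(var, quarter)

    counts = np.zeros((L, 4, 4), dtype=np.int64)
    counts[np.arange(L), ref_idx] = ref_cells
    var_rows = np.nonzero(var > 0)[0]
    for i in var_rows:
        cells = var_cells[i]
        if artifact[i]:
            fwd, rev = cells[0] + cells[1], cells[2] + cells[3]
            cells = (
                np.array([fwd, 0, rev, 0]) if config.artifact_orientation == "F1R2"
                else np.array([0, fwd, 0, rev])
            )
        counts[i, alt_idx[i]] += cells

    err_rows = np.nonzero(err > 0)[0]
    for i in err_rows:
        allowed = [b for b in range(4) if b != ref_idx[i]]
        if artifact[i] and alt_idx[i] in allowed:
            # keep artifact variant support strictly single-orientation:
            # sequencing errors never mimic the artifact allele
            allowed.remove(alt_idx[i])
        for _ in range(err[i]):
            b = allowed[rng.integers(len(allowed))]
            cell = rng.integers(4)
            counts[i, b, cell] += 1

    sites = []
    for i in range(L):
        base_counts = {b: tuple(int(c) for c in counts[i, j]) for b, j in _BASE_IDX.items()}
        bq = {
            b: (config.mean_base_quality if sum(base_counts[b]) else 0.0)
            for b in BASES
        }
        sites.append(
            SiteCounts(reference.name, i + 1, BASES[ref_idx[i]], base_counts, bq,
                       config.mean_mapping_quality)
        )
    return sites


@dataclass
class SimulatedPair:
    sites_t1: list[SiteCounts]
    sites_t2: list[SiteCounts]
    truth: list[TruthRecord]


def simulate_pair(config: SimulationConfig, simref: SimulatedReference,
                  pair_index: int = 0) -> SimulatedPair:
    """Simulate one tissue pair's pileups plus the ground-truth table.

    Deterministic: the RNG stream is derived from (seed, pair index), so a
    fixed config yields byte-identical outputs.
    """
    rng = np.random.default_rng((config.seed, 7, pair_index))
    truth = plan_truth(config, simref, rng)
    sites_t1 = _tissue_sites(config, simref.reference, truth, 1, rng)
    sites_t2 = _tissue_sites(config, simref.reference, truth, 2, rng)
    return SimulatedPair(sites_t1, sites_t2, truth)


_TRUTH_HEADER = ["chrom", "pos", "ref", "alt", "origin", "sub_class", "het_tissue", "vaf_t1", "vaf_t2"]


def write_truth_table(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_HEADER) + "\n")
        for r in truth:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.origin}\t{r.sub_class}\t"
                f"{r.het_tissue}\t{r.vaf_t1:.6g}\t{r.vaf_t2:.6g}\n"
            )


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRUTH_HEADER:
            raise ValueError(f"{path}: unexpected truth header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(TruthRecord(f[0], int(f[1]), f[2], f[3], f[4], f[5], f[6],
                                       float(f[7]), float(f[8])))
    return records


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write a full dataset: reference, pileups, truth, mask, genes, sets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simref = simulate_reference(config)
    paths: dict[str, Path] = {}

    paths["reference"] = outdir / "ref.fa"
    simref.reference.to_fasta(paths["reference"])
    paths["mask"] = outdir / "mask.bed"
    simref.decoy_mask.to_bed(paths["mask"])
    paths["genes"] = outdir / "genes.gffl"
    write_gene_models(simref.genes.values(), paths["genes"])
    paths["gene_sets"] = outdir / "sets.gmt"
    write_gmt(simref.gene_sets, paths["gene_sets"])

    for pair_index in range(config.n_pairs):
        pair = simulate_pair(config, simref, pair_index)
        prefix = "" if config.n_pairs == 1 else f"pair{pair_index + 1}."
        for name, sites in (("t1_pileup", pair.sites_t1), ("t2_pileup", pair.sites_t2)):
            p = outdir / f"{prefix}{name.split('_')[0]}.pileup.tsv"
            write_pileup_table(sites, p)
            paths[f"{prefix}{name}"] = p
        p = outdir / f"{prefix}truth.tsv"
        write_truth_table(pair.truth, p)
        paths[f"{prefix}truth"] = p
    return paths
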