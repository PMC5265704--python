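"""End-to-end orchestration: simulate -> call -> filter -> spectrum -> annotate -> validate.

A single YAML-able config dict governs every stage; each threshold the
analysis uses surfaces as a named key with its standard default. Every run
writes a manifest recording the config snapshot, seed, per-stage output
checksums and site counts, and re-running with the same config and seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation_enrichment import (
    annotate_effect,
    long_gene_test,
    overrepresentation,
    syn_nonsyn_summary,
)
from .artifact_filters import apply_filters
from .io_formats import (
    read_gene_models,
    read_gmt,
    read_pileup_table,
    RegionMask,
    ReferenceSequence,
    write_vcf,
)
from .somatic_calling import (
    CallingParams,
    CallStatus,
    PairedCall,
    classify_pair,
    somatic_percentage,
)
from .spectrum_context import (
    SUBSTITUTION_CLASSES,
    ccg_motif_fraction,
    enrichment,
    spectrum,
    three_prime_context,
    zygosity_by_tissue,
)
from .synthetic_data import SimulationConfig, simulate_dataset
from .validation_concordance import (
    read_validation_table,
    records_to_frame,
    validate_table,
    validation_summary,
)

logger = logging.getLogger("oxisoma")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def default_config() -> dict:
    return {
        "seed": 42,
        "simulate": {"enabled": True},
        "inputs": {},
        "calling": {},
        "filters": {"max_strand_bias": 0.90, "read_bias": True, "use_mask": True},
        "spectrum": {"zygosity_class": "G:C>T:A"},
        "annotation": {"long_gene_threshold": 2_000},
        "validation": {"min_var_reads": 100, "min_fold": 2.0},
    }


def load_config(path: str | Path | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def classify_sites(sites1, sites2, params: CallingParams) -> list[PairedCall]:
    """Classify aligned per-site pileups for the two tissues."""
    if len(sites1) != len(sites2):
        raise ValueError("tissue pileups differ in length")
    return [classify_pair(s1, s2, params) for s1, s2 in zip(sites1, sites2)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StageRecord:
    name: str
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int | float | None] = field(default_factory=dict)
    skipped: bool = False


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    stages: list[StageRecord] = field(default_factory=list)

    def stage(self, name: str) -> StageRecord:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_json(self, path: Path) -> None:
        data = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "stages": [
                {"name": s.name, "skipped": s.skipped, "outputs": s.outputs, "counts": s.counts}
                for s in self.stages
            ],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _record_outputs(stage: StageRecord, outdir: Path, paths) -> None:
    for p in paths:
        p = Path(p)
        stage.outputs[str(p.relative_to(outdir))] = _sha256(p)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: dict | str | Path | None, outdir: str | Path,
                 seed: int | None = None) -> RunManifest:
    """Run every stage and return the manifest (also written as manifest.json).

    ``config`` may be a dict, a YAML path, or None (defaults). ``seed``
    overrides the config seed. Any stage failure raises
    :class:`PipelineError` naming the stage; outputs written so far stay on
    disk.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    config = copy.deepcopy(config)
    if seed is not None:
        config["seed"] = seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(version=__version__, seed=int(config["seed"]), config=config)
    params = CallingParams(**config.get("calling", {}))
    logger.info("calling parameters: %s", params.to_dict())

    # --- simulate ----------------------------------------------------------
    stage = StageRecord("simulate")
    manifest.stages.append(stage)
    inputs = dict(config.get("inputs", {}))
    sim_cfg = dict(config.get("simulate", {}))
    sim_enabled = sim_cfg.pop("enabled", True)
    if sim_enabled:
        try:
            sim = SimulationConfig.from_dict({"seed": int(config["seed"]), **sim_cfg})
            paths = simulate_dataset(sim, outdir / "sim")
            inputs.update({k: str(v) for k, v in paths.items()})
            stage.counts["genome_length"] = sim.genome_length
            stage.counts["n_injected"] = sim.n_germline + sim.n_somatic + sim.n_artifact
            _record_outputs(stage, outdir, paths.values())
        except Exception as exc:
            raise PipelineError("simulate", exc) from exc
    else:
        stage.skipped = True

    # --- call ---------------------------------------------------------------
    stage = StageRecord("call")
    manifest.stages.append(stage)
    try:
        for key in ("t1_pileup", "t2_pileup"):
            if not inputs.get(key):
                raise ValueError(f"missing input '{key}' with simulation disabled")
        sites1 = read_pileup_table(inputs["t1_pileup"])
        sites2 = read_pileup_table(inputs["t2_pileup"])
        calls = classify_sites(sites1, sites2, params)
        for status in CallStatus:
            stage.counts[status.value.lower()] = sum(c.status is status for c in calls)
        stage.counts["sites"] = len(calls)
    except Exception as exc:
        raise PipelineError("call", exc) from exc

    # --- filter -------------------------------------------------------------
    stage = StageRecord("filter")
    manifest.stages.append(stage)
    try:
        fcfg = config.get("filters", {})
        mask = None
        if fcfg.get("use_mask", True) and inputs.get("mask"):
            mask = RegionMask.from_bed(inputs["mask"])
        somatic = [c for c in calls if c.status is CallStatus.SOMATIC]
        germline = [c for c in calls if c.status is CallStatus.GERMLINE]
        for call in somatic + germline:
            apply_filters(call, mask=mask,
                          max_strand_bias=fcfg.get("max_strand_bias", params.max_strand_bias),
                          read_bias=fcfg.get("read_bias", True))
        somatic_kept = [c for c in somatic if c.kept]
        germline_kept = [c for c in germline if c.kept]
        somatic_vcf = outdir / "somatic.vcf"
        germline_vcf = outdir / "germline.vcf"
        write_vcf(sorted(somatic, key=lambda c: (c.chrom, c.pos)), somatic_vcf)
        write_vcf(sorted(germline_kept, key=lambda c: (c.chrom, c.pos)), germline_vcf)
        stage.counts["somatic_in"] = len(somatic)
        stage.counts["somatic_kept"] = len(somatic_kept)
        stage.counts["somatic_filtered"] = len(somatic) - len(somatic_kept)
        stage.counts["germline_in"] = len(germline)
        stage.counts["germline_kept"] = len(germline_kept)
        stage.counts["germline_filtered"] = len(germline) - len(germline_kept)
        _record_outputs(stage, outdir, [somatic_vcf, germline_vcf])
    except Exception as exc:
        raise PipelineError("filter", exc) from exc

    # --- spectrum / context --------------------------------------------------
    stage = StageRecord("spectrum")
    manifest.stages.append(stage)
    try:
        scfg = config.get("spectrum", {})
        som_spec = spectrum(somatic_kept, "somatic")
        germ_spec = spectrum(germline_kept, "germline")
        outputs = []
        for tab, name in ((som_spec, "spectrum_somatic.tsv"), (germ_spec, "spectrum_germline.tsv")):
            props = tab.proportions or {c: float("nan") for c in SUBSTITUTION_CLASSES}
            df = pd.DataFrame({
                "sub_class": list(SUBSTITUTION_CLASSES),
                "count": [tab.counts[c] for c in SUBSTITUTION_CLASSES],
                "proportion": [props[c] for c in SUBSTITUTION_CLASSES],
            })
            _write_tsv(df, outdir / name)
            outputs.append(outdir / name)
        if som_spec.total and germ_spec.total:
            enr = enrichment(som_spec, germ_spec)
            df = pd.DataFrame({
                "sub_class": list(SUBSTITUTION_CLASSES),
                "difference": [enr.differences[c] for c in SUBSTITUTION_CLASSES],
            })
            _write_tsv(df, outdir / "enrichment.tsv")
            outputs.append(outdir / "enrichment.tsv")

        zclass = scfg.get("zygosity_class", "G:C>T:A")
        zyg = zygosity_by_tissue(somatic_kept, zclass)
        df = pd.DataFrame([{
            "sub_class": zclass,
            "het_tissue1": zyg.het_tissue1,
            "het_tissue2": zyg.het_tissue2,
            "indeterminate": zyg.indeterminate,
            "fraction_het_tissue1": zyg.fraction_het_tissue1,
        }])
        _write_tsv(df, outdir / "zygosity.tsv")
        outputs.append(outdir / "zygosity.tsv")

        ref = ReferenceSequence.from_fasta(inputs["reference"]) if inputs.get("reference") else None
        if ref is not None:
            tally = three_prime_context(somatic_kept, ref)
            motif = ccg_motif_fraction(somatic_kept, ref)
            df = pd.DataFrame({
                "base": list("ACGT"),
                "count": [tally.counts[b] for b in "ACGT"],
            })
            _write_tsv(df, outdir / "context_3prime.tsv")
            outputs.append(outdir / "context_3prime.tsv")
            stage.counts["ccg_motif"] = motif.n_motif
            stage.counts["ccg_evaluable"] = motif.n_evaluable
            frac_a = tally.counts["A"] / tally.total if tally.total else None
            stage.counts["three_prime_A_fraction"] = frac_a

        n_variant_sites = len(somatic_kept) + len(germline_kept)
        stage.counts["somatic_percentage"] = (
            somatic_percentage(len(somatic_kept), n_variant_sites) if n_variant_sites else None
        )
        stage.counts["zygosity_fraction_het_tissue1"] = zyg.fraction_het_tissue1
        _record_outputs(stage, outdir, outputs)
    except Exception as exc:
        raise PipelineError("spectrum", exc) from exc

    # --- annotate / enrich ----------------------------------------------------
    stage = StageRecord("annotate")
    manifest.stages.append(stage)
    if inputs.get("genes") and inputs.get("reference"):
        try:
            acfg = config.get("annotation", {})
            genes = read_gene_models(inputs["genes"])
            ref = ReferenceSequence.from_fasta(inputs["reference"])
            effects = [annotate_effect(c, genes, ref) for c in somatic_kept]
            df = pd.DataFrame({
                "chrom": [c.chrom for c in somatic_kept],
                "pos": [c.pos for c in somatic_kept],
                "ref": [c.ref_base for c in somatic_kept],
                "alt": [c.alt_base for c in somatic_kept],
                "gene_id": [e.gene_id for e in effects],
                "effect": [e.effect for e in effects],
                "ref_aa": [e.ref_aa for e in effects],
                "alt_aa": [e.alt_aa for e in effects],
            })
            _write_tsv(df, outdir / "effects.tsv")
            outputs = [outdir / "effects.tsv"]
            summary = syn_nonsyn_summary(effects)
            stage.counts["coding"] = summary.n_coding
            stage.counts["nonsynonymous"] = summary.n_nonsynonymous
            stage.counts["fraction_nonsynonymous"] = summary.fraction_nonsynonymous

            fg = sorted({e.gene_id for e in effects if e.gene_id})
            if fg:
                lg = long_gene_test([genes[g] for g in fg], list(genes.values()),
                                    acfg.get("long_gene_threshold", 100_000))
                stage.counts["long_gene_p"] = lg.p_value
                if inputs.get("gene_sets"):
                    sets = read_gmt(inputs["gene_sets"])
                    ora = overrepresentation(fg, sets, set(genes))
                    df = pd.DataFrame({
                        "set": [r.name for r in ora],
                        "k": [r.k for r in ora],
                        "n": [r.n for r in ora],
                        "K": [r.K for r in ora],
                        "N": [r.N for r in ora],
                        "p_value": [r.p_value for r in ora],
                        "adj_p": [r.adj_p for r in ora],
                    })
                    _write_tsv(df, outdir / "enrichment_sets.tsv")
                    outputs.append(outdir / "enrichment_sets.tsv")
            _record_outputs(stage, outdir, outputs)
        except Exception as exc:
            raise PipelineError("annotate", exc) from exc
    else:
        stage.skipped = True

    # --- validate -------------------------------------------------------------
    stage = StageRecord("validate")
    manifest.stages.append(stage)
    if inputs.get("validation_table"):
        try:
            vcfg = config.get("validation", {})
            table = read_validation_table(inputs["validation_table"])
            records = validate_table(table, min_var_reads=vcfg.get("min_var_reads", 100),
                                     min_fold=vcfg.get("min_fold", 2.0))
            summary = validation_summary(records)
            _write_tsv(records_to_frame(records), outdir / "validated.tsv")
            stage.counts["validated"] = summary.n_validated
            stage.counts["failed"] = summary.n_failed
            stage.counts["unevaluable"] = summary.n_unevaluable
            stage.counts["rate"] = summary.rate
            _record_outputs(stage, outdir, [outdir / "validated.tsv"])
        except Exception as exc:
            raise PipelineError("validate", exc) from exc
    else:
        stage.skipped = True

    manifest.to_json(outdir / "manifest.json")
    return manifest
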