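"""Amplicon re-sequencing validation of somatic sites.

A site discovered on the high-depth exome platform is *validated* on the
very-high-depth amplicon platform when, on the amplicon data, (a) the
variant allele in the variant-carrying tissue is supported by at least 100
reads, (b) the VAFs of the two tissues differ at least two-fold, and (c)
the tissue with the higher VAF is the same on both platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass
class ValidationRecord:
    site: str
    disc_vaf_t1: float | None
    disc_vaf_t2: float | None
    val_vaf_t1: float | None
    val_vaf_t2: float | None
    val_var_reads_t1: int | None
    val_var_reads_t2: int | None
    evaluable: bool = False
    validated: bool = False
    direction_consistent: bool = False


def validate_site(
    site: str,
    disc_vaf_t1: float | None,
    disc_vaf_t2: float | None,
    val_vaf_t1: float | None,
    val_vaf_t2: float | None,
    val_var_reads_t1: int | None,
    val_var_reads_t2: int | None,
    min_var_reads: int = 100,
    min_fold: float = 2.0,
    reads_in_both: bool = False,
) -> ValidationRecord:
    """Apply the conjunctive validation rule to one site.

    The read-support requirement applies to the variant-carrying tissue on
    the validation platform (both tissues with ``reads_in_both``). A zero
    VAF in one tissue counts as a fold-difference pass when the other
    tissue's VAF is positive; two zero VAFs fail. Missing fields mark the
    record unevaluable.
    """
    rec = ValidationRecord(site, disc_vaf_t1, disc_vaf_t2, val_vaf_t1, val_vaf_t2,
                           val_var_reads_t1, val_var_reads_t2)
    values = [disc_vaf_t1, disc_vaf_t2, val_vaf_t1, val_vaf_t2, val_var_reads_t1, val_var_reads_t2]
    if any(v is None or pd.isna(v) for v in values):
        return rec
    for v in (disc_vaf_t1, disc_vaf_t2, val_vaf_t1, val_vaf_t2):
        if not 0 <= v <= 1:
            raise ValueError(f"{site}: VAF outside [0, 1]")
    if min(val_var_reads_t1, val_var_reads_t2) < 0:
        raise ValueError(f"{site}: negative read count")
    rec.evaluable = True

    hi, lo = max(val_vaf_t1, val_vaf_t2), min(val_vaf_t1, val_vaf_t2)
    if hi == 0:
        fold_ok = False
    elif lo == 0:
        fold_ok = True
    else:
        fold_ok = hi / lo >= min_fold

    if reads_in_both:
        reads_ok = min(val_var_reads_t1, val_var_reads_t2) >= min_var_reads
    else:
        var_reads = val_var_reads_t1 if val_vaf_t1 >= val_vaf_t2 else val_var_reads_t2
        reads_ok = var_reads >= min_var_reads

    disc_dir = 1 if disc_vaf_t1 > disc_vaf_t2 else (2 if disc_vaf_t2 > disc_vaf_t1 else 0)
    val_dir = 1 if val_vaf_t1 > val_vaf_t2 else (2 if val_vaf_t2 > val_vaf_t1 else 0)
    rec.direction_consistent = disc_dir != 0 and disc_dir == val_dir

    rec.validated = fold_ok and reads_ok and rec.direction_consistent
    return rec


@dataclass
class ValidationSummary:
    n_validated: int
    n_failed: int
    n_unevaluable: int

    @property
    def n_evaluable(self) -> int:
        return self.n_validated + self.n_failed

    @property
    def rate(self) -> float:
        return self.n_validated / self.n_evaluable


def validation_summary(records: list[ValidationRecord]) -> ValidationSummary:
    n_val = sum(r.validated for r in records)
    n_eval = sum(r.evaluable for r in records)
    if n_eval == 0:
        raise ValueError("no evaluable validation records")
    return ValidationSummary(
        n_validated=n_val,
        n_failed=n_eval - n_val,
        n_unevaluable=len(records) - n_eval,
    )


_COLUMNS = ["site", "t1_disc_vaf", "t2_disc_vaf", "t1_val_vaf", "t2_val_vaf",
            "t1_val_varreads", "t2_val_varreads"]


def read_validation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def validate_table(df: pd.DataFrame, **kwargs) -> list[ValidationRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(
            validate_site(
                str(row.site),
                row.t1_disc_vaf, row.t2_disc_vaf,
                row.t1_val_vaf, row.t2_val_vaf,
                row.t1_val_varreads, row.t2_val_varreads,
                **kwargs,
            )
        )
    return records


def records_to_frame(records: list[ValidationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": [r.site for r in records],
            "t1_disc_vaf": [r.disc_vaf_t1 for r in records],
            "t2_disc_vaf": [r.disc_vaf_t2 for r in records],
            "t1_val_vaf": [r.val_vaf_t1 for r in records],
            "t2_val_vaf": [r.val_vaf_t2 for r in records],
            "t1_val_varreads": [r.val_var_reads_t1 for r in records],
            "t2_val_varreads": [r.val_var_reads_t2 for r in records],
            "evaluable": [r.evaluable for r in records],
            "direction_consistent": [r.direction_consistent for r in records],
            "validated": [r.validated for r in records],
        }
    )
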