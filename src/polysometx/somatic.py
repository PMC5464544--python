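"""Cohort-level somatic mutation summaries.

Four small operations over a MAF-like :class:`~polysometx.io.MutationTable`:
per-sample mutation burden (mutations per megabase of covered territory),
mutual-exclusivity tallies over a driver-gene set, residue-level hotspot
recurrence, and per-sample allelic-fraction percentiles. Duplicate records
of the same event (same sample, gene, locus, alleles) are dropped before
any counting, since spreadsheet exports often repeat rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MutationTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BurdenSummary",
    "ExclusivityResult",
    "CODING_CLASSES",
    "mutation_burden",
    "coexclusivity",
    "hotspot_tally",
    "af_summary",
]

#: All exonic classes, synonymous included (burden counts both synonymous
#: and nonsynonymous events by default; pass a narrower set to restrict).
CODING_CLASSES = frozenset(
    {"missense", "nonsense", "splice", "frameshift_indel", "inframe_indel", "synonymous"}
)


@dataclass
class BurdenSummary:
    """Per-sample coding mutation counts/rates and cohort aggregates."""

    per_sample: pd.DataFrame  # columns: n_coding, territory_mb, rate_per_mb
    mean_rate: float
    rate_range: tuple[float, float]
    mean_count: float


def _territory_series(territory_mb) -> pd.Series:
    if isinstance(territory_mb, pd.DataFrame):
        if "territory_mb" not in territory_mb.columns:
            raise ValidationError("territory table needs a 'territory_mb' column")
        if "sample_id" in territory_mb.columns:
            territory_mb = territory_mb.set_index("sample_id")
        ser = territory_mb["territory_mb"].astype(float)
    elif isinstance(territory_mb, Mapping):
        ser = pd.Series(territory_mb, dtype=float)
    else:
        ser = pd.Series(territory_mb, dtype=float)
    if (ser <= 0).any():
        bad = ser.index[ser <= 0][0]
        raise ValidationError(f"non-positive territory for sample {bad!r}")
    return ser


def mutation_burden(
    mt: MutationTable,
    territory_mb,
    coding_classes: Sequence[str] | frozenset[str] = CODING_CLASSES,
) -> BurdenSummary:
    """Per-sample and cohort mutation burden.

    ``territory_mb`` gives each sample's covered coding territory in
    megabases (Series/dict keyed by sample, or a DataFrame with sample_id
    and territory_mb columns); it defines the cohort, so samples without
    mutation records count zero. Every mutated sample must have a territory
    entry. Rates are counts restricted to ``coding_classes`` divided by
    territory.
    """
    territory = _territory_series(territory_mb)
    df = mt.deduplicated().frame
    missing = sorted(set(df["sample_id"]) - set(territory.index))
    if missing:
        raise ValidationError(f"samples without territory entries: {missing}")
    coding = df[df["variant_class"].isin(set(coding_classes))]
    counts = (
        coding.groupby("sample_id").size().reindex(territory.index, fill_value=0)
    )
    per_sample = pd.DataFrame(
        {
            "n_coding": counts.astype(int),
            "territory_mb": territory,
            "rate_per_mb": counts / territory,
        }
    )
    per_sample.index.name = "sample_id"
    rates = per_sample["rate_per_mb"]
    return BurdenSummary(
        per_sample=per_sample,
        mean_rate=float(rates.mean()),
        rate_range=(float(rates.min()), float(rates.max())),
        mean_count=float(per_sample["n_coding"].mean()),
    )


@dataclass
class ExclusivityResult:
    """Mutual-exclusivity tallies over a driver-gene set."""

    genes: tuple[str, ...]
    per_sample: pd.Series  # distinct mutated genes of the set, per sample
    n_mutated: int  # samples with >= 1 gene of the set mutated
    n_multi: int  # samples with > 1 gene of the set mutated

    def __post_init__(self):
        assert self.n_multi <= self.n_mutated <= max(len(self.per_sample), self.n_mutated)


def coexclusivity(
    mt: MutationTable, genes: Sequence[str] = ("BAP1", "SF3B1", "EIF1AX")
) -> ExclusivityResult:
    """Count, per sample, how many distinct genes of a set are mutated."""
    if not genes:
        raise ValidationError("gene list must be non-empty")
    df = mt.deduplicated().frame
    sub = df[df["gene"].isin(set(genes))]
    per_sample = sub.groupby("sample_id")["gene"].nunique().sort_index()
    per_sample.name = "n_genes_mutated"
    return ExclusivityResult(
        genes=tuple(genes),
        per_sample=per_sample,
        n_mutated=int((per_sample >= 1).sum()),
        n_multi=int((per_sample > 1).sum()),
    )


def hotspot_tally(mt: MutationTable, min_recurrence: int = 2) -> pd.DataFrame:
    """Residue-level recurrence per gene, sorted by descending count.

    Records without a parsable protein change are skipped (logged). Rows
    below ``min_recurrence`` are omitted. Columns: gene, residue, count,
    alt_aas (sorted unique alternate amino acids).
    """
    df = mt.deduplicated().frame
    parsable = df[np.isfinite(df["residue"].astype(float))]
    n_skipped = len(df) - len(parsable)
    if n_skipped:
        logger.info("%d record(s) without parsable protein change skipped", n_skipped)
    if parsable.empty:
        return pd.DataFrame(columns=["gene", "residue", "count", "alt_aas"])
    grouped = (
        parsable.groupby(["gene", "residue"])
        .agg(
            count=("sample_id", "size"),
            alt_aas=("alt_aa", lambda s: ",".join(sorted({a for a in s if a}))),
        )
        .reset_index()
    )
    grouped["residue"] = grouped["residue"].astype(int)
    grouped = grouped[grouped["count"] >= min_recurrence]
    return grouped.sort_values(
        ["count", "gene", "residue"], ascending=[False, True, True]
    ).reset_index(drop=True)


def af_summary(mt: MutationTable) -> pd.DataFrame:
    """Per-sample allelic-fraction percentiles (5, 25, 50, 75, 95).

    Uses the linear-interpolation quantile definition. Samples with no
    allelic fractions are omitted (logged).
    """
    df = mt.deduplicated().frame
    with_af = df[df["allelic_fraction"].notna()]
    dropped = sorted(set(df["sample_id"]) - set(with_af["sample_id"]))
    if dropped:
        logger.info("samples without allelic fractions omitted: %s", dropped)
    rows = []
    for sample, sub in with_af.groupby("sample_id"):
        q = np.percentile(sub["allelic_fraction"].to_numpy(), [5, 25, 50, 75, 95])
        rows.append(
            {
                "sample_id": sample,
                "p5": q[0],
                "p25": q[1],
                "p50": q[2],
                "p75": q[3],
                "p95": q[4],
                "n_records": len(sub),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "p5", "p25", "p50", "p75", "p95", "n_records"]).set_index("sample_id") if rows else pd.DataFrame(
        columns=["p5", "p25", "p50", "p75", "p95", "n_records"]
    )
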