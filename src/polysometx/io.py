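"""Tabular input/output and validated in-memory containers.

The pipeline touches three tabular formats, all plain TSV:

* a gene x sample integer count matrix (first column gene IDs, header row
  sample IDs), one matrix per experiment covering both RNA fractions;
* a sample sheet with one row per library giving its cell line, replicate,
  condition (control/knockdown) and fraction (total/polysome);
* a MAF-like somatic mutation table with one row per mutation event.

Readers validate on ingestion and raise :class:`ValidationError` with
row/column context; writers round-trip losslessly with the readers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "knockdown")
FRACTIONS = ("total", "polysome")

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "splice",
    "frameshift_indel",
    "inframe_indel",
    "synonymous",
    "other",
)

#: MAF Variant_Classification values mapped onto the normalized vocabulary.
MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "splice_site": "splice",
    "splice": "splice",
    "splice_region": "splice",
    "frame_shift_del": "frameshift_indel",
    "frame_shift_ins": "frameshift_indel",
    "frameshift_indel": "frameshift_indel",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "inframe_indel": "inframe_indel",
    "silent": "synonymous",
    "synonymous": "synonymous",
}

#: Default column-name aliases for mutation tables (lower-cased lookup).
#: Covers both this package's dialect and standard MAF headers.
MUTATION_ALIASES: Mapping[str, str] = {
    "sample_id": "sample_id",
    "sample": "sample_id",
    "tumor_sample_barcode": "sample_id",
    "gene": "gene",
    "gene_symbol": "gene",
    "hugo_symbol": "gene",
    "chromosome": "chromosome",
    "chrom": "chromosome",
    "position": "position",
    "start_position": "position",
    "pos": "position",
    "ref_allele": "ref_allele",
    "reference_allele": "ref_allele",
    "alt_allele": "alt_allele",
    "tumor_seq_allele2": "alt_allele",
    "variant_class": "variant_class",
    "variant_classification": "variant_class",
    "protein_change": "protein_change",
    "hgvsp_short": "protein_change",
    "allelic_fraction": "allelic_fraction",
    "allele_fraction": "allelic_fraction",
    "af": "allelic_fraction",
    "t_alt_count": "t_alt_count",
    "t_ref_count": "t_ref_count",
}


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene ID with sample IDs as columns. Values must
        be non-negative integers (integer dtype, or floats that are exactly
        integral).
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups[:5]}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups[:5]}")
        values = counts.to_numpy()
        if values.size == 0:
            raise ValidationError("count matrix is empty")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(values != np.floor(values))
                g, s = bad[0] if len(bad) else (0, 0)
                raise ValidationError(
                    f"non-integer count at gene {counts.index[g]!r}, "
                    f"sample {counts.columns[s]!r}"
                )
            values = values.astype(np.int64)
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {counts.index[g]!r}, "
                f"sample {counts.columns[s]!r}"
            )
        self._df = pd.DataFrame(
            values.astype(np.int64), index=counts.index.astype(str),
            columns=counts.columns.astype(str),
        )
        self._df.index.name = "gene_id"

    # -- accessors ---------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def gene_ids(self) -> pd.Index:
        return self._df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self._df.columns

    @property
    def lib_sizes(self) -> pd.Series:
        """Per-sample library sizes (column sums)."""
        return self._df.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self._df.shape[0]

    @property
    def n_samples(self) -> int:
        return self._df.shape[1]

    def subset_genes(self, genes: Sequence[str] | np.ndarray) -> "CountMatrix":
        return CountMatrix(self._df.loc[genes])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountMatrix({self.n_genes} genes x {self.n_samples} samples)"


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column gene IDs, header sample IDs)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad) or converted.isna().any():
            where = bad[0] if len(bad) else df.index[converted.isna()][0]
            raise ValidationError(
                f"{path}: non-numeric or missing count at gene {where!r}, "
                f"sample {col!r}"
            )
        numeric[col] = converted
    return CountMatrix(numeric)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Factor levels for one sequencing library."""

    sample_id: str
    cell_line: str
    replicate: str
    condition: str  # "control" | "knockdown"
    fraction: str  # "total" | "polysome"

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: condition {self.condition!r} "
                f"not in allowed levels {CONDITIONS}"
            )
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: fraction {self.fraction!r} "
                f"not in allowed levels {FRACTIONS}"
            )


SAMPLE_SHEET_COLUMNS = ("sample_id", "cell_line", "replicate", "condition", "fraction")


def read_sample_sheet(path: str | Path) -> list[SampleDesign]:
    """Read a TSV sample sheet into a list of :class:`SampleDesign`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    return [
        SampleDesign(
            sample_id=row.sample_id,
            cell_line=row.cell_line,
            replicate=str(row.replicate),
            condition=row.condition,
            fraction=row.fraction,
        )
        for row in df.itertuples()
    ]


def design_frame(designs: Sequence[SampleDesign]) -> pd.DataFrame:
    """Sample sheet as a DataFrame indexed by sample_id (order preserved)."""
    df = pd.DataFrame([d.__dict__ for d in designs]).set_index("sample_id")
    return df


def write_sample_sheet(designs: Sequence[SampleDesign], path: str | Path) -> None:
    design_frame(designs).to_csv(path, sep="\t")


def align_design(cm: CountMatrix, designs: Sequence[SampleDesign]) -> list[SampleDesign]:
    """Match a sample sheet to a count matrix.

    A count-matrix sample with no sheet row is an error; a sheet row with no
    count column is dropped with a warning. Returns designs in count-matrix
    column order.
    """
    by_id = {d.sample_id: d for d in designs}
    missing = [s for s in cm.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"samples missing from sample sheet: {missing}")
    extra = [d.sample_id for d in designs if d.sample_id not in set(cm.sample_ids)]
    if extra:
        logger.warning("sample sheet rows without count columns ignored: %s", extra)
    return [by_id[s] for s in cm.sample_ids]


# ---------------------------------------------------------------------------
# Mutation table
# ---------------------------------------------------------------------------

_PROTEIN_RE = re.compile(r"^([A-Z\*])(\d+)([A-Za-z\*=]*)$")


def parse_protein_change(change: object) -> tuple[float, str | None, str | None]:
    """Parse a protein change like ``Q209L`` into (residue, ref AA, alt).

    Accepts optional ``p.`` prefixes and parenthesized forms such as
    ``GGA>CTA (G48L)`` — an in-cis dinucleotide substitution is one event
    with one protein change. Unparsable input yields ``(nan, None, None)``.
    """
    if change is None or (isinstance(change, float) and np.isnan(change)):
        return (np.nan, None, None)
    text = str(change).strip()
    paren = re.search(r"\(([^)]+)\)", text)
    if paren:
        text = paren.group(1).strip()
    if text.startswith(("p.", "P.")):
        text = text[2:]
    m = _PROTEIN_RE.match(text)
    if not m:
        return (np.nan, None, None)
    ref_aa, residue, alt = m.group(1), int(m.group(2)), m.group(3) or None
    return (float(residue), ref_aa, alt)


MUTATION_COLUMNS = (
    "sample_id",
    "gene",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "variant_class",
    "protein_change",
    "allelic_fraction",
)


class MutationTable:
    """MAF-like somatic mutation records (1-based inclusive coordinates).

    Wraps a DataFrame with the normalized columns in
    :data:`MUTATION_COLUMNS`, plus parsed ``residue``/``ref_aa``/``alt_aa``
    derived from ``protein_change``. Allelic fractions, when present, must
    lie in [0, 1].
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        for col in ("sample_id", "gene"):
            if col not in df.columns:
                raise ValidationError(f"mutation table lacks a {col!r} column")
        for col in MUTATION_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        af = pd.to_numeric(df["allelic_fraction"], errors="coerce")
        supplied = df["allelic_fraction"].notna()
        out_of_range = supplied & ((af < 0) | (af > 1))
        if out_of_range.any():
            i = df.index[out_of_range][0]
            raise ValidationError(
                f"allelic fraction {df.loc[i, 'allelic_fraction']!r} outside "
                f"[0, 1] for sample {df.loc[i, 'sample_id']!r}"
            )
        df["allelic_fraction"] = af
        norm = (
            df["variant_class"].astype(str).str.strip().str.lower().map(MAF_CLASS_MAP)
        )
        df["variant_class"] = norm.where(norm.notna(), "other")
        parsed = df["protein_change"].map(parse_protein_change)
        df["residue"] = [p[0] for p in parsed]
        df["ref_aa"] = [p[1] for p in parsed]
        df["alt_aa"] = [p[2] for p in parsed]
        n_unparsed = int(df["protein_change"].notna().sum() - np.isfinite(df["residue"]).sum())
        if n_unparsed:
            logger.info("%d protein changes could not be parsed to a residue", n_unparsed)
        self._df = df.loc[:, list(MUTATION_COLUMNS) + ["residue", "ref_aa", "alt_aa"]]
        self._df = self._df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def deduplicated(self) -> "MutationTable":
        """Drop repeated records of the same event (same sample, gene, locus,
        alleles); XLS exports often duplicate rows."""
        keys = ["sample_id", "gene", "chromosome", "position", "ref_allele", "alt_allele"]
        return MutationTable(self._df.drop_duplicates(subset=keys))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MutationTable({len(self)} records, {self._df['sample_id'].nunique()} samples)"


def read_mutations(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> MutationTable:
    """Read a mutation table from TSV or an XLS/XLSX export.

    ``aliases`` maps source column names (case-insensitive) onto the
    normalized names; it extends/overrides :data:`MUTATION_ALIASES`. Standard
    MAF columns (Hugo_Symbol, Tumor_Sample_Barcode, Variant_Classification,
    Protein_Change, t_alt_count/t_ref_count) are recognized out of the box;
    the count pair is converted to an allelic fraction.
    """
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path, sep="\t")
    alias_map = dict(MUTATION_ALIASES)
    if aliases:
        alias_map.update({k.lower(): v for k, v in aliases.items()})
    renamed = {}
    for col in raw.columns:
        target = alias_map.get(str(col).strip().lower())
        if target and target not in renamed.values():
            renamed[col] = target
    df = raw.rename(columns=renamed)
    df = df.loc[:, [c for c in df.columns if c in set(alias_map.values())]]
    if "sample_id" not in df.columns or "gene" not in df.columns:
        raise ValidationError(
            f"{path}: no recognizable sample/gene columns "
            f"(got {list(raw.columns)})"
        )
    if "allelic_fraction" not in df.columns and {"t_alt_count", "t_ref_count"} <= set(
        df.columns
    ):
        alt = pd.to_numeric(df["t_alt_count"], errors="coerce")
        ref = pd.to_numeric(df["t_ref_count"], errors="coerce")
        df["allelic_fraction"] = alt / (alt + ref)
    df = df.drop(columns=[c for c in ("t_alt_count", "t_ref_count") if c in df.columns])
    return MutationTable(df)


def write_mutations(mt: MutationTable, path: str | Path) -> None:
    mt.frame.loc[:, list(MUTATION_COLUMNS)].to_csv(path, sep="\t", index=False)
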