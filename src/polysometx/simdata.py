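"""Synthetic polysome-profiling datasets and toy mutation cohorts.

The count generator emulates the design of a polysome-profiling shRNA
knockdown experiment: a panel of cell lines (one flagged "mutant-like"),
control vs. knockdown, total vs. polysome-associated RNA, replicated
libraries. Counts are negative binomial with the variance law
``var = mu + phi * mu**2`` and a log-linear mean,

    log mu_gs = log L_s + b0_g + cell-line effect + replicate effect
                + gamma_g * KD + delta_g * POLY + theta_g * KD * POLY,

where ``theta_g`` is the knockdown x fraction interaction — the quantity the
downstream GLM tests. A configurable fraction of genes carries a nonzero
``theta``, and one coordinated "regulon" gene set shares a common negative
``theta`` applied only in designated (by default, the non-mutant-like) cell
lines, mimicking a wild-type-only translational response of ribosomal
proteins. The latent mean matrix is retained in :class:`SimTruth` so tests
can make white-box assertions.

The mutation simulator produces small MAF-like cohorts with hotspot
residues in the Gq-pathway genes and a configurable exclusivity structure
among three driver genes, plus optional Poisson background mutations for
burden summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    MutationTable,
    SampleDesign,
    ValidationError,
    write_counts,
    write_sample_sheet,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "simulate_mutation_table",
    "write_dataset",
]


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the study design.

    Three cell lines (the first flagged mutant-like) x {control, knockdown}
    x {total, polysome} x 2 replicates = 24 libraries.

    Parameters
    ----------
    baseline_log_mean
        (mean, sd) of the per-gene natural-log baseline abundance ``b0_g``.
        The default (3.5, 1.5) gives a mean count of ~100 per gene, i.e.
        ~0.5M reads per library at 5000 genes.
    dispersion_trend
        (phi0, a) of the trend ``phi_g = phi0 + a / exp(b0_g)`` — dispersion
        decays with abundance toward an asymptote, as in real RNA-seq.
    lib_size_range
        Uniform range of multiplicative per-library depth factors ``L_s``.
    nuisance_effect_sd
        SD of the per-gene normal draws for the cell-line, replicate,
        knockdown and fraction main effects. Nonzero even for interaction-null
        genes so that normalization and nuisance-coefficient estimation are
        genuinely exercised.
    frac_te_shifted
        Proportion of genes given a nonzero interaction ``theta_g`` (drawn
        uniformly in ``te_effect_range`` with random sign, natural-log scale).
    regulon_size, regulon_effect
        Size and common (negative) interaction of the coordinated gene set;
        the effect applies only in ``regulon_cell_lines`` (default: every
        line except the mutant-like one).
    """

    n_genes: int = 5000
    cell_lines: tuple[str, ...] = ("mut1", "wt1", "wt2")
    mutant_like: str = "mut1"
    n_replicates: int = 2
    baseline_log_mean: tuple[float, float] = (3.5, 1.5)
    dispersion_trend: tuple[float, float] = (0.05, 1.0)
    lib_size_range: tuple[float, float] = (0.5, 2.0)
    nuisance_effect_sd: float = 0.1
    frac_te_shifted: float = 0.05
    te_effect_range: tuple[float, float] = (0.5, 1.5)
    regulon_size: int = 78
    regulon_effect: float = -1.0
    regulon_cell_lines: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if len(self.cell_lines) < 1 or len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValidationError("cell_lines must be non-empty and unique")
        if self.mutant_like not in self.cell_lines:
            raise ValidationError(
                f"mutant_like {self.mutant_like!r} not among cell lines"
            )
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not 0.0 <= self.frac_te_shifted <= 1.0:
            raise ValidationError("frac_te_shifted must lie in [0, 1]")
        lo, hi = self.te_effect_range
        if lo < 0 or hi < lo:
            raise ValidationError("te_effect_range bounds must be positive and ordered")
        phi0, a = self.dispersion_trend
        if phi0 < 0 or a < 0:
            raise ValidationError("dispersion_trend parameters must be non-negative")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ValidationError("lib_size_range must be positive and ordered")
        if self.regulon_size < 0 or self.regulon_size > self.n_genes:
            raise ValidationError("regulon_size must lie in [0, n_genes]")
        if self.regulon_cell_lines is not None:
            unknown = set(self.regulon_cell_lines) - set(self.cell_lines)
            if unknown:
                raise ValidationError(f"unknown regulon cell lines: {sorted(unknown)}")

    @property
    def effective_regulon_cell_lines(self) -> tuple[str, ...]:
        if self.regulon_cell_lines is not None:
            return self.regulon_cell_lines
        return tuple(c for c in self.cell_lines if c != self.mutant_like)


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset.

    ``theta`` holds each gene's true interaction effect; ``applies_in`` is a
    gene x cell-line boolean matrix saying where that effect is active (only
    regulon genes are restricted). ``mean_matrix`` is the latent NB mean for
    every (gene, sample), kept for white-box tests.
    """

    theta: pd.Series
    dispersion: pd.Series
    is_regulon: pd.Series
    applies_in: pd.DataFrame
    mean_matrix: pd.DataFrame
    baseline_log_mean: pd.Series = field(repr=False, default=None)

    def frame(self) -> pd.DataFrame:
        """Per-gene truth as a flat table (without the mean matrix)."""
        out = pd.DataFrame(
            {
                "theta": self.theta,
                "dispersion": self.dispersion,
                "is_regulon": self.is_regulon,
            }
        )
        for cl in self.applies_in.columns:
            out[f"applies_in_{cl}"] = self.applies_in[cl]
        return out


def _make_designs(config: SimConfig) -> list[SampleDesign]:
    designs = []
    for cell in config.cell_lines:
        for condition in ("control", "knockdown"):
            for fraction in ("total", "polysome"):
                for rep in range(1, config.n_replicates + 1):
                    designs.append(
                        SampleDesign(
                            sample_id=f"{cell}_{condition}_{fraction}_r{rep}",
                            cell_line=cell,
                            replicate=f"r{rep}",
                            condition=condition,
                            fraction=fraction,
                        )
                    )
    return designs


def simulate_dataset(
    config: SimConfig | None = None,
) -> tuple[CountMatrix, list[SampleDesign], SimTruth]:
    """Draw a synthetic count dataset with known interaction ground truth.

    Deterministic for a fixed ``config.seed``. Exactly
    ``round(frac_te_shifted * n_genes)`` genes receive an individual nonzero
    ``theta`` before the regulon is added on top (regulon genes are drawn
    from the remaining null genes).
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    designs = _make_designs(config)
    n_samples = len(designs)
    G = config.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(G)], name="gene_id")

    mu0, sd0 = config.baseline_log_mean
    b0 = rng.normal(mu0, sd0, size=G)
    phi0, a = config.dispersion_trend
    phi = phi0 + a / np.exp(b0)

    sd = config.nuisance_effect_sd
    cell_eff = {config.cell_lines[0]: np.zeros(G)}
    for cl in config.cell_lines[1:]:
        cell_eff[cl] = rng.normal(0.0, sd, size=G) if sd > 0 else np.zeros(G)
    rep_eff = {"r1": np.zeros(G)}
    for r in range(2, config.n_replicates + 1):
        rep_eff[f"r{r}"] = rng.normal(0.0, sd, size=G) if sd > 0 else np.zeros(G)
    gamma = rng.normal(0.0, sd, size=G) if sd > 0 else np.zeros(G)
    delta = rng.normal(0.0, sd, size=G) if sd > 0 else np.zeros(G)

    # interaction ground truth
    theta = np.zeros(G)
    n_shift = int(round(config.frac_te_shifted * G))
    shifted = rng.choice(G, size=n_shift, replace=False)
    lo, hi = config.te_effect_range
    signs = rng.choice([-1.0, 1.0], size=n_shift)
    theta[shifted] = signs * rng.uniform(lo, hi, size=n_shift)

    applies = np.ones((G, len(config.cell_lines)), dtype=bool)
    is_regulon = np.zeros(G, dtype=bool)
    if config.regulon_size > 0:
        null_pool = np.setdiff1d(np.arange(G), shifted)
        if len(null_pool) < config.regulon_size:
            raise ValidationError("not enough interaction-null genes for the regulon")
        reg = rng.choice(null_pool, size=config.regulon_size, replace=False)
        is_regulon[reg] = True
        theta[reg] = config.regulon_effect
        active = np.array(
            [cl in config.effective_regulon_cell_lines for cl in config.cell_lines]
        )
        applies[reg] = active[None, :]

    cell_index = {cl: j for j, cl in enumerate(config.cell_lines)}
    lib = rng.uniform(*config.lib_size_range, size=n_samples)

    log_mu = np.empty((G, n_samples))
    for s, d in enumerate(designs):
        kd = 1.0 if d.condition == "knockdown" else 0.0
        poly = 1.0 if d.fraction == "polysome" else 0.0
        eta = (
            np.log(lib[s])
            + b0
            + cell_eff[d.cell_line]
            + rep_eff[d.replicate]
            + gamma * kd
            + delta * poly
            + theta * applies[:, cell_index[d.cell_line]] * kd * poly
        )
        log_mu[:, s] = eta
    mu = np.exp(log_mu)

    counts = np.empty((G, n_samples), dtype=np.int64)
    pos = phi > 0
    if np.any(pos):
        shape = 1.0 / phi[pos]
        lam = rng.gamma(shape[:, None], mu[pos] * phi[pos, None])
        counts[pos] = rng.poisson(lam)
    if np.any(~pos):
        counts[~pos] = rng.poisson(mu[~pos])

    sample_ids = [d.sample_id for d in designs]
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    truth = SimTruth(
        theta=pd.Series(theta, index=gene_ids, name="theta"),
        dispersion=pd.Series(phi, index=gene_ids, name="dispersion"),
        is_regulon=pd.Series(is_regulon, index=gene_ids, name="is_regulon"),
        applies_in=pd.DataFrame(applies, index=gene_ids, columns=list(config.cell_lines)),
        mean_matrix=pd.DataFrame(mu, index=gene_ids, columns=sample_ids),
        baseline_log_mean=pd.Series(b0, index=gene_ids, name="baseline_log_mean"),
    )
    return cm, designs, truth


def write_dataset(
    cm: CountMatrix,
    designs: Sequence[SampleDesign],
    truth: SimTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write counts.tsv, samples.tsv and truth.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
    }
    write_counts(cm, paths["counts"])
    write_sample_sheet(designs, paths["samples"])
    truth.frame().to_csv(paths["truth"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# Toy somatic mutation cohorts
# ---------------------------------------------------------------------------

#: Hotspot residues per Gq-pathway gene: (residue, ref AA, alt AA choices).
DEFAULT_HOTSPOTS: Mapping[str, Sequence[tuple[int, str, Sequence[str]]]] = {
    "GNAQ": [(209, "Q", ("L", "P")), (183, "R", ("Q",))],
    "GNA11": [(209, "Q", ("L",)), (183, "R", ("C",))],
    "SF3B1": [(625, "R", ("H", "C")), (662, "Q", ("K",)), (666, "K", ("T",))],
}

#: The three drivers whose mutual exclusivity structure is simulated.
EXCLUSIVE_DRIVERS = ("BAP1", "SF3B1", "EIF1AX")


def simulate_mutation_table(
    n_samples: int,
    gene_panel: Sequence[str] = ("GNAQ", "GNA11", "BAP1", "SF3B1", "EIF1AX"),
    seed: int = 0,
    hotspots: Mapping[str, Sequence[tuple[int, str, Sequence[str]]]] | None = None,
    exclusivity: str = "strict",
    background_mean: float = 0.0,
    af_beta: tuple[float, float] = (5.0, 7.0),
) -> MutationTable:
    """Simulate a MAF-like cohort table with known structure.

    Every sample receives one Gq-pathway hotspot mutation (if GNAQ/GNA11 are
    in the panel, mutually exclusive between the two genes) and one of the
    three driver genes in :data:`EXCLUSIVE_DRIVERS` that are in the panel.
    With ``exclusivity="strict"`` no sample carries more than one of the
    three drivers; ``"almost"`` gives a small number of double-mutant
    samples (~5% of samples, at least one when n_samples >= 10).
    ``background_mean`` adds Poisson-distributed passenger missense
    mutations in synthetic genes for burden summaries. Allelic fractions are
    Beta-distributed, clipped into (0, 1].
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if not gene_panel:
        raise ValidationError("gene_panel must be non-empty")
    if exclusivity not in ("strict", "almost"):
        raise ValidationError("exclusivity must be 'strict' or 'almost'")
    hotspots = dict(DEFAULT_HOTSPOTS if hotspots is None else hotspots)
    rng = np.random.default_rng(seed)
    panel = list(gene_panel)
    records: list[dict] = []

    def draw_af() -> float:
        af = float(rng.beta(*af_beta))
        return max(af, 1e-3)

    def add(sample: str, gene: str, variant_class: str, protein_change: str | None,
            residue: int | None) -> None:
        pos = int(residue * 3 if residue else rng.integers(1, 10_000_000))
        records.append(
            {
                "sample_id": sample,
                "gene": gene,
                "chromosome": f"chr{(abs(hash(gene)) % 22) + 1}",
                "position": pos,
                "ref_allele": str(rng.choice(list("ACGT"))),
                "alt_allele": str(rng.choice(list("ACGT"))),
                "variant_class": variant_class,
                "protein_change": protein_change,
                "allelic_fraction": draw_af(),
            }
        )

    gq_genes = [g for g in panel if g in ("GNAQ", "GNA11") and g in hotspots]
    drivers = [g for g in EXCLUSIVE_DRIVERS if g in panel]
    other = [g for g in panel if g not in gq_genes and g not in drivers]

    for i in range(n_samples):
        sample = f"UM{i + 1:02d}"
        if gq_genes:
            gene = str(rng.choice(gq_genes))
            residue, ref_aa, alts = hotspots[gene][int(rng.integers(len(hotspots[gene])))]
            alt = str(rng.choice(list(alts)))
            add(sample, gene, "missense", f"{ref_aa}{residue}{alt}", residue)
        if drivers:
            gene = drivers[i % len(drivers)]
            if gene in hotspots:
                residue, ref_aa, alts = hotspots[gene][int(rng.integers(len(hotspots[gene])))]
                add(sample, gene, "missense", f"{ref_aa}{residue}{rng.choice(list(alts))}",
                    residue)
            else:
                residue = int(rng.integers(2, 700))
                add(sample, gene, str(rng.choice(["missense", "nonsense"])),
                    f"{rng.choice(list('ACDEFGHIKLMNPQRSTVWY'))}{residue}"
                    f"{rng.choice(list('ACDEFGHIKLMNPQRSTVWY*'))}", residue)
        for gene in other:
            residue = int(rng.integers(2, 700))
            add(sample, gene, "missense",
                f"{rng.choice(list('ACDEFGHIKLMNPQRSTVWY'))}{residue}"
                f"{rng.choice(list('ACDEFGHIKLMNPQRSTVWY'))}", residue)
        if background_mean > 0:
            already = sum(1 for r in records if r["sample_id"] == sample)
            n_bg = max(int(rng.poisson(background_mean)) - already, 0)
            for _ in range(n_bg):
                gene = f"GENE{int(rng.integers(1, 5000)):04d}"
                residue = int(rng.integers(2, 900))
                vc = str(
                    rng.choice(
                        ["missense", "synonymous", "nonsense", "splice"],
                        p=[0.6, 0.3, 0.05, 0.05],
                    )
                )
                add(sample, gene, vc,
                    f"{rng.choice(list('ACDEFGHIKLMNPQRSTVWY'))}{residue}"
                    f"{rng.choice(list('ACDEFGHIKLMNPQRSTVWY'))}", residue)

    if exclusivity == "almost" and len(drivers) >= 2 and n_samples >= 2:
        n_double = max(1, int(round(0.05 * n_samples))) if n_samples >= 10 else 1
        doubles = rng.choice(n_samples, size=n_double, replace=False)
        for i in doubles:
            sample = f"UM{i + 1:02d}"
            carried = {r["gene"] for r in records if r["sample_id"] == sample}
            free = [g for g in drivers if g not in carried]
            if free:
                gene = str(rng.choice(free))
                residue = int(rng.integers(2, 700))
                add(sample, gene, "missense",
                    f"{rng.choice(list('ACDEFGHIKLMNPQRSTVWY'))}{residue}"
                    f"{rng.choice(list('ACDEFGHIKLMNPQRSTVWY'))}", residue)

    return MutationTable(pd.DataFrame.from_records(records))
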