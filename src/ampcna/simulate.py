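"""Synthetic amplicon-coverage cohorts with known copy-number truth.

The generator emulates a targeted sequencing panel: each cell's coverage
is the product of a base depth, a per-sample library-depth factor, a
per-amplicon PCR-efficiency factor, the sample's bulk copy number at that
amplicon's gene relative to diploid, and multiplicative lognormal noise:

    coverage(a, s) = base_depth * depth(s) * efficiency(a)
                     * bulk_cn(g(a), s) / 2 * exp(noise_sigma * Z(a, s))

Clonal alterations are diluted by tumour purity: a clone at copy number c
in a sample of purity p yields bulk CN = p * c + (1 - p) * 2, so low
purity pulls real alterations back toward the diploid baseline — the
main sensitivity limitation of bulk coverage-based CNA detection.

Spiked alterations must affect fewer than half of the samples of any
amplicon; beyond that the median normalization would absorb the
alteration into the baseline and the truth labels would be meaningless,
so the generator rejects such configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import AmpcnaError, CoverageMatrix
from .significance import CallSet

DIPLOID_CN = 2.0


@dataclass
class SimulationConfig:
    """Cohort-generation settings.

    Defaults emulate a mid-size diagnostic panel run: 48 genes with two
    amplicons each, 100 samples, a mean depth of 1000 reads per amplicon,
    lognormal library-depth and amplicon-efficiency factors (sd of the
    log: 0.5, i.e. a few-fold spread, as seen across real libraries and
    PCR efficiencies), and 10% residual multiplicative noise per cell.
    """

    n_genes: int = 48
    #: fixed count, or inclusive (lo, hi) range drawn per gene from the seed
    amplicons_per_gene: int | tuple[int, int] = 2
    #: explicit per-gene amplicon counts (length n_genes); overrides the above
    amplicon_counts: Optional[Sequence[int]] = None
    n_samples: int = 100
    base_depth: float = 1000.0
    depth_sigma: float = 0.5  # sd of log library-depth factor
    efficiency_sigma: float = 0.5  # sd of log amplicon-efficiency factor
    noise_sigma: float = 0.1  # sd of log per-cell noise
    #: (gene, sample, clonal_cn) triples; ids as generated, e.g. ("G03", "S011", 6.0)
    spiked_cnas: Sequence[tuple[str, str, float]] = field(default_factory=list)
    #: tumour purity per sample: scalar applied to all, or mapping sample -> purity
    purity: float | dict = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("depth_sigma", "efficiency_sigma", "noise_sigma"):
            if getattr(self, name) < 0:
                raise AmpcnaError(f"{name} must be >= 0")
        apg = self.amplicons_per_gene
        min_apg = apg if isinstance(apg, int) else min(apg)
        if self.n_genes < 1 or self.n_samples < 2 or min_apg < 1:
            raise AmpcnaError("cohort dimensions too small")
        if self.amplicon_counts is not None:
            if len(self.amplicon_counts) != self.n_genes:
                raise AmpcnaError("amplicon_counts must have one entry per gene")
            if min(self.amplicon_counts) < 1:
                raise AmpcnaError("every gene needs at least one amplicon")
        if self.base_depth <= 0:
            raise AmpcnaError("base_depth must be positive")
        for g, s, c in self.spiked_cnas:
            if c < 0:
                raise AmpcnaError(f"clonal CN must be >= 0 (gene {g}, sample {s})")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{str(i).zfill(width)}" for i in range(self.n_genes)]

    @property
    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples - 1))
        return [f"S{str(i).zfill(width)}" for i in range(self.n_samples)]

    def purity_of(self, sample: str) -> float:
        p = self.purity[sample] if isinstance(self.purity, dict) else self.purity
        if not 0.0 < p <= 1.0:
            raise AmpcnaError(f"purity of {sample} must be in (0, 1], got {p}")
        return p


@dataclass
class SimulationTruth:
    """Ground truth per (gene, sample): bulk CN and gain/loss/none label."""

    bulk_cn: pd.DataFrame  # genes x samples
    label: pd.DataFrame  # "gain" / "loss" / "none"
    purity: pd.Series  # per sample

    @property
    def gene_ids(self) -> list[str]:
        return list(self.bulk_cn.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.bulk_cn.columns)


def bulk_copy_number(clonal_cn: float, purity: float) -> float:
    """Purity-diluted bulk CN of a clonal alteration in an impure sample."""
    return purity * clonal_cn + (1.0 - purity) * DIPLOID_CN


def simulate_cohort(cfg: SimulationConfig) -> tuple[CoverageMatrix, SimulationTruth]:
    """Generate one cohort and its truth; fully reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids
    samples = cfg.sample_ids
    apg = cfg.amplicons_per_gene
    if cfg.amplicon_counts is not None:
        counts = np.asarray(cfg.amplicon_counts, dtype=int)
    elif isinstance(apg, int):
        counts = np.full(cfg.n_genes, apg)
    else:
        lo, hi = apg
        counts = rng.integers(lo, hi + 1, cfg.n_genes)
    amplicons = [f"{g}_{k + 1}" for g, c in zip(genes, counts) for k in range(c)]
    gene_of = np.repeat(np.arange(cfg.n_genes), counts)

    purity = pd.Series([cfg.purity_of(s) for s in samples], index=samples)
    bulk = np.full((cfg.n_genes, cfg.n_samples), DIPLOID_CN)
    label = np.full((cfg.n_genes, cfg.n_samples), "none", dtype=object)
    spikes_per_gene: dict[str, int] = {}
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: j for j, s in enumerate(samples)}
    for g, s, clonal in cfg.spiked_cnas:
        if g not in gi or s not in si:
            raise AmpcnaError(f"spiked CNA refers to unknown gene/sample ({g}, {s})")
        bulk[gi[g], si[s]] = bulk_copy_number(clonal, purity[s])
        if clonal > DIPLOID_CN:
            label[gi[g], si[s]] = "gain"
        elif clonal < DIPLOID_CN:
            label[gi[g], si[s]] = "loss"
        spikes_per_gene[g] = spikes_per_gene.get(g, 0) + 1
    for g, k in spikes_per_gene.items():
        if k >= cfg.n_samples / 2:
            raise AmpcnaError(
                f"gene {g} is spiked in {k}/{cfg.n_samples} samples; median "
                "normalization requires alterations in fewer than half of the samples"
            )

    depth = np.exp(rng.normal(0.0, cfg.depth_sigma, cfg.n_samples))
    efficiency = np.exp(rng.normal(0.0, cfg.efficiency_sigma, len(amplicons)))
    noise = np.exp(rng.normal(0.0, cfg.noise_sigma, (len(amplicons), cfg.n_samples)))
    coverage = (
        cfg.base_depth
        * depth[None, :]
        * efficiency[:, None]
        * (bulk[gene_of, :] / DIPLOID_CN)
        * noise
    )
    cov = CoverageMatrix(
        values=pd.DataFrame(coverage, index=amplicons, columns=samples), stage="raw"
    )
    truth = SimulationTruth(
        bulk_cn=pd.DataFrame(bulk, index=genes, columns=samples),
        label=pd.DataFrame(label, index=genes, columns=samples),
        purity=purity,
    )
    return cov, truth


def choose_spikes(
    cfg: SimulationConfig,
    fraction: float,
    clonal_cn: float,
    rng: np.random.Generator,
) -> list[tuple[str, str, float]]:
    """Pick round(fraction * n_samples) distinct samples per gene to spike."""
    k = int(round(fraction * cfg.n_samples))
    samples = np.array(cfg.sample_ids)
    spikes = []
    for g in cfg.gene_ids:
        for s in rng.choice(samples, size=k, replace=False):
            spikes.append((g, str(s), clonal_cn))
    return spikes


@dataclass
class RecoveryMetrics:
    sensitivity: float
    specificity: float
    any_false_call: bool  # family-wise false-positive indicator for the replicate
    n_true: int
    n_null: int
    n_called: int
    by_stratum: pd.DataFrame  # sensitivity stratified by (purity, true bulk CN)


def evaluate_recovery(calls: CallSet, truth: SimulationTruth) -> RecoveryMetrics:
    """Compare a gene-level call set against simulation truth.

    Sensitivity counts truth cells recovered with the correct direction;
    specificity counts truth-null cells left uncalled; any call on a
    truth-null cell raises the family-wise false-positive indicator.
    """
    if list(calls.status.index) != truth.gene_ids or list(
        calls.status.columns
    ) != truth.sample_ids:
        raise AmpcnaError("call set and truth have different axes")
    status = calls.status.to_numpy()
    lab = truth.label.to_numpy()
    is_true = lab != "none"
    hit = is_true & (status == lab)
    false_pos = ~is_true & (status != "none")
    n_true = int(is_true.sum())
    n_null = int((~is_true).sum())
    sens = float(hit.sum() / n_true) if n_true else float("nan")
    spec = float(1.0 - false_pos.sum() / n_null) if n_null else float("nan")

    rows = []
    if n_true:
        pur = np.broadcast_to(truth.purity.to_numpy()[None, :], lab.shape)
        cn = truth.bulk_cn.to_numpy()
        strata = pd.DataFrame(
            {
                "purity": pur[is_true],
                "bulk_cn": cn[is_true],
                "recovered": hit[is_true].astype(float),
            }
        )
        rows = strata.groupby(["purity", "bulk_cn"], as_index=False)["recovered"].agg(
            ["mean", "count"]
        )
        rows = rows.rename(columns={"mean": "sensitivity", "count": "n"})
    by_stratum = (
        rows
        if len(rows)
        else pd.DataFrame(columns=["purity", "bulk_cn", "sensitivity", "n"])
    )
    return RecoveryMetrics(
        sensitivity=sens,
        specificity=spec,
        any_false_call=bool(false_pos.any()),
        n_true=n_true,
        n_null=n_null,
        n_called=int((status != "none").sum()),
        by_stratum=by_stratum,
    )
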