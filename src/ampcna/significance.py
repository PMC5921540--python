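"""Outlier significance, Fisher combination, multiple-testing control and calling.

The null model for each amplicon is a normal distribution centred at the
diploid copy number CN = 2 whose scale is the normal-consistent MAD
(median absolute deviation times 1.4826) of that amplicon's CN estimates
across the cohort.  One-sided tail probabilities give separate gain and
loss p-values per amplicon and sample.  In gene-wise mode the amplicon
p-values of a gene are combined with Fisher's method (-2 * sum(ln p) is
chi-square with 2k degrees of freedom under the null).  Corrected
p-values control FWER (Bonferroni) or FDR (Benjamini-Hochberg) over a
configurable scope: none, samples, genes/units, or both.  A gain (loss)
is called when the corrected p-value passes alpha, the CN estimate lies
above (below) 2, and enough individual amplicons support the call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AmpcnaError, CopyNumberMatrix, GeneCopyNumberMatrix, GeneMap

#: normal-consistency factor: sigma = MAD_CONSTANT * median(|x - median(x)|)
MAD_CONSTANT = 1.4826

#: smallest positive double; p-values of exactly 0 are clamped here before ln
TINY_P = np.nextafter(0.0, 1.0)

SCOPES = ("none", "samples", "genes", "both")
METHODS = ("bonferroni", "bh")


@dataclass
class NullModelSet:
    """Per-amplicon normal null: fixed centre 2, MAD-calibrated sigma.

    Amplicons whose MAD is zero have no usable spread estimate; they are
    flagged ``degenerate`` and treated as uncallable (p = 1 both ways).
    """

    sigma: pd.Series
    center: float = 2.0

    @property
    def degenerate(self) -> pd.Series:
        return self.sigma == 0.0

    @property
    def degenerate_amplicons(self) -> list[str]:
        return list(self.sigma.index[self.degenerate])


@dataclass
class SignificanceTable:
    """Gain/loss p-values on one axis (amplicon or gene) x samples."""

    axis: str  # "amplicon" or "gene"
    p_gain: pd.DataFrame
    p_loss: pd.DataFrame
    degenerate_units: list[str] = field(default_factory=list)
    p_gain_corrected: Optional[pd.DataFrame] = None
    p_loss_corrected: Optional[pd.DataFrame] = None
    correction_scope: str = "none"
    correction_method: Optional[str] = None
    zero_p_clamped: int = 0

    @property
    def unit_ids(self) -> list[str]:
        return list(self.p_gain.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.p_gain.columns)


@dataclass
class CallSet:
    """Called gains/losses per unit (gene or amplicon) x sample.

    ``p_corrected`` and ``support_count`` refer to the direction of the
    CN deviation of each cell (gain when CN > 2, loss when CN < 2),
    whether or not the cell was called.
    """

    status: pd.DataFrame  # values in {"gain", "loss", "none"}
    cn: pd.DataFrame
    p_corrected: pd.DataFrame
    support_count: pd.DataFrame
    support_required: pd.Series  # per unit
    alpha: float
    mode: str  # "gene_wise" or "amplicon_wise"
    igi: Optional[pd.Series] = None

    @property
    def n_gains(self) -> int:
        return int((self.status == "gain").to_numpy().sum())

    @property
    def n_losses(self) -> int:
        return int((self.status == "loss").to_numpy().sum())

    @property
    def n_cells(self) -> int:
        return int(self.status.size)

    def to_records(self) -> pd.DataFrame:
        """One row per called alteration (long format)."""
        unit_col = "gene" if self.mode == "gene_wise" else "amplicon"
        rows = []
        mask = self.status != "none"
        for unit in self.status.index:
            for sample in self.status.columns[mask.loc[unit].to_numpy()]:
                rows.append(
                    {
                        "gene": unit,
                        "sample": sample,
                        "status": self.status.at[unit, sample],
                        "CN": self.cn.at[unit, sample],
                        "p_corrected": self.p_corrected.at[unit, sample],
                        "support_count": int(self.support_count.at[unit, sample]),
                    }
                )
        df = pd.DataFrame(
            rows, columns=["gene", "sample", "status", "CN", "p_corrected", "support_count"]
        )
        if unit_col != "gene":
            df = df.rename(columns={"gene": unit_col})
        return df


def fit_null_models(cn: CopyNumberMatrix) -> NullModelSet:
    """Fit the MAD-calibrated normal null to each amplicon's CN row."""
    arr = cn.cn.to_numpy(dtype=float)
    if arr.size == 0:
        raise AmpcnaError("empty copy-number matrix")
    med = np.median(arr, axis=1, keepdims=True)
    mad = np.median(np.abs(arr - med), axis=1)
    sigma = pd.Series(MAD_CONSTANT * mad, index=cn.cn.index)
    return NullModelSet(sigma=sigma)


def amplicon_pvalues(cn: CopyNumberMatrix, nulls: NullModelSet) -> SignificanceTable:
    """One-sided outlier p-values per amplicon and sample.

    z = (CN(a, s) - 2) / sigma_a; p_gain is the upper normal tail, p_loss
    the lower.  Degenerate amplicons get p = 1 in both directions.
    """
    if list(nulls.sigma.index) != list(cn.cn.index):
        raise AmpcnaError("null models were fitted on a different amplicon set")
    sigma = nulls.sigma.to_numpy()
    degen = sigma == 0.0
    safe_sigma = np.where(degen, 1.0, sigma)
    z = (cn.cn.to_numpy() - nulls.center) / safe_sigma[:, None]
    p_gain = stats.norm.sf(z)
    p_loss = stats.norm.cdf(z)
    p_gain[degen, :] = 1.0
    p_loss[degen, :] = 1.0
    idx, cols = cn.cn.index, cn.cn.columns
    return SignificanceTable(
        axis="amplicon",
        p_gain=pd.DataFrame(p_gain, index=idx, columns=cols),
        p_loss=pd.DataFrame(p_loss, index=idx, columns=cols),
        degenerate_units=list(nulls.degenerate_amplicons),
    )


def _fisher_combine(p: np.ndarray) -> tuple[np.ndarray, int]:
    """Fisher's method down axis 0: chi2 survival of -2 sum(ln p) at 2k df."""
    clamped = int((p <= 0).sum())
    p = np.clip(p, TINY_P, None)
    x2 = -2.0 * np.log(p).sum(axis=0)
    k = p.shape[0]
    return stats.chi2.sf(x2, 2 * k), clamped


def combine_fisher(amp_table: SignificanceTable, gmap: GeneMap) -> SignificanceTable:
    """Combine each gene's amplicon p-values into one gene-level p-value.

    Only non-degenerate amplicons enter the combination; a gene with none
    is degenerate at gene level (p = 1 in both directions).
    """
    if amp_table.axis != "amplicon":
        raise AmpcnaError("combine_fisher expects an amplicon-level table")
    degen = set(amp_table.degenerate_units)
    samples = amp_table.sample_ids
    genes = gmap.genes
    p_gain = np.ones((len(genes), len(samples)))
    p_loss = np.ones((len(genes), len(samples)))
    degenerate_genes: list[str] = []
    clamped = 0
    for i, g in enumerate(genes):
        amps = [a for a in gmap.amplicons_of[g] if a not in degen]
        if not amps:
            degenerate_genes.append(g)
            continue
        pg, c1 = _fisher_combine(amp_table.p_gain.loc[amps].to_numpy())
        pl, c2 = _fisher_combine(amp_table.p_loss.loc[amps].to_numpy())
        p_gain[i], p_loss[i] = pg, pl
        clamped += c1 + c2
    return SignificanceTable(
        axis="gene",
        p_gain=pd.DataFrame(p_gain, index=genes, columns=samples),
        p_loss=pd.DataFrame(p_loss, index=genes, columns=samples),
        degenerate_units=degenerate_genes,
        zero_p_clamped=clamped,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one flat family."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


def _bonferroni_factor(scope: str, n_samples: int, n_units: int) -> int:
    return {
        "none": 1,
        "samples": n_samples,
        "genes": n_units,
        "both": n_samples * n_units,
    }[scope]


def _correct_one(p: pd.DataFrame, scope: str, method: str) -> pd.DataFrame:
    n_units, n_samples = p.shape
    arr = p.to_numpy(dtype=float)
    if method == "bonferroni":
        out = np.minimum(arr * _bonferroni_factor(scope, n_samples, n_units), 1.0)
    else:  # bh
        if scope == "none":
            out = arr.copy()
        elif scope == "both":
            out = _bh_adjust(arr.ravel()).reshape(arr.shape)
        elif scope == "samples":
            out = np.vstack([_bh_adjust(row) for row in arr])
        else:  # genes: family = all units within each sample
            out = np.column_stack([_bh_adjust(col) for col in arr.T])
    return pd.DataFrame(out, index=p.index, columns=p.columns)


def correct_pvalues(
    table: SignificanceTable, scope: str, method: str
) -> SignificanceTable:
    """Attach corrected gain/loss p-values for the given scope and method.

    Bonferroni multiplies by the number of tests in scope (capped at 1);
    Benjamini-Hochberg applies the step-up adjustment to the pooled
    family of p-values in scope, separately per direction.
    """
    if scope not in SCOPES:
        raise AmpcnaError(f"unknown correction scope {scope!r}; choose from {SCOPES}")
    if method not in METHODS:
        raise AmpcnaError(f"unknown correction method {method!r}; choose from {METHODS}")
    return SignificanceTable(
        axis=table.axis,
        p_gain=table.p_gain,
        p_loss=table.p_loss,
        degenerate_units=table.degenerate_units,
        p_gain_corrected=_correct_one(table.p_gain, scope, method),
        p_loss_corrected=_correct_one(table.p_loss, scope, method),
        correction_scope=scope,
        correction_method=method,
        zero_p_clamped=table.zero_p_clamped,
    )


def required_support(support: tuple, n_amplicons: int) -> int:
    """Number of supporting amplicon calls required under a support rule.

    ``("none",)`` requires 1; ``("count", k)`` requires k; ``("fraction", f)``
    requires ceil(f * n) so that e.g. 50% of 3 amplicons means at least 2.
    """
    kind = support[0]
    if kind == "none":
        return 1
    if kind == "count":
        return int(support[1])
    if kind == "fraction":
        return math.ceil(float(support[1]) * n_amplicons)
    raise AmpcnaError(f"unknown support rule {support!r}")


def call_cnas(
    gene_table: SignificanceTable,
    gene_cn: GeneCopyNumberMatrix,
    amp_table: SignificanceTable,
    gmap: GeneMap,
    alpha: float = 0.05,
    support: tuple = ("none",),
) -> CallSet:
    """Call gene-level gains and losses.

    A cell (g, s) is a gain iff its corrected gain p-value is below alpha,
    CN(g, s) > 2, and at least the required number of the gene's amplicons
    individually pass the same corrected threshold in the gain direction
    (symmetrically for losses).  ``amp_table`` must carry corrected
    amplicon-level p-values (corrected over the amplicon x sample scope).
    """
    if not 0.0 < alpha < 1.0:
        raise AmpcnaError(f"alpha must be in (0, 1), got {alpha}")
    if gene_table.p_gain_corrected is None or amp_table.p_gain_corrected is None:
        raise AmpcnaError("call_cnas requires corrected p-values on both tables")

    genes, samples = gene_table.unit_ids, gene_table.sample_ids
    cn = gene_cn.cn.loc[genes, samples]
    amp_gain_pass = amp_table.p_gain_corrected < alpha
    amp_loss_pass = amp_table.p_loss_corrected < alpha

    sup_gain = pd.DataFrame(
        {g: amp_gain_pass.loc[gmap.amplicons_of[g]].sum(axis=0) for g in genes}
    ).T.set_axis(samples, axis=1)
    sup_loss = pd.DataFrame(
        {g: amp_loss_pass.loc[gmap.amplicons_of[g]].sum(axis=0) for g in genes}
    ).T.set_axis(samples, axis=1)

    req = pd.Series({g: required_support(support, gmap.n_of(g)) for g in genes})

    gain = (
        (gene_table.p_gain_corrected < alpha)
        & (cn > 2.0)
        & sup_gain.ge(req, axis=0)
    )
    loss = (
        (gene_table.p_loss_corrected < alpha)
        & (cn < 2.0)
        & sup_loss.ge(req, axis=0)
    )

    status = pd.DataFrame("none", index=genes, columns=samples)
    status = status.mask(gain, "gain").mask(loss, "loss")
    # per-cell direction of CN deviation decides which p / support to report
    toward_gain = cn.to_numpy() > 2.0
    p_dir = np.where(
        toward_gain,
        gene_table.p_gain_corrected.to_numpy(),
        gene_table.p_loss_corrected.to_numpy(),
    )
    sup_dir = np.where(toward_gain, sup_gain.to_numpy(), sup_loss.to_numpy())
    return CallSet(
        status=status,
        cn=cn,
        p_corrected=pd.DataFrame(p_dir, index=genes, columns=samples),
        support_count=pd.DataFrame(sup_dir.astype(int), index=genes, columns=samples),
        support_required=req,
        alpha=alpha,
        mode="gene_wise",
    )


def run_amplicon_wise(
    amp_table: SignificanceTable,
    cn: CopyNumberMatrix,
    scope: str = "both",
    method: str = "bonferroni",
    alpha: float = 0.05,
) -> CallSet:
    """Amplicon-resolution calling: each amplicon is its own test unit."""
    if not 0.0 < alpha < 1.0:
        raise AmpcnaError(f"alpha must be in (0, 1), got {alpha}")
    corrected = (
        amp_table
        if amp_table.p_gain_corrected is not None
        else correct_pvalues(amp_table, scope, method)
    )
    amps, samples = corrected.unit_ids, corrected.sample_ids
    cn_df = cn.cn.loc[amps, samples]
    gain = (corrected.p_gain_corrected < alpha) & (cn_df > 2.0)
    loss = (corrected.p_loss_corrected < alpha) & (cn_df < 2.0)
    status = pd.DataFrame("none", index=amps, columns=samples)
    status = status.mask(gain, "gain").mask(loss, "loss")
    toward_gain = cn_df.to_numpy() > 2.0
    p_dir = np.where(
        toward_gain,
        corrected.p_gain_corrected.to_numpy(),
        corrected.p_loss_corrected.to_numpy(),
    )
    called = (status != "none").to_numpy()
    return CallSet(
        status=status,
        cn=cn_df,
        p_corrected=pd.DataFrame(p_dir, index=amps, columns=samples),
        support_count=pd.DataFrame(
            called.astype(int), index=amps, columns=samples
        ),
        support_required=pd.Series(1, index=amps),
        alpha=alpha,
        mode="amplicon_wise",
    )
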