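"""Model/Results interface tying the pipeline together.

:class:`CopyNumberModel` holds a raw coverage cohort, an optional
reference cohort and the amplicon -> gene map; :meth:`CopyNumberModel.fit`
runs normalization, null-model fitting, significance assessment,
multiple-testing correction and calling, and returns a
:class:`CNACallResults` carrying every intermediate table, the call set,
the per-sample IGI quality scores and a text ``summary()``.  Heatmaps and
TSV export hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as aio
from .cluster import AxisOrdering, hierarchical_order, identity_order, render_heatmap, write_ordering
from .containers import (
    AmpcnaError,
    CopyNumberMatrix,
    CoverageMatrix,
    GeneCopyNumberMatrix,
    GeneMap,
)
from .normalize import estimate_copy_numbers, normalize_samples, summarize_gene_cn
from .qc import QCReport, compute_igi
from .significance import (
    CallSet,
    NullModelSet,
    SignificanceTable,
    amplicon_pvalues,
    call_cnas,
    combine_fisher,
    correct_pvalues,
    fit_null_models,
    run_amplicon_wise,
)

MODES = ("gene_wise", "amplicon_wise")


class CopyNumberModel:
    """Copy-number alteration calling model for an amplicon coverage cohort.

    Parameters
    ----------
    coverage
        Raw target-cohort coverages (amplicons x samples).
    gene_map
        Amplicon -> gene assignment; parsed from the amplicon ids with the
        ``delimiter`` when not given.
    reference
        Optional raw coverages of a reference (normal/germline) cohort
        over the identical amplicon set; its per-amplicon medians then
        define the diploid baseline instead of the target cohort's own.
    """

    def __init__(
        self,
        coverage: CoverageMatrix,
        gene_map: Optional[GeneMap] = None,
        reference: Optional[CoverageMatrix] = None,
        delimiter: str = "_",
    ) -> None:
        self.coverage = coverage
        self.reference = reference
        self.gene_map = gene_map or aio.parse_gene_map(
            coverage.amplicon_ids, "prefix_delimiter", delimiter
        )
        unmapped = [a for a in coverage.amplicon_ids if a not in set(self.gene_map.amplicons)]
        if unmapped:
            raise AmpcnaError(f"amplicon(s) missing from the gene map: {unmapped}")

    @classmethod
    def from_tsv(
        cls,
        target_path,
        reference_path=None,
        annotation_path=None,
        delimiter: str = "_",
    ) -> "CopyNumberModel":
        """Build a model from TSV files (several target files are concatenated)."""
        paths = [target_path] if isinstance(target_path, (str, Path)) else list(target_path)
        coverage = aio.concat_coverage([aio.read_coverage_matrix(p) for p in paths])
        reference = (
            aio.read_coverage_matrix(reference_path) if reference_path else None
        )
        gene_map = (
            aio.parse_gene_map(coverage.amplicon_ids, "annotation_file", annotation_path)
            if annotation_path
            else aio.parse_gene_map(coverage.amplicon_ids, "prefix_delimiter", delimiter)
        )
        return cls(coverage, gene_map=gene_map, reference=reference)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        gene_map: Optional[GeneMap] = None,
        reference: Optional[pd.DataFrame] = None,
        delimiter: str = "_",
    ) -> "CopyNumberModel":
        cov = CoverageMatrix(values=df, stage="raw")
        ref = CoverageMatrix(values=reference, stage="raw") if reference is not None else None
        return cls(cov, gene_map=gene_map, reference=ref, delimiter=delimiter)

    def fit(
        self,
        mode: str = "gene_wise",
        scope: str = "both",
        method: str = "bonferroni",
        alpha: float = 0.05,
        support: tuple = ("none",),
    ) -> "CNACallResults":
        """Run the full calling pipeline and return the results object."""
        if mode not in MODES:
            raise AmpcnaError(f"unknown analysis mode {mode!r}; choose from {MODES}")
        target_norm = normalize_samples(self.coverage)
        ref_norm = normalize_samples(self.reference) if self.reference is not None else None
        cn = estimate_copy_numbers(target_norm, ref_norm)
        nulls = fit_null_models(cn)
        amp_raw = amplicon_pvalues(cn, nulls)
        # amplicon-level correction (units = amplicons) drives both the
        # amplicon-wise mode and the support counts of the gene-wise mode
        amp_corr = correct_pvalues(amp_raw, scope, method)
        gene_cn = summarize_gene_cn(cn, self.gene_map)
        qc = compute_igi(cn, gene_cn, self.gene_map, nulls.degenerate_amplicons)

        if mode == "gene_wise":
            gene_raw = combine_fisher(amp_raw, self.gene_map)
            gene_corr = correct_pvalues(gene_raw, scope, method)
            calls = call_cnas(
                gene_corr, gene_cn, amp_corr, self.gene_map, alpha=alpha, support=support
            )
        else:
            gene_corr = None
            calls = run_amplicon_wise(amp_corr, cn, scope, method, alpha)
        calls.igi = qc.igi
        return CNACallResults(
            model=self,
            cn=cn,
            gene_cn=gene_cn,
            nulls=nulls,
            amplicon_table=amp_corr,
            gene_table=gene_corr,
            calls=calls,
            qc=qc,
            mode=mode,
            scope=scope,
            method=method,
            alpha=alpha,
            support=support,
        )


@dataclass
class CNACallResults:
    """Fitted results: CN estimates, significance tables, calls and QC."""

    model: CopyNumberModel
    cn: CopyNumberMatrix
    gene_cn: GeneCopyNumberMatrix
    nulls: NullModelSet
    amplicon_table: SignificanceTable
    gene_table: Optional[SignificanceTable]
    calls: CallSet
    qc: QCReport
    mode: str
    scope: str
    method: str
    alpha: float
    support: tuple

    @property
    def n_gains(self) -> int:
        return self.calls.n_gains

    @property
    def n_losses(self) -> int:
        return self.calls.n_losses

    def summary(self) -> str:
        c = self.model.coverage
        n_cells = self.calls.n_cells
        lines = [
            "Copy-number alteration calling results",
            "=" * 54,
            f"samples:            {len(c.sample_ids)}",
            f"amplicons:          {len(c.amplicon_ids)}",
            f"genes:              {len(self.model.gene_map)}",
            f"reference cohort:   {'yes' if self.cn.reference_used else 'no (internal baseline)'}",
            f"mode:               {self.mode}",
            f"correction:         {self.method} over scope '{self.scope}'",
            f"alpha:              {self.alpha}",
            f"support rule:       {self.support}",
            "-" * 54,
            f"gains called:       {self.n_gains} ({100 * self.n_gains / n_cells:.1f}% of cells)",
            f"losses called:      {self.n_losses} ({100 * self.n_losses / n_cells:.1f}% of cells)",
            f"degenerate amplicons: {len(self.nulls.degenerate_amplicons)}",
            f"median IGI:         {self.qc.igi.median():.3f}",
        ]
        if self.scope == "none" or self.method is None:
            lines.append(
                "note: uncorrected p-values are recommendable only as a search "
                "test; validate candidates with an independent confirmatory assay"
            )
        return "\n".join(lines)

    # -- ordering / plotting -------------------------------------------------

    def gene_ordering(self, cluster: bool = True) -> AxisOrdering:
        m = self.gene_cn.cn
        return hierarchical_order(m, axis="genes") if cluster and len(m) > 1 else identity_order(m.index, "genes")

    def sample_ordering(self, cluster: bool = True) -> AxisOrdering:
        m = self.gene_cn.cn
        return (
            hierarchical_order(m.T, axis="samples")
            if cluster and m.shape[1] > 1
            else identity_order(m.columns, "samples")
        )

    def plot_cn_heatmap(self, path=None, cluster_samples=True, cluster_genes=True):
        return render_heatmap(
            self.gene_cn.cn,
            self.gene_ordering(cluster_genes),
            self.sample_ordering(cluster_samples),
            kind="cn",
            path=path,
            title="Copy-number estimates (genes x samples)",
        )

    def plot_call_heatmap(self, path=None, cluster_samples=True, cluster_genes=True):
        return render_heatmap(
            self.calls.status,
            self.gene_ordering(cluster_genes) if self.mode == "gene_wise" else identity_order(self.calls.status.index, "genes"),
            self.sample_ordering(cluster_samples),
            kind="calls",
            path=path,
            title="CNA calls (gain / loss / none)",
        )

    # -- export --------------------------------------------------------------

    def to_directory(self, outdir, heatmaps: bool = True, cluster_samples=True, cluster_genes=True) -> None:
        """Write every table (and optionally the heatmaps) under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        aio.write_matrix(self.cn.cn, out / "cn_amplicons.tsv", "amplicon")
        aio.write_matrix(self.gene_cn.cn, out / "cn_genes.tsv", "gene")
        t = self.amplicon_table
        aio.write_matrix(t.p_gain, out / "p_gain_amplicons.tsv", "amplicon")
        aio.write_matrix(t.p_loss, out / "p_loss_amplicons.tsv", "amplicon")
        aio.write_matrix(t.p_gain_corrected, out / "p_gain_amplicons_corrected.tsv", "amplicon")
        aio.write_matrix(t.p_loss_corrected, out / "p_loss_amplicons_corrected.tsv", "amplicon")
        if self.gene_table is not None:
            g = self.gene_table
            aio.write_matrix(g.p_gain, out / "p_gain_genes.tsv", "gene")
            aio.write_matrix(g.p_loss, out / "p_loss_genes.tsv", "gene")
            aio.write_matrix(g.p_gain_corrected, out / "p_gain_genes_corrected.tsv", "gene")
            aio.write_matrix(g.p_loss_corrected, out / "p_loss_genes_corrected.tsv", "gene")
        aio.write_calls(self.calls, out / "calls_matrix.tsv", "matrix")
        aio.write_calls(self.calls, out / "calls_by_gene.tsv", "gene_list")
        aio.write_calls(self.calls, out / "calls_by_sample.tsv", "sample_list")
        self.qc.to_frame().to_csv(out / "qc_igi.tsv", sep="\t", index=False)
        (out / "summary.txt").write_text(self.summary() + "\n", encoding="utf-8")
        if heatmaps:
            go = self.gene_ordering(cluster_genes)
            so = self.sample_ordering(cluster_samples)
            write_ordering(go, out / "gene_order.txt")
            write_ordering(so, out / "sample_order.txt")
            render_heatmap(self.gene_cn.cn, go, so, "cn", out / "heatmap_cn.png")
            if self.mode == "gene_wise":
                render_heatmap(self.calls.status, go, so, "calls", out / "heatmap_calls.png")
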