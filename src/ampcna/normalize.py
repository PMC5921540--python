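"""Two-stage median normalization and copy-number estimation.

Stage 1 removes sequencing-depth differences: every sample (column) is
divided by the median of its amplicon coverages.  Stage 2 removes
amplicon-efficiency differences: every amplicon (row) is divided by its
median normalized coverage, taken over a reference cohort when one is
available and over the target cohort otherwise, and multiplied by two so
that the diploid state sits at CN = 2.  All scaling is multiplicative on
the linear scale; medians use the midpoint convention for even counts.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .containers import (
    AmpcnaError,
    CopyNumberMatrix,
    CoverageMatrix,
    GeneCopyNumberMatrix,
    GeneMap,
)


def normalize_samples(m: CoverageMatrix) -> CoverageMatrix:
    """Scale each sample by the median of its amplicon coverages."""
    if m.stage != "raw":
        raise AmpcnaError(f"normalize_samples expects raw coverages, got {m.stage!r}")
    med = m.values.median(axis=0)
    zero = med[med <= 0]
    if len(zero):
        raise AmpcnaError(
            f"sample(s) with zero median coverage (likely failed libraries): "
            f"{list(zero.index)}"
        )
    return m.advanced(m.values.div(med, axis=1), "sample_normalized")


def estimate_copy_numbers(
    target: CoverageMatrix,
    reference: Optional[CoverageMatrix] = None,
) -> CopyNumberMatrix:
    """Scale each amplicon by its median normalized coverage and double it.

    With a reference cohort the per-amplicon medians come from the
    reference (aligned by amplicon id; order may differ); otherwise from
    the target itself, in which case every amplicon's cross-sample CN
    median is exactly 2.
    """
    if target.stage != "sample_normalized":
        raise AmpcnaError(
            f"estimate_copy_numbers expects sample-normalized coverages, got {target.stage!r}"
        )
    if reference is not None:
        if reference.stage != "sample_normalized":
            raise AmpcnaError("reference cohort must be sample-normalized first")
        if set(reference.amplicon_ids) != set(target.amplicon_ids):
            raise AmpcnaError(
                "reference and target amplicon sets differ: "
                f"only in target {sorted(set(target.amplicon_ids) - set(reference.amplicon_ids))}, "
                f"only in reference {sorted(set(reference.amplicon_ids) - set(target.amplicon_ids))}"
            )
        scaler = reference.values.median(axis=1).reindex(target.values.index)
    else:
        scaler = target.values.median(axis=1)
    zero = scaler[scaler <= 0]
    if len(zero):
        raise AmpcnaError(
            f"amplicon(s) with zero scaling median: {list(zero.index)}"
        )
    cn = 2.0 * target.values.div(scaler, axis=0)
    return CopyNumberMatrix(cn=cn, reference_used=reference is not None)


def summarize_gene_cn(cn: CopyNumberMatrix, gmap: GeneMap) -> GeneCopyNumberMatrix:
    """Gene-level CN(g, s): unweighted mean of CN(a, s) over the gene's amplicons."""
    missing = [a for a in gmap.amplicons if a not in cn.cn.index]
    if missing:
        raise AmpcnaError(f"gene map references amplicons absent from CN matrix: {missing}")
    rows = {
        g: cn.cn.loc[amps].mean(axis=0) for g, amps in gmap.amplicons_of.items()
    }
    gene_cn = pd.DataFrame(rows).T.reindex(gmap.genes)
    gene_cn.columns = cn.cn.columns
    return GeneCopyNumberMatrix(cn=gene_cn)
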