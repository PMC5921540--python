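"""Sample-quality control via the intra-gene inconsistency (IGI) statistic.

Amplicons interrogating the same gene should report the same copy number;
disagreement within genes signals degraded DNA or uneven amplification
rather than biology.  IGI(s) sums, over all genes with at least two
amplicons, the sample standard deviation (denominator n(g) - 1) of the
amplicon-level CN estimates of gene g in sample s.  IGI is zero exactly
when every multi-amplicon gene is internally consistent, and grows with
within-gene spread.  Genes with a single amplicon carry no inconsistency
information and are excluded (and reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AmpcnaError, CopyNumberMatrix, GeneCopyNumberMatrix, GeneMap


@dataclass
class QCReport:
    igi: pd.Series  # per sample
    excluded_genes: list[str] = field(default_factory=list)
    degenerate_amplicons: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.igi.index)

    def to_frame(self) -> pd.DataFrame:
        return self.igi.rename("IGI").rename_axis("sample").reset_index()


def compute_igi(
    cn: CopyNumberMatrix,
    gene_cn: GeneCopyNumberMatrix,
    gmap: GeneMap,
    degenerate_amplicons: list[str] | None = None,
) -> QCReport:
    """Intra-gene inconsistency per sample.

    ``gene_cn`` must hold the unweighted amplicon means consistent with
    ``cn`` and ``gmap``; it provides the per-gene centres the deviations
    are taken from.
    """
    samples = cn.sample_ids
    if gene_cn.sample_ids != samples:
        raise AmpcnaError("gene-level CN matrix has a different sample axis")
    total = np.zeros(len(samples))
    excluded: list[str] = []
    for g, amps in gmap.amplicons_of.items():
        n = len(amps)
        if n < 2:
            excluded.append(g)
            continue
        dev = cn.cn.loc[amps].to_numpy() - gene_cn.cn.loc[g].to_numpy()[None, :]
        total += np.sqrt((dev**2).sum(axis=0) / (n - 1))
    return QCReport(
        igi=pd.Series(total, index=samples),
        excluded_genes=excluded,
        degenerate_amplicons=list(degenerate_amplicons or []),
    )
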