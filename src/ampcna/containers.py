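"""Core in-memory containers for amplicon coverage data and gene maps.

All matrices are pandas DataFrames with amplicon (or gene) identifiers on
the row index and sample identifiers on the columns.  Coverage values move
through three one-way stages: ``raw`` read counts, ``sample_normalized``
(each sample divided by its own median coverage) and finally copy-number
estimates on the scale where the diploid state is CN = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("raw", "sample_normalized", "copy_number")


class AmpcnaError(ValueError):
    """Base class for input/contract violations raised by this package."""


def _check_axis_unique(ids, what: str) -> None:
    seen = set()
    dupes = []
    for x in ids:
        if x in seen:
            dupes.append(x)
        seen.add(x)
    if dupes:
        raise AmpcnaError(f"duplicate {what} identifier(s): {sorted(set(dupes))}")
    if len(ids) == 0:
        raise AmpcnaError(f"no {what} identifiers present")


@dataclass
class CoverageMatrix:
    """Amplicon x sample matrix of read coverages (or normalized coverages).

    Parameters
    ----------
    values
        DataFrame with amplicon ids as index, sample ids as columns and
        non-negative numeric entries.
    stage
        One of ``raw``, ``sample_normalized``.  Copy-number scale data live
        in :class:`CopyNumberMatrix` instead.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES[:2]:
            raise AmpcnaError(f"invalid coverage stage {self.stage!r}")
        _check_axis_unique(list(self.values.index), "amplicon")
        _check_axis_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise AmpcnaError("coverage matrix contains missing values")
        if (arr < 0).any():
            raise AmpcnaError("coverage matrix contains negative values")
        self.values = self.values.astype(float)

    @property
    def amplicon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def advanced(self, values: pd.DataFrame, stage: str) -> "CoverageMatrix":
        """Return a new matrix at a later stage; transitions are one-way."""
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise AmpcnaError(
                f"stage transition {self.stage!r} -> {stage!r} is not allowed"
            )
        return CoverageMatrix(values=values, stage=stage)


@dataclass
class GeneMap:
    """Mapping gene -> ordered list of the amplicons interrogating it.

    Every amplicon belongs to exactly one gene; gene order is the order of
    first appearance in the input.
    """

    amplicons_of: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.amplicons_of:
            raise AmpcnaError("gene map is empty")
        all_amps: list[str] = []
        for g, amps in self.amplicons_of.items():
            if len(amps) == 0:
                raise AmpcnaError(f"gene {g!r} maps to no amplicons")
            all_amps.extend(amps)
        _check_axis_unique(all_amps, "amplicon")
        self._gene_of = {a: g for g, amps in self.amplicons_of.items() for a in amps}

    @property
    def genes(self) -> list[str]:
        return list(self.amplicons_of)

    @property
    def amplicons(self) -> list[str]:
        return [a for amps in self.amplicons_of.values() for a in amps]

    def n_of(self, gene: str) -> int:
        return len(self.amplicons_of[gene])

    def gene_of(self, amplicon: str) -> str:
        return self._gene_of[amplicon]

    def __len__(self) -> int:
        return len(self.amplicons_of)


@dataclass
class CopyNumberMatrix:
    """Per-amplicon copy-number estimates CN(a, s) on the diploid CN = 2 scale."""

    cn: pd.DataFrame
    reference_used: bool = False

    def __post_init__(self) -> None:
        _check_axis_unique(list(self.cn.index), "amplicon")
        _check_axis_unique(list(self.cn.columns), "sample")
        arr = self.cn.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise AmpcnaError("copy-number matrix contains non-finite values")
        if (arr < 0).any():
            raise AmpcnaError("copy-number matrix contains negative values")

    @property
    def amplicon_ids(self) -> list[str]:
        return list(self.cn.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cn.columns)


@dataclass
class GeneCopyNumberMatrix:
    """Gene-level copy numbers: unweighted mean of CN(a, s) over a gene's amplicons."""

    cn: pd.DataFrame  # genes x samples

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cn.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cn.columns)
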