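"""Per-contig, per-sample coverage and its pre-clustering transform.

Differential-coverage binning exploits that contigs from one genome share an
abundance trajectory across samples (here, time points). The raw signal is a
matrix of mean sequencing depths; before distances are computed the matrix is
depth-normalised per sample (so samples sequenced deeper do not dominate) and
log-transformed (depth noise is multiplicative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CoverageMatrix:
    """Mean depth of each contig in each sample.

    Rows follow ``contig_ids``; columns follow ``samples``. Values are mean
    per-base depths, hence non-negative and independent of contig length.
    """

    contig_ids: list[str]
    samples: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.contig_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.contig_ids)} contigs x {len(self.samples)} samples"
            )
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")
        if len(set(self.contig_ids)) != len(self.contig_ids):
            raise ValueError("contig_ids must be unique")

    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.contig_ids, name="contig_id"),
                            columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CoverageMatrix":
        return cls(list(frame.index.astype(str)), list(frame.columns.astype(str)),
                   frame.to_numpy(dtype=float))


def prepare_coverage(cov: CoverageMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """Depth-normalise per sample, then log10-transform.

    Each column is scaled so all column sums equal the largest column sum
    (equalising sequencing effort across samples), then the matrix is mapped
    elementwise through ``log10(x + pseudocount)``.

    Raises ``ValueError`` for a non-positive pseudocount or an all-zero
    sample column (a degenerate sample carries no depth information).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    colsums = cov.values.sum(axis=0)
    if (colsums == 0).any():
        bad = [s for s, c in zip(cov.samples, colsums) if c == 0]
        raise ValueError(f"all-zero coverage column(s): {', '.join(bad)}")
    scaled = cov.values * (colsums.max() / colsums)
    return np.log10(scaled + pseudocount)
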