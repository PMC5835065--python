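"""qPCR absolute quantification via a serially diluted standard curve.

A dilution series of known copy numbers yields a line Ct = slope·log10(copies)
+ intercept (slope negative; perfect doubling gives slope −1/log10(2) ≈
−3.32 and 100% amplification efficiency). Unknown Ct values are inverted
through the fitted line to absolute gene copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class QpcrStandardCurve:
    slope: float  # Ct per log10(copies), negative
    intercept: float  # Ct at 1 copy
    efficiency: float  # fraction; 1.0 = perfect doubling per cycle
    r2: float


def qpcr_quantify(standards: Sequence[tuple[float, float]],
                  unknowns: Sequence[float]) -> tuple[np.ndarray, QpcrStandardCurve]:
    """Quantify unknown Ct values against (log10_copies, Ct) standards.

    Requires at least three standards spanning at least two log10 units.
    Raises ``ValueError`` if the fitted slope is non-negative (inverted or
    mislabelled standards).
    """
    logc = np.array([s[0] for s in standards], dtype=float)
    ct = np.array([s[1] for s in standards], dtype=float)
    if logc.size < 3:
        raise ValueError("need at least 3 standards")
    if logc.max() - logc.min() < 2.0:
        raise ValueError("standards must span at least 2 log10 units")
    res = stats.linregress(logc, ct)
    if res.slope >= 0:
        raise ValueError("fitted standard-curve slope is non-negative: inverted standards?")
    curve = QpcrStandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(10.0 ** (-1.0 / res.slope) - 1.0),
        r2=float(res.rvalue**2),
    )
    unknowns_arr = np.asarray(unknowns, dtype=float)
    copies = 10.0 ** ((unknowns_arr - curve.intercept) / curve.slope)
    return copies, curve
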