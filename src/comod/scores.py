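"""Element x cluster score matrices.

All scorers produce log-likelihood-like scores where *lower is better*.
NaN marks an unscorable (element, cluster) entry; before combination those
entries are imputed with the column's worst finite score so that being
unscorable is never attractive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScoreMatrix:
    row_ids: list[str]
    values: np.ndarray          # |rows| x k, lower = better
    kind: str = ""              # R | S | T | E | M | p

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_ids):
            raise ValueError("score matrix shape mismatch")

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def imputed(self) -> np.ndarray:
        """Values with unscorable entries replaced by the column's worst score."""
        out = self.values.copy()
        for j in range(out.shape[1]):
            col = out[:, j]
            bad = ~np.isfinite(col)
            if bad.any():
                finite = col[~bad]
                col[bad] = finite.max() if finite.size else 0.0
        return out
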