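"""Linkage-disequilibrium correlation matrices used for instrument clumping.

An :class:`LDMatrix` stores pairwise correlations ``r`` (not r-squared)
between variants, in a fixed variant order, optionally annotated with
chromosome/position so clumping can apply its physical window.  Variants
absent from the matrix are treated as independent by the clumping routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

#: eigenvalue tolerance for the positive-semidefinite check
PSD_TOL = 1e-8


@dataclass
class LDMatrix:
    """Symmetric correlation matrix over an ordered set of variants."""

    ids: list[str]
    r: np.ndarray
    validate: bool = True
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise InvalidParameterError("LD matrix must be square")
        if len(self.ids) != self.r.shape[0]:
            raise InvalidParameterError("variant ids do not match matrix size")
        if len(set(self.ids)) != len(self.ids):
            raise InvalidParameterError("duplicate variant ids in LD matrix")
        if self.validate:
            if not np.allclose(self.r, self.r.T, atol=1e-10):
                raise InvalidParameterError("LD matrix must be symmetric")
            if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
                raise InvalidParameterError("LD matrix diagonal must be 1")
            if np.abs(self.r).max() > 1 + 1e-10:
                raise InvalidParameterError("correlations must lie in [-1, 1]")
            if np.linalg.eigvalsh(self.r).min() < -PSD_TOL:
                raise InvalidParameterError(
                    "LD matrix is not positive semi-definite within tolerance"
                )
        self._index = {rsid: i for i, rsid in enumerate(self.ids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def __len__(self) -> int:
        return len(self.ids)

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants (0.0 if either is absent)."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r[ia, ib] ** 2)

    def to_tsv(self, path: str | Path) -> None:
        """Write as a dense tab-separated matrix with id header row/column."""
        pd.DataFrame(self.r, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="rsid"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, validate: bool = True) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(c) for c in df.columns], r=df.to_numpy(float), validate=validate)
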