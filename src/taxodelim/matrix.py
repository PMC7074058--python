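"""Labeled symmetric matrices of pairwise distances or percent similarities.

A :class:`DistanceMatrix` is the common currency between the metric modules
(MLSA, ANIb, POCP, surrogate dDDH) and the downstream consumers (tree
building, threshold clustering).  Two modes exist:

* ``"distance"`` — substitutions/site or any non-negative distance, zero
  diagonal;
* ``"percent"`` — percent similarity in [0, 100], diagonal fixed at 100.

Missing pairs are represented as NaN (percent mode only); consumers decide
whether that is an error.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]

_MODES = ("distance", "percent")


class DistanceMatrix:
    """Symmetric labeled matrix with a mode flag.

    Parameters
    ----------
    labels:
        Ordered, unique strain identifiers.
    values:
        Square array-like, symmetric up to ``1e-8``.
    mode:
        ``"distance"`` (zero diagonal, entries >= 0) or ``"percent"``
        (diagonal 100, entries in [0, 100], NaN allowed off-diagonal).
    """

    def __init__(self, labels: Sequence[str], values, mode: str) -> None:
        labels = [str(l) for l in labels]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError(
                f"matrix shape {values.shape} does not match {len(labels)} labels"
            )
        if mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(values - values.T), initial=0.0)
        if asym > 1e-8:
            raise ValueError(f"matrix is not symmetric (max deviation {asym:g})")
        diag = np.diagonal(values)
        target = 0.0 if mode == "distance" else 100.0
        if np.nanmax(np.abs(diag - target), initial=0.0) > 1e-8:
            raise ValueError(f"{mode} matrix must have diagonal {target}")
        finite = values[np.isfinite(values)]
        if finite.size and finite.min() < -1e-12:
            raise ValueError("negative entries not allowed")
        if mode == "percent" and finite.size and finite.max() > 100 + 1e-9:
            raise ValueError("percent similarities must be <= 100")
        if mode == "distance" and np.isnan(values).any():
            raise ValueError("NaN entries only allowed in percent mode")
        # store symmetrized to wash out float round-off
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, target)
        self.labels: list[str] = labels
        self.values: np.ndarray = values
        self.mode: str = mode
        self._index = {l: i for i, l in enumerate(labels)}

    # -- construction ----------------------------------------------------
    @classmethod
    def from_pair_values(
        cls,
        labels: Sequence[str],
        pair_value: Callable[[str, str], float] | dict,
        mode: str,
    ) -> "DistanceMatrix":
        """Build from a callable or dict keyed by frozenset({a, b})."""
        labels = list(labels)
        n = len(labels)
        vals = np.zeros((n, n))
        if mode == "percent":
            np.fill_diagonal(vals, 100.0)
        for i in range(n):
            for j in range(i + 1, n):
                if callable(pair_value):
                    v = pair_value(labels[i], labels[j])
                else:
                    v = pair_value[frozenset((labels[i], labels[j]))]
                vals[i, j] = vals[j, i] = v
        return cls(labels, vals, mode)

    @classmethod
    def from_tsv(cls, path, mode: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("TSV matrix rows and columns must agree")
        return cls(list(df.index), df.values, mode)

    # -- access ----------------------------------------------------------
    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for i, a in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                yield a, self.labels[j], float(self.values[i, j])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.mode)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")

    def to_phylip(self, path) -> None:
        """Square PHYLIP format, as consumed by classic tree programs."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                cells = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{label:<12s}{cells}\n")
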