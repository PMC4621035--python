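"""Core value types shared across the alignment pipeline."""

from __future__ import annotations

import dataclasses

import numpy as np


class Alignment:
    """A strictly monotone list of aligned residue-index pairs (iA, iB).

    Stored as an (L, 2) integer array; may be empty.  Both coordinates must
    be strictly increasing, which is what makes the list a sequence
    alignment rather than an arbitrary matching.
    """

    __slots__ = ("pairs",)

    def __init__(self, pairs) -> None:
        arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        if len(arr) > 1:
            d = np.diff(arr, axis=0)
            if not np.all(d > 0):
                raise ValueError("alignment pairs must be strictly increasing "
                                 "in both coordinates")
        if len(arr) and arr.min() < 0:
            raise ValueError("negative residue index in alignment")
        self.pairs = arr

    @classmethod
    def empty(cls) -> "Alignment":
        return cls(np.empty((0, 2), dtype=np.int64))

    @classmethod
    def identity(cls, n: int) -> "Alignment":
        idx = np.arange(n, dtype=np.int64)
        return cls(np.column_stack([idx, idx]))

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.pairs.shape == other.pairs.shape and bool(
            np.array_equal(self.pairs, other.pairs))

    def __hash__(self) -> int:
        return hash(self.key())

    def key(self) -> bytes:
        """Canonical hashable form, used for de-duplication."""
        return self.pairs.tobytes()

    def as_tuples(self) -> list[tuple[int, int]]:
        return [tuple(p) for p in self.pairs.tolist()]

    def shifted(self, dA: int, dB: int) -> "Alignment":
        return Alignment(self.pairs + np.array([dA, dB]))

    def __repr__(self) -> str:
        return f"Alignment(L={len(self)})"


@dataclasses.dataclass(frozen=True)
class GapPenalty:
    """Affine gap cost g(k) = open + extend * (k - 1) for a run of k gaps."""

    open: float
    extend: float

    def __post_init__(self):
        if self.open < 0 or self.extend < 0:
            raise ValueError("gap penalties must be non-negative")

    def cost(self, k: int) -> float:
        return 0.0 if k <= 0 else self.open + self.extend * (k - 1)
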