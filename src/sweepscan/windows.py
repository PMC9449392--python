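"""Half-step sliding-window engine.

Default geometry is 100-kb windows advancing by 50 kb, so every interior
base is covered by exactly two windows; trailing partial windows are emitted
(flagged ``truncated``) so the union of windows always equals the contig.
Window identity is (contig, start) — the key used when combining evidence
across statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sweepscan.core_io import VariantMatrix

DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_WINDOW_STEP = 50_000


@dataclass
class Window:
    contig: str
    start: int          # 0-based half-open
    end: int
    truncated: bool = False
    snp_indices: np.ndarray | None = field(default=None, repr=False)

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.start)

    @property
    def n_snps(self) -> int:
        return 0 if self.snp_indices is None else len(self.snp_indices)


def make_windows(
    contig: str,
    contig_length: int,
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
) -> list[Window]:
    """Sliding windows starting at 0, step, 2*step, ... while start < length.

    The final windows are truncated at the contig end rather than dropped.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if step > size:
        raise ValueError("step must not exceed window size")
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    out = []
    for start in range(0, contig_length, step):
        end = min(start + size, contig_length)
        out.append(Window(contig, start, end, truncated=(end - start) < size))
    return out


def assign_snps(wins: list[Window], vm: VariantMatrix) -> list[Window]:
    """Fill snp_indices by binary search on the sorted 1-based positions.

    A SNP at 1-based POS belongs to window [start, end) iff
    start <= POS-1 < end.
    """
    pos0 = vm.positions - 1  # to 0-based
    for w in wins:
        if w.contig != vm.contig:
            raise ValueError(f"contig mismatch: window {w.contig} vs matrix {vm.contig}")
        lo = np.searchsorted(pos0, w.start, side="left")
        hi = np.searchsorted(pos0, w.end, side="left")
        w.snp_indices = np.arange(lo, hi, dtype=np.intp)
    return wins
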