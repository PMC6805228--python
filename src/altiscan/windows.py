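"""Sliding-window generation and site-to-window assignment.

The genome scan uses 100 kb windows advanced by 15 kb; fine-mapping uses
non-overlapping 20 kb windows.  Windows are anchored at coordinate 1 and are
1-based inclusive: window w covers [start, start + size - 1].  A site at
position p belongs to every window whose span contains p, so with step <
size a site has multiple memberships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import GenotypeMatrix


@dataclass
class WindowSpec:
    """Window geometry and eligibility.

    size/step in bp (scan default 100 kb / 15 kb; fine-map 20 kb / 20 kb);
    windows with fewer than ``min_snps`` assigned sites are flagged
    insufficient and excluded from outlier quantile ranking.
    """

    size: int = 100_000
    step: int = 15_000
    min_snps: int = 10
    keep_partial_last: bool = False

    def __post_init__(self) -> None:
        if self.size <= 0 or self.step <= 0:
            raise ValueError("size and step must be positive")
        if self.step > self.size:
            raise ValueError("step must not exceed size")


@dataclass
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    site_idx: np.ndarray = field(default_factory=lambda: np.empty(0, np.intp))
    insufficient: bool = True

    @property
    def n_snps(self) -> int:
        return len(self.site_idx)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def make_windows(
    contig_length: int, spec: WindowSpec, chrom: str = ""
) -> list[Window]:
    """Windows starting at 1, 1+step, 1+2*step, ... within the contig.

    Only windows fully inside the contig are emitted unless
    ``keep_partial_last`` adds one trailing truncated window.
    """
    if contig_length < 1:
        raise ValueError("contig_length must be >= 1")
    out = []
    start = 1
    while start + spec.size - 1 <= contig_length:
        out.append(Window(chrom, start, start + spec.size - 1))
        start += spec.step
    if spec.keep_partial_last and start <= contig_length:
        out.append(Window(chrom, start, contig_length))
    return out


def assign_sites(
    windows: list[Window], matrix: GenotypeMatrix, min_snps: int = 10
) -> list[Window]:
    """Attach contained site indices to each window (in place, returned).

    Windows are assumed to lie on a single contig matching the matrix
    subset they are applied to; a mixed-contig matrix must be split first.
    """
    if windows and matrix.n_sites:
        chroms = set(matrix.chrom)
        wchrom = {w.chrom for w in windows}
        if not wchrom.issubset(chroms | {""}):
            raise ValueError(f"window contigs {wchrom} not in matrix {chroms}")
    pos = matrix.positions
    for w in windows:
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        w.site_idx = np.arange(lo, hi, dtype=np.intp)
        w.insufficient = w.n_snps < min_snps
    return windows
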