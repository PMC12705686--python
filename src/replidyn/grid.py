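"""Fixed-width genomic bin grids.

A :class:`BinGrid` is the coordinate backbone for every DNA-side data
structure in the package: per-cell bin counts, binarized replication
states, average replication-timing profiles and CNV segments all carry
their values as flat arrays aligned to one grid.  Coordinates are 0-based
half-open throughout.  Because bins are non-overlapping, sorted and (except
possibly the last bin of each chromosome) of constant width, interval
queries reduce to integer arithmetic and ``searchsorted`` -- no interval
tree is needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ArgumentError, StructuralError

__all__ = ["BinGrid"]


class BinGrid:
    """Sorted, non-overlapping, fixed-width genomic bins.

    Parameters
    ----------
    bins : pandas.DataFrame
        Columns ``chrom``, ``start``, ``end``.  Must be sorted by
        (chrom, start), non-overlapping within each chromosome, and of
        constant width except possibly the last bin per chromosome.
    """

    def __init__(self, bins: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required.issubset(bins.columns):
            raise StructuralError(f"bin table needs columns {sorted(required)}")
        bins = bins.reset_index(drop=True)
        chrom = bins["chrom"].to_numpy()
        start = bins["start"].to_numpy(dtype=np.int64)
        end = bins["end"].to_numpy(dtype=np.int64)
        if len(bins) == 0:
            raise ArgumentError("empty bin grid")
        if np.any(end <= start):
            i = int(np.argmax(end <= start))
            raise StructuralError(f"bin {i}: end <= start")
        widths = []
        for c in pd.unique(chrom):
            m = chrom == c
            s, e = start[m], end[m]
            if np.any(np.diff(s) <= 0):
                raise StructuralError(f"bins on {c} are unsorted or duplicated")
            if np.any(s[1:] < e[:-1]):
                i = int(np.argmax(s[1:] < e[:-1]))
                raise StructuralError(f"overlapping bins on {c} near index {i}")
            w = e - s
            if len(w) > 1 and len(np.unique(w[:-1])) > 1:
                raise StructuralError(f"non-constant bin width on {c}")
            widths.append(w[0] if len(w) == 1 else w[0])
        self._df = bins[["chrom", "start", "end"]].copy()
        self.chrom = chrom
        self.start = start
        self.end = end
        self.width = int(np.max(widths))
        # per-chromosome slices in grid order
        self._chrom_slices: dict[str, slice] = {}
        for c in pd.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            self._chrom_slices[c] = slice(int(idx[0]), int(idx[-1]) + 1)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_chrom_sizes(cls, chrom_sizes: dict[str, int], width: int) -> "BinGrid":
        """Tile chromosomes with ``width``-bp bins (last bin may be short)."""
        if width <= 0:
            raise ArgumentError("bin width must be positive")
        rows = []
        for c, size in chrom_sizes.items():
            starts = np.arange(0, size, width, dtype=np.int64)
            ends = np.minimum(starts + width, size)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return cls(pd.concat(rows, ignore_index=True))

    # -- basics ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_slices)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def chrom_mask(self, chroms) -> np.ndarray:
        """Boolean mask of bins lying on any of ``chroms``."""
        chroms = set(chroms)
        return np.isin(self.chrom, list(chroms))

    def same_grid(self, other: "BinGrid") -> bool:
        return (
            len(self) == len(other)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
        )

    def bin_ids(self) -> pd.Index:
        return pd.Index(
            [f"{c}:{s}-{e}" for c, s, e in zip(self.chrom, self.start, self.end)]
        )

    # -- interval queries --------------------------------------------------
    def region_mask(self, regions: pd.DataFrame) -> np.ndarray:
        """Boolean mask of bins overlapping any region (e.g. a blacklist BED).

        ``regions`` has columns chrom/start/end, 0-based half-open.
        """
        mask = np.zeros(len(self), dtype=bool)
        if regions is None or len(regions) == 0:
            return mask
        for c, grp in regions.groupby("chrom"):
            if c not in self._chrom_slices:
                continue
            sl = self._chrom_slices[c]
            rs = grp["start"].to_numpy(dtype=np.int64)
            re = grp["end"].to_numpy(dtype=np.int64)
            order = np.argsort(rs)
            rs, re = rs[order], re[order]
            cummax_end = np.maximum.accumulate(re)
            bs, be = self.start[sl], self.end[sl]
            # a bin overlaps some region iff among regions with start < bin end
            # the running max end exceeds the bin start
            k = np.searchsorted(rs, be, side="left")
            hit = (k > 0) & (cummax_end[np.maximum(k - 1, 0)] > bs)
            mask[sl] = hit
        return mask

    def bins_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of bins with any base-pair overlap with [start, end)."""
        if chrom not in self._chrom_slices:
            return np.array([], dtype=np.int64)
        sl = self._chrom_slices[chrom]
        bs, be = self.start[sl], self.end[sl]
        lo = np.searchsorted(be, start, side="right")
        hi = np.searchsorted(bs, end, side="left")
        return np.arange(sl.start + lo, sl.start + hi, dtype=np.int64)

    def coarsen(self, factor: int) -> tuple["BinGrid", np.ndarray]:
        """Merge ``factor`` consecutive bins per chromosome.

        Returns the coarse grid and, for each fine bin, the index of the
        coarse bin it belongs to.  Used to re-bin 40-kb counts to the 200-kb
        windows of the MAD score, or to coarser CNV bin sizes.
        """
        if factor < 1:
            raise ArgumentError("factor must be >= 1")
        group = np.empty(len(self), dtype=np.int64)
        rows = []
        offset = 0
        for c in self.chroms:
            sl = self._chrom_slices[c]
            n = sl.stop - sl.start
            g = np.arange(n) // factor
            group[sl] = g + offset
            n_coarse = int(g[-1]) + 1
            starts = self.start[sl][:: factor]
            ends = np.empty(n_coarse, dtype=np.int64)
            for j in range(n_coarse):
                ends[j] = self.end[sl][min((j + 1) * factor - 1, n - 1)]
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
            offset += n_coarse
        return BinGrid(pd.concat(rows, ignore_index=True)), group
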