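"""Binned genomic track data model.

All pipeline stages operate on fixed-width genomic bins (1 kb by default).
Two container types cover every signal in the pipeline:

* :class:`StrandBinTrack` — per-bin values kept separately for the Watson
  (reference-forward) and Crick (reference-reverse) strands, e.g. raw or
  depth-normalised rNMP 5'-end counts.
* :class:`IndexTrack` — a single signed per-bin signal such as an RFD,
  initiation index, fork index or coupling index.

Both carry a per-bin validity mask; masked bins (low read count, zero
denominators, chromosome edges of differentials) are excluded from every
downstream statistic.  Coordinates are 0-based half-open; bin ``i`` spans
``[i*bin_size, (i+1)*bin_size)`` and is reported at its start coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "StrandBinTrack",
    "IndexTrack",
    "moving_average",
    "znorm_shift",
    "diff_track",
    "read_layout",
    "write_layout",
    "read_strand_csv",
    "write_strand_csv",
    "read_bedgraph",
    "write_bedgraph",
    "read_wig",
    "write_wig",
]


class TrackError(ValueError):
    """Raised on contract violations: layout mismatches, malformed files."""


@dataclass(frozen=True)
class GenomeLayout:
    """Partition of a genome into fixed-width bins.

    Parameters
    ----------
    chromosomes:
        Mapping of chromosome name to length in base pairs, in a stable
        order.  Each chromosome is split into ``ceil(length / bin_size)``
        bins; the final bin may be short.
    bin_size:
        Bin width in base pairs (default 1000).
    """

    chromosomes: Tuple[Tuple[str, int], ...]
    bin_size: int = 1000

    def __init__(self, chromosomes: Mapping[str, int] | Iterable[Tuple[str, int]],
                 bin_size: int = 1000):
        items = tuple(chromosomes.items()) if isinstance(chromosomes, Mapping) \
            else tuple((str(c), int(n)) for c, n in chromosomes)
        if bin_size <= 0:
            raise TrackError("bin_size must be positive")
        if not items:
            raise TrackError("layout needs at least one chromosome")
        for name, length in items:
            if length <= 0:
                raise TrackError(f"chromosome {name!r} has non-positive length")
        object.__setattr__(self, "chromosomes", items)
        object.__setattr__(self, "bin_size", int(bin_size))

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for c, n in self.chromosomes:
            if c == chrom:
                return n
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self.chromosomes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.length(chrom) // self.bin_size)

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_size

    def bin_centers(self, chrom: str) -> np.ndarray:
        """Midpoint of each bin (final short bin uses its true midpoint)."""
        starts = self.bin_starts(chrom)
        ends = np.minimum(starts + self.bin_size, self.length(chrom))
        return (starts + ends) / 2.0

    def bin_index(self, chrom: str, position: int) -> int:
        if not 0 <= position < self.length(chrom):
            raise TrackError(
                f"position {position} outside chromosome {chrom!r}")
        return int(position) // self.bin_size

    def zeros(self, dtype=float) -> Dict[str, np.ndarray]:
        return {c: np.zeros(self.n_bins(c), dtype=dtype) for c in self.names}

    def full_mask(self, value: bool = True) -> Dict[str, np.ndarray]:
        return {c: np.full(self.n_bins(c), value, dtype=bool)
                for c in self.names}


def _check_arrays(layout: GenomeLayout, arrays: Mapping[str, np.ndarray],
                  what: str) -> Dict[str, np.ndarray]:
    out = {}
    for chrom in layout.names:
        if chrom not in arrays:
            raise TrackError(f"{what} missing chromosome {chrom!r}")
        a = np.asarray(arrays[chrom])
        if a.shape != (layout.n_bins(chrom),):
            raise TrackError(
                f"{what}[{chrom!r}] has shape {a.shape}, expected "
                f"({layout.n_bins(chrom)},)")
        out[chrom] = a
    return out


@dataclass
class StrandBinTrack:
    """Per-bin values on the Watson and Crick strands with a validity mask."""

    layout: GenomeLayout
    watson: Dict[str, np.ndarray]
    crick: Dict[str, np.ndarray]
    mask: Dict[str, np.ndarray] = None  # True = valid bin

    def __post_init__(self):
        self.watson = _check_arrays(self.layout, self.watson, "watson")
        self.crick = _check_arrays(self.layout, self.crick, "crick")
        if self.mask is None:
            self.mask = self.layout.full_mask()
        self.mask = {c: np.asarray(m, dtype=bool)
                     for c, m in _check_arrays(self.layout, self.mask,
                                               "mask").items()}

    def copy(self) -> "StrandBinTrack":
        return StrandBinTrack(
            self.layout,
            {c: v.copy() for c, v in self.watson.items()},
            {c: v.copy() for c, v in self.crick.items()},
            {c: v.copy() for c, v in self.mask.items()},
        )

    def strand_total(self, strand: str) -> float:
        arrays = self.watson if strand == "watson" else self.crick
        return float(sum(a.sum() for a in arrays.values()))

    def total(self) -> float:
        return self.strand_total("watson") + self.strand_total("crick")


@dataclass
class IndexTrack:
    """A single signed per-bin signal (RFD, Ini, Fk, CI, ...).

    ``normalization`` records the (mean, sd) of the unmasked values at the
    time a Z-shift was applied, for provenance.
    """

    layout: GenomeLayout
    values: Dict[str, np.ndarray]
    mask: Dict[str, np.ndarray] = None
    normalization: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.values = {c: np.asarray(v, dtype=float)
                       for c, v in _check_arrays(self.layout, self.values,
                                                 "values").items()}
        if self.mask is None:
            self.mask = self.layout.full_mask()
        self.mask = {c: np.asarray(m, dtype=bool)
                     for c, m in _check_arrays(self.layout, self.mask,
                                               "mask").items()}

    def copy(self) -> "IndexTrack":
        return IndexTrack(
            self.layout,
            {c: v.copy() for c, v in self.values.items()},
            {c: m.copy() for c, m in self.mask.items()},
            self.normalization,
        )

    def unmasked_values(self) -> np.ndarray:
        """All valid values, concatenated genome-wide."""
        return np.concatenate(
            [self.values[c][self.mask[c]] for c in self.layout.names]
        ) if self.layout.names else np.empty(0)

    def smoothed(self, m: int) -> "IndexTrack":
        """Moving average of half-width ``m`` bins, per chromosome."""
        vals, mask = {}, {}
        for c in self.layout.names:
            vals[c], mask[c] = moving_average(self.values[c], self.mask[c], m)
        return IndexTrack(self.layout, vals, mask, self.normalization)


# ---------------------------------------------------------------------------
# core per-chromosome operations
# ---------------------------------------------------------------------------

def _window_sums(a: np.ndarray, m: int) -> np.ndarray:
    """Sum over the window [i-m, i+m], truncated at the array ends."""
    n = a.shape[0]
    c = np.concatenate([[0.0], np.cumsum(a, dtype=float)])
    idx = np.arange(n)
    hi = np.minimum(idx + m + 1, n)
    lo = np.maximum(idx - m, 0)
    return c[hi] - c[lo]


def moving_average(values: np.ndarray, mask: np.ndarray,
                   m: int) -> Tuple[np.ndarray, np.ndarray]:
    """Centred moving average of 2m+1 bins over one chromosome.

    Each output bin is the mean of the *unmasked* values in its window;
    windows are truncated at chromosome ends rather than padded, so
    telomeric bins stay defined.  Bins whose window contains no unmasked
    value are masked in the output.  ``m = 0`` is the identity.
    """
    if m < 0:
        raise TrackError("m must be non-negative")
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if m == 0:
        return values.copy(), mask.copy()
    num = _window_sums(np.where(mask, values, 0.0), m)
    den = _window_sums(mask.astype(float), m)
    out_mask = den > 0
    out = np.zeros_like(values)
    out[out_mask] = num[out_mask] / den[out_mask]
    return out, out_mask


def znorm_shift(values: np.ndarray, mask: np.ndarray = None,
                ) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Z-score normalise, then subtract Z(0) to keep the sign structure.

    Z(x) - Z(0) = (x - mu)/sd - (0 - mu)/sd = x / sd, so this is a pure
    rescaling by the population standard deviation of the unmasked values:
    zeros stay zero and signs are preserved.  Returns the rescaled array
    (masked entries passed through untouched) and the (mean, sd) record.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    sel = values[np.asarray(mask, dtype=bool)]
    if sel.size < 2:
        raise TrackError("znorm_shift needs at least 2 unmasked values")
    mu = float(sel.mean())
    sd = float(sel.std())  # population (n) convention
    if sd == 0.0:
        raise TrackError("znorm_shift: zero variance (constant input)")
    out = values / sd
    return out, (mu, sd)


def znorm_shift_track(track: IndexTrack) -> IndexTrack:
    """Genome-wide Z-shift of an :class:`IndexTrack` (one sd per track)."""
    flat = track.unmasked_values()
    _, (mu, sd) = znorm_shift(flat)
    vals = {c: track.values[c] / sd for c in track.layout.names}
    return IndexTrack(track.layout, vals,
                      {c: m.copy() for c, m in track.mask.items()},
                      normalization=(mu, sd))


def diff_track(values: np.ndarray, mask: np.ndarray = None,
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Neighbouring-bin differential dv(x) = v(x+1) - v(x), stored at x.

    The last bin of the chromosome is masked (no right neighbour), as is
    any differential touching a masked bin.  A single-bin chromosome
    yields an all-masked output.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n = values.shape[0]
    out = np.zeros(n)
    out_mask = np.zeros(n, dtype=bool)
    if n >= 2:
        out[:-1] = values[1:] - values[:-1]
        out_mask[:-1] = mask[1:] & mask[:-1]
    out[~out_mask] = 0.0
    return out, out_mask


def diff_index_track(track: IndexTrack) -> IndexTrack:
    vals, mask = {}, {}
    for c in track.layout.names:
        vals[c], mask[c] = diff_track(track.values[c], track.mask[c])
    return IndexTrack(track.layout, vals, mask)


# ---------------------------------------------------------------------------
# I/O: genome layout, binned CSV, bedGraph, wig
# ---------------------------------------------------------------------------

def read_layout(path, bin_size: int = 1000) -> GenomeLayout:
    """Read a two-column (name, length) TSV — e.g. a faidx/chrom.sizes file."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["chrom", "length"], comment="#")
    return GenomeLayout({r.chrom: int(r.length) for r in df.itertuples()},
                        bin_size=bin_size)


def write_layout(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for c, n in layout.chromosomes:
            fh.write(f"{c}\t{n}\n")


def write_strand_csv(track: StrandBinTrack, path, header: str = "") -> None:
    """Four-column CSV (chrom, bin_start, watson, crick); masked bins omitted."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        fh.write("chrom,bin_start,watson,crick\n")
        for c in track.layout.names:
            starts = track.layout.bin_starts(c)
            m = track.mask[c]
            for s, w, k in zip(starts[m], track.watson[c][m],
                               track.crick[c][m]):
                fh.write(f"{c},{s},{float(w)!r},{float(k)!r}\n")


def read_strand_csv(path, layout: GenomeLayout) -> StrandBinTrack:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    watson = layout.zeros()
    crick = layout.zeros()
    mask = layout.full_mask(False)
    for chrom, grp in df.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in layout:
            raise TrackError(f"chromosome {chrom!r} not in layout")
        starts = grp["bin_start"].to_numpy()
        if np.any(starts % layout.bin_size != 0):
            raise TrackError("bin_start not aligned to layout bin width")
        idx = starts // layout.bin_size
        if np.any(idx >= layout.n_bins(chrom)):
            raise TrackError(f"bin beyond end of {chrom!r}")
        if np.unique(idx).size != idx.size:
            raise TrackError(f"duplicate bins on {chrom!r}")
        watson[chrom][idx] = grp["watson"].to_numpy(dtype=float)
        crick[chrom][idx] = grp["crick"].to_numpy(dtype=float)
        mask[chrom][idx] = True
    return StrandBinTrack(layout, watson, crick, mask)


def write_bedgraph(track: IndexTrack, path, header: str = "") -> None:
    """bedGraph (0-based half-open), one line per unmasked bin."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        bs = track.layout.bin_size
        for c in track.layout.names:
            length = track.layout.length(c)
            starts = track.layout.bin_starts(c)
            m = track.mask[c]
            for s, v in zip(starts[m], track.values[c][m]):
                e = min(s + bs, length)
                fh.write(f"{c}\t{s}\t{e}\t{float(v)!r}\n")


def read_bedgraph(path, layout: GenomeLayout) -> IndexTrack:
    values = layout.zeros()
    mask = layout.full_mask(False)
    bs = layout.bin_size
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if (not line or line.startswith("#")
                    or line.startswith(("track", "browser"))):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            s, e = int(s), int(e)
            if chrom not in layout:
                raise TrackError(f"chromosome {chrom!r} not in layout")
            if s % bs != 0 or (e - s != bs
                               and e != layout.length(chrom)):
                raise TrackError(
                    f"interval {chrom}:{s}-{e} inconsistent with "
                    f"{bs}-bp bins")
            i = s // bs
            if mask[chrom][i]:
                raise TrackError(f"overlapping intervals at {chrom}:{s}")
            values[chrom][i] = float(v)
            mask[chrom][i] = True
    return IndexTrack(layout, values, mask)


def write_wig(track: IndexTrack, path, header: str = "") -> None:
    """fixedStep wig (1-based starts per the wiggle standard).

    Masked bins break the track into multiple fixedStep blocks.
    """
    bs = track.layout.bin_size
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        for c in track.layout.names:
            m = track.mask[c]
            vals = track.values[c]
            i = 0
            n = m.shape[0]
            while i < n:
                if not m[i]:
                    i += 1
                    continue
                j = i
                while j < n and m[j]:
                    j += 1
                fh.write(f"fixedStep chrom={c} start={i * bs + 1} "
                         f"step={bs} span={bs}\n")
                for v in vals[i:j]:
                    fh.write(f"{float(v)!r}\n")
                i = j
    return None


def read_wig(path, layout: GenomeLayout) -> IndexTrack:
    values = layout.zeros()
    mask = layout.full_mask(False)
    bs = layout.bin_size
    chrom, pos = None, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                if chrom not in layout:
                    raise TrackError(f"chromosome {chrom!r} not in layout")
                if int(kv.get("step", bs)) != bs:
                    raise TrackError("wig step inconsistent with layout bins")
                start0 = int(kv["start"]) - 1
                if start0 % bs != 0:
                    raise TrackError("wig start not aligned to bins")
                pos = start0 // bs
                continue
            if chrom is None:
                raise TrackError("wig data before fixedStep declaration")
            if pos >= layout.n_bins(chrom):
                raise TrackError(f"wig data beyond end of {chrom!r}")
            if mask[chrom][pos]:
                raise TrackError(f"overlapping wig data on {chrom!r}")
            values[chrom][pos] = float(line)
            mask[chrom][pos] = True
            pos += 1
    return IndexTrack(layout, values, mask)
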