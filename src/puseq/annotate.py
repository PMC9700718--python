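"""Gene-anchored summaries of replication signals.

Meta-profiles around TSS/TTS (with expression or gene-length
stratification), scaled gene-body profiles, 0–30 kb window sums of the
initiation index versus expression or length, and the partition of
initiation-zone base pairs over annotation categories.

Orientation handling: profiles of minus-strand genes are mirrored so that
positive offsets always point downstream of transcription, and for
fork-direction-specific tracks the rightward/leftward pair is swapped so
that categories become co-directional (CD) and convergent (CV) with
transcription.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tracks import GenomeLayout, IndexTrack, TrackError, znorm_shift
from .zones import InitiationZone

__all__ = [
    "GeneRecord",
    "read_genes",
    "metaprofile",
    "directional_metaprofile",
    "stratify",
    "scaled_gene_profile",
    "window_sum_vs_feature",
    "zone_overlap_partition",
]


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    tss: int
    tts: int
    strand: str           # '+' | '-'
    fpkm: float
    name: str = ""
    protein_coding: bool = True

    def __post_init__(self):
        if self.strand not in "+-":
            raise TrackError("strand must be '+' or '-'")
        if self.tss == self.tts:
            raise TrackError("zero-length gene")
        if self.fpkm < 0:
            raise TrackError("negative FPKM")

    @property
    def length(self) -> int:
        return abs(self.tts - self.tss)

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        return max(self.tss, self.tts)


def read_genes(path) -> List[GeneRecord]:
    """BED-like TSV: chrom, start, end, name, fpkm, strand[, biotype].

    start/end are 0-based half-open gene-body coordinates; the TSS is
    ``start`` for plus-strand and ``end`` for minus-strand genes.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    genes = []
    for row in df.itertuples(index=False):
        chrom, start, end, name, fpkm, strand = row[:6]
        coding = True if len(row) < 7 else str(row[6]) == "protein_coding"
        tss, tts = (int(start), int(end)) if strand == "+" \
            else (int(end), int(start))
        genes.append(GeneRecord(str(chrom), tss, tts, str(strand),
                                float(fpkm), str(name), coding))
    return genes


def _gene_profile(track: IndexTrack, gene: GeneRecord, anchor: int,
                  k: int, orient: bool) -> Tuple[np.ndarray, np.ndarray]:
    """Signal at bins anchor-k .. anchor+k, mirrored for minus strand."""
    layout = track.layout
    n = layout.n_bins(gene.chrom)
    abin = anchor // layout.bin_size
    idx = abin + np.arange(-k, k + 1)
    ok = (idx >= 0) & (idx < n)
    vals = np.zeros(2 * k + 1)
    valid = np.zeros(2 * k + 1, dtype=bool)
    sel = idx[ok]
    vals[ok] = track.values[gene.chrom][sel]
    valid[ok] = track.mask[gene.chrom][sel]
    if orient and gene.strand == "-":
        vals = vals[::-1]
        valid = valid[::-1]
    return vals, valid


def metaprofile(track: IndexTrack, genes: Sequence[GeneRecord],
                anchor_type: str = "TSS", flank: int = 100_000,
                orient: bool = True) -> pd.DataFrame:
    """Mean signal per offset around gene anchors.

    Returns a DataFrame with columns ``offset`` (bp, bin-stepped; positive
    offsets point downstream of transcription when ``orient``), ``mean``
    and ``n`` (anchors contributing a valid bin at that offset).
    """
    if not genes:
        raise TrackError("no anchor genes supplied")
    if anchor_type not in ("TSS", "TTS"):
        raise TrackError("anchor_type must be 'TSS' or 'TTS'")
    bs = track.layout.bin_size
    k = flank // bs
    total = np.zeros(2 * k + 1)
    count = np.zeros(2 * k + 1)
    for g in genes:
        if g.chrom not in track.layout:
            continue
        anchor = g.tss if anchor_type == "TSS" else g.tts
        vals, valid = _gene_profile(track, g, anchor, k, orient)
        total[valid] += vals[valid]
        count[valid] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return pd.DataFrame({"offset": np.arange(-k, k + 1) * bs,
                         "mean": mean, "n": count.astype(int)})


def directional_metaprofile(track_right: IndexTrack, track_left: IndexTrack,
                            genes: Sequence[GeneRecord],
                            anchor_type: str = "TSS",
                            flank: int = 100_000) -> Dict[str, pd.DataFrame]:
    """CD/CV meta-profiles of a rightward/leftward track pair.

    For plus-strand genes the co-directional (CD) fork is rightward and
    the convergent (CV) fork leftward; minus-strand genes swap the pair in
    addition to the coordinate mirroring.
    """
    if not genes:
        raise TrackError("no anchor genes supplied")
    plus = [g for g in genes if g.strand == "+"]
    minus = [g for g in genes if g.strand == "-"]
    out = {}
    for label, ptrack, mtrack in (("CD", track_right, track_left),
                                  ("CV", track_left, track_right)):
        frames = []
        if plus:
            frames.append(metaprofile(ptrack, plus, anchor_type, flank,
                                      orient=True))
        if minus:
            frames.append(metaprofile(mtrack, minus, anchor_type, flank,
                                      orient=True))
        if len(frames) == 1:
            out[label] = frames[0]
        else:
            a, b = frames
            n = a["n"] + b["n"]
            tot = (a["mean"].fillna(0) * a["n"] + b["mean"].fillna(0) * b["n"])
            mean = np.where(n > 0, tot / n.replace(0, 1), np.nan)
            out[label] = pd.DataFrame({"offset": a["offset"],
                                       "mean": mean, "n": n})
    return out


def metaprofile_matrix(track: IndexTrack, genes: Sequence[GeneRecord],
                       anchor_type: str = "TSS", flank: int = 100_000,
                       sort_by: str = "length") -> pd.DataFrame:
    """Per-gene signal matrix (gene x offset) for heat-map rendering.

    Rows are genes sorted by ``sort_by`` ("length" or "fpkm"), columns are
    bin-stepped offsets around the anchor; invalid bins are NaN.  Oriented
    like :func:`metaprofile` (positive offsets downstream of transcription).
    """
    if not genes:
        raise TrackError("no anchor genes supplied")
    bs = track.layout.bin_size
    k = flank // bs
    key = {"length": lambda g: g.length, "fpkm": lambda g: g.fpkm}[sort_by]
    ordered = sorted((g for g in genes if g.chrom in track.layout), key=key)
    rows = []
    for g in ordered:
        anchor = g.tss if anchor_type == "TSS" else g.tts
        vals, valid = _gene_profile(track, g, anchor, k, orient=True)
        rows.append(np.where(valid, vals, np.nan))
    return pd.DataFrame(rows, index=[g.name for g in ordered],
                        columns=np.arange(-k, k + 1) * bs)


def stratify(genes: Sequence[GeneRecord], by: str = "fpkm",
             n_groups: int = 4, active_top_fraction: Optional[float] = None,
             ) -> List[List[GeneRecord]]:
    """Split genes into rank-based groups by expression or length.

    Groups are returned low to high.  Boundaries are computed on the
    supplied set; ties resolve by stable input order.  For length
    stratification the most-active filter (``active_top_fraction`` by
    FPKM) is applied first, matching the convention of restricting length
    analyses to transcriptionally active genes.
    """
    genes = list(genes)
    if active_top_fraction is not None:
        order = np.argsort([-g.fpkm for g in genes], kind="stable")
        keep = max(1, int(round(active_top_fraction * len(genes))))
        genes = [genes[i] for i in sorted(order[:keep])]
    key = {"fpkm": lambda g: g.fpkm, "length": lambda g: g.length}[by]
    order = np.argsort([key(g) for g in genes], kind="stable")
    bounds = np.linspace(0, len(genes), n_groups + 1).round().astype(int)
    return [[genes[i] for i in order[bounds[j]:bounds[j + 1]]]
            for j in range(n_groups)]


def scaled_gene_profile(track: IndexTrack, genes: Sequence[GeneRecord],
                        nbins: int = 100, flip: str = "proportion",
                        ) -> Tuple[pd.DataFrame, int]:
    """Mean signal over gene bodies rescaled to ``nbins`` relative slots.

    Minus-strand genes are mirrored so slot 0 is always the 5' (TSS) end;
    their values are additionally converted to the opposite orientation:
    ``flip='proportion'`` maps a rightward-fork percentage v to 100 - v,
    ``flip='signed'`` negates a signed RFD, ``flip='none'`` leaves values
    untouched.  Genes spanning less than one bin are skipped; the skip
    count is returned alongside the profile.
    """
    if flip not in ("proportion", "signed", "none"):
        raise TrackError("flip must be 'proportion', 'signed' or 'none'")
    bs = track.layout.bin_size
    total = np.zeros(nbins)
    count = np.zeros(nbins)
    skipped = 0
    for g in genes:
        if g.chrom not in track.layout:
            continue
        lo = g.start // bs
        hi = g.end // bs
        if hi <= lo:
            skipped += 1
            continue
        vals = track.values[g.chrom][lo:hi].astype(float).copy()
        valid = track.mask[g.chrom][lo:hi].copy()
        if g.strand == "-":
            vals = vals[::-1]
            valid = valid[::-1]
            if flip == "proportion":
                vals = 100.0 - vals
            elif flip == "signed":
                vals = -vals
        slot = (np.arange(vals.size) * nbins) // vals.size
        np.add.at(total, slot[valid], vals[valid])
        np.add.at(count, slot[valid], 1)
    mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    df = pd.DataFrame({"rel_pos": (np.arange(nbins) + 0.5) / nbins,
                       "mean": mean, "n": count.astype(int)})
    return df, skipped


def window_sum_vs_feature(ini: IndexTrack, genes: Sequence[GeneRecord],
                          window: int = 30_000, anchor_type: str = "TSS",
                          ) -> pd.DataFrame:
    """Per-gene initiation-index sum in the 0–``window`` bp region upstream
    of the TSS (or downstream of the TTS), in transcription orientation.

    The sums are Z-shifted (scaled by their standard deviation so zero
    stays zero); log FPKM is Z-score normalised, with FPKM = 0 genes
    floored just below the finite minimum and flagged in ``fpkm_zero``.
    """
    if not genes:
        raise TrackError("no genes supplied")
    bs = ini.layout.bin_size
    k = window // bs
    rows = []
    for g in genes:
        if g.chrom not in ini.layout:
            continue
        abin = (g.tss if anchor_type == "TSS" else g.tts) // bs
        upstream = (g.strand == "+") == (anchor_type == "TSS")
        if upstream:
            lo, hi = abin - k, abin
        else:
            lo, hi = abin + 1, abin + k + 1
        n = ini.layout.n_bins(g.chrom)
        lo, hi = max(lo, 0), min(hi, n)
        vals = ini.values[g.chrom][lo:hi]
        valid = ini.mask[g.chrom][lo:hi]
        rows.append((g.name, float(vals[valid].sum()), g.fpkm, g.length))
    df = pd.DataFrame(rows, columns=["name", "ini_sum", "fpkm", "length"])
    shifted, _ = znorm_shift(df["ini_sum"].to_numpy())
    df["ini_sum_z"] = shifted
    df["fpkm_zero"] = df["fpkm"] == 0
    logf = np.log(df["fpkm"].to_numpy(),
                  where=df["fpkm"].to_numpy() > 0,
                  out=np.full(len(df), np.nan))
    finite_min = np.nanmin(logf) if np.isfinite(np.nanmin(logf)) else 0.0
    logf = np.where(np.isnan(logf), finite_min - 1.0, logf)
    sd = logf.std()
    df["log_fpkm_z"] = (logf - logf.mean()) / sd if sd > 0 \
        else np.zeros(len(df))
    return df


_CATEGORIES = ("other", "non_transcribed", "flank", "transcribed")


def zone_overlap_partition(zones: Sequence[InitiationZone],
                           genes: Sequence[GeneRecord],
                           layout: GenomeLayout, flank: int = 30_000,
                           ) -> Dict[str, float]:
    """Fraction of total zone base pairs over annotation categories.

    Categories, in decreasing precedence where features overlap:
    ``transcribed`` (bodies of FPKM > 0 protein-coding genes), ``flank``
    (0–``flank`` bp upstream of TSS / downstream of TTS of protein-coding
    genes), ``non_transcribed`` (bodies of FPKM = 0 protein-coding genes)
    and ``other``.  Fractions sum to 1.
    """
    if not zones:
        return {c: 0.0 for c in _CATEGORIES}
    paint: Dict[str, np.ndarray] = {}
    chroms_needed = {z.chrom for z in zones}
    for chrom in chroms_needed:
        paint[chrom] = np.zeros(layout.length(chrom), dtype=np.int8)

    def mark(chrom, start, end, code):
        if chrom in paint:
            lo = max(0, start)
            hi = min(layout.length(chrom), end)
            if hi > lo:
                arr = paint[chrom][lo:hi]
                np.maximum(arr, code, out=arr)

    coding = [g for g in genes if g.protein_coding]
    # paint lowest precedence first; np.maximum enforces the priority order
    for g in coding:
        if g.fpkm == 0:
            mark(g.chrom, g.start, g.end, 1)
    for g in coding:
        if g.strand == "+":
            mark(g.chrom, g.tss - flank, g.tss, 2)
            mark(g.chrom, g.tts, g.tts + flank, 2)
        else:
            mark(g.chrom, g.tss, g.tss + flank, 2)
            mark(g.chrom, g.tts - flank, g.tts, 2)
    for g in coding:
        if g.fpkm > 0:
            mark(g.chrom, g.start, g.end, 3)
    counts = np.zeros(4, dtype=np.int64)
    for z in zones:
        counts += np.bincount(paint[z.chrom][z.start:z.end], minlength=4)
    total = counts.sum()
    return {cat: counts[i] / total for i, cat in enumerate(_CATEGORIES)}
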