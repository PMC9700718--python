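"""Initiation-zone calling and coupling-index outlier detection.

An initiation zone is a maximal run of consecutive valid bins with a
positive initiation index; its summit is the bin of maximal index, its
area the summed index over the run.  Replicate concordance, summary
statistics and the Smirnov–Grubbs outlier machinery used to find loci of
uncoupled leading/lagging-strand synthesis live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .tracks import IndexTrack, TrackError

__all__ = [
    "InitiationZone",
    "OutlierLocus",
    "call_zones",
    "zone_stats",
    "replicate_concordance",
    "grubbs_critical",
    "grubbs_outliers",
    "coupling_outlier_loci",
    "pearson_one_tailed",
    "write_zones_bed",
    "write_outlier_tsv",
]


@dataclass(frozen=True)
class InitiationZone:
    chrom: str
    start: int   # bp, 0-based half-open
    end: int
    summit: int  # bp, start coordinate of the maximal bin
    area: float  # summed index over the zone

    @property
    def width(self) -> int:
        return self.end - self.start


def call_zones(ini: IndexTrack, min_area: float = 0.0,
               min_width: int = 3000) -> List[InitiationZone]:
    """Maximal runs of positive initiation index, filtered by size.

    Runs break at masked bins and at bins with index <= 0.  A run is kept
    if its summed index reaches ``min_area`` and its width (bp) reaches
    ``min_width``.  The summit is the leftmost bin attaining the maximum.
    """
    zones: List[InitiationZone] = []
    bs = ini.layout.bin_size
    for chrom in ini.layout.names:
        v = ini.values[chrom]
        ok = ini.mask[chrom] & (v > 0)
        n = ok.size
        i = 0
        while i < n:
            if not ok[i]:
                i += 1
                continue
            j = i
            while j < n and ok[j]:
                j += 1
            seg = v[i:j]
            area = float(seg.sum())
            start = i * bs
            end = min(j * bs, ini.layout.length(chrom))
            if area >= min_area and end - start >= min_width:
                summit = (i + int(np.argmax(seg))) * bs
                zones.append(InitiationZone(chrom, start, end, summit, area))
            i = j
    return zones


def zone_stats(zones: Sequence[InitiationZone]) -> Dict[str, float]:
    """Count, width and within-chromosome inter-summit spacing summaries."""
    if not zones:
        return {}
    widths = np.array([z.width for z in zones], dtype=float)
    spacings: List[float] = []
    by_chrom: Dict[str, List[int]] = {}
    for z in zones:
        by_chrom.setdefault(z.chrom, []).append(z.summit)
    for summits in by_chrom.values():
        s = np.sort(np.array(summits, dtype=float))
        spacings.extend(np.diff(s).tolist())
    out = {
        "count": float(len(zones)),
        "mean_width": float(widths.mean()),
        "max_width": float(widths.max()),
    }
    if spacings:
        out["mean_summit_spacing"] = float(np.mean(spacings))
    return out


def _top_fraction(zones: Sequence[InitiationZone],
                  fraction: float) -> List[InitiationZone]:
    if not 0 < fraction <= 1:
        raise TrackError("top_fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(zones)
    ranked = sorted(zones, key=lambda z: z.area, reverse=True)
    keep = max(1, int(round(fraction * len(ranked))))
    return ranked[:keep]


def _overlaps_any(zone: InitiationZone,
                  others: Sequence[InitiationZone]) -> bool:
    return any(o.chrom == zone.chrom and o.start < zone.end
               and zone.start < o.end for o in others)


def replicate_concordance(*zone_sets: Sequence[InitiationZone],
                          top_fraction: float = 1.0) -> float:
    """Fraction of first-replicate zones overlapping a zone in every other
    replicate, optionally restricted to each replicate's top zones by area.
    """
    if len(zone_sets) < 2:
        raise TrackError("need at least two replicate zone sets")
    if any(len(zs) == 0 for zs in zone_sets):
        raise TrackError("empty zone set")
    sets = [_top_fraction(zs, top_fraction) for zs in zone_sets]
    considered = sets[0]
    hits = sum(1 for z in considered
               if all(_overlaps_any(z, other) for other in sets[1:]))
    return hits / len(considered)


# ---------------------------------------------------------------------------
# Smirnov–Grubbs outliers
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) critical point of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise TrackError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(values: Sequence[float], alpha: float = 0.05,
                    iterate: bool = True) -> List[int]:
    """Indices of two-sided Smirnov–Grubbs outliers.

    G = max |x_i - mean| / s with the sample (n-1) standard deviation.  If
    ``iterate``, the flagged point is removed and the test repeated until
    no rejection (classical repeated Grubbs).  Indices refer to the input
    order.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise TrackError("Grubbs test needs n >= 3")
    active = np.arange(x.size)
    flagged: List[int] = []
    while active.size >= 3:
        sel = x[active]
        s = sel.std(ddof=1)
        if s == 0.0:
            if flagged:
                break
            raise TrackError("Grubbs test on constant values")
        dev = np.abs(sel - sel.mean())
        i = int(np.argmax(dev))
        g = dev[i] / s
        if g > grubbs_critical(active.size, alpha):
            flagged.append(int(active[i]))
            active = np.delete(active, i)
            if not iterate:
                break
        else:
            break
    return flagged


@dataclass(frozen=True)
class OutlierLocus:
    chrom: str
    start: int
    end: int
    direction: str       # 'rightward' | 'leftward'
    mean_ci: float       # mean windowed CI across replicates
    grubbs_stat: float   # largest G among supporting replicates
    alpha: float
    n_replicates: int    # replicates in which the window was significant

    @property
    def sign(self) -> int:
        return 1 if self.mean_ci > 0 else -1


def _window_means(track: IndexTrack, chrom: str, window: int,
                  min_bins: int = 1) -> Tuple[np.ndarray, np.ndarray]:
    """Mean CI per non-overlapping window; NaN where too few valid bins."""
    bs = track.layout.bin_size
    if window % bs != 0:
        raise TrackError("window must be a multiple of the bin size")
    per = window // bs
    v, m = track.values[chrom], track.mask[chrom]
    n_win = -(-v.size // per)
    means = np.full(n_win, np.nan)
    for w in range(n_win):
        sl = slice(w * per, (w + 1) * per)
        mm = m[sl]
        if mm.sum() >= min_bins:
            means[w] = v[sl][mm].mean()
    return means, np.arange(n_win) * window


def coupling_outlier_loci(replicates: Sequence[Dict[str, IndexTrack]],
                          window: int = 100_000, alpha: float = 0.05,
                          min_replicates: int = 2,
                          iterate: bool = True) -> List[OutlierLocus]:
    """Loci where windowed CI is a chromosome-wide Grubbs outlier in >= 2
    biological replicates.

    ``replicates`` is a sequence of ``{"rightward": ci_r, "leftward":
    ci_l}`` coupling-index track pairs.  Per chromosome and per direction,
    window-mean CI values form the test population within each replicate;
    windows flagged in at least ``min_replicates`` replicates are merged
    (when adjacent) into loci annotated with direction and the sign of the
    divergence.  Chromosomes with fewer than 3 usable windows are skipped.
    """
    if len(replicates) < min_replicates:
        raise TrackError(f"need at least {min_replicates} replicates")
    layout = replicates[0]["rightward"].layout
    loci: List[OutlierLocus] = []
    for chrom in layout.names:
        for direction in ("rightward", "leftward"):
            per_rep = []
            for rep in replicates:
                means, starts = _window_means(rep[direction], chrom, window)
                per_rep.append(means)
            starts = np.arange(per_rep[0].size) * window
            votes = np.zeros(per_rep[0].size, dtype=int)
            gmax = np.zeros(per_rep[0].size)
            for means in per_rep:
                valid = np.nonzero(~np.isnan(means))[0]
                if valid.size < 3:
                    continue
                sel = means[valid]
                idx = grubbs_outliers(sel, alpha=alpha, iterate=iterate)
                s = sel.std(ddof=1)
                for i in idx:
                    w = valid[i]
                    votes[w] += 1
                    gmax[w] = max(gmax[w], abs(sel[i] - sel.mean()) / s)
            hit = votes >= min_replicates
            i = 0
            while i < hit.size:
                if not hit[i]:
                    i += 1
                    continue
                j = i
                while j < hit.size and hit[j]:
                    j += 1
                mean_ci = float(np.nanmean(
                    [np.nanmean([m[w] for m in per_rep])
                     for w in range(i, j)]))
                loci.append(OutlierLocus(
                    chrom,
                    int(starts[i]),
                    int(min(starts[j - 1] + window, layout.length(chrom))),
                    direction, mean_ci, float(gmax[i:j].max()), alpha,
                    int(votes[i:j].max())))
                i = j
    return loci


def pearson_one_tailed(x: Sequence[float],
                       y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r with a one-tailed t-test p-value in the observed direction.

    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom; the p-value is
    the single tail on the side of the observed sign of r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise TrackError("need >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise TrackError("non-finite values in input")
    if x.std() == 0.0 or y.std() == 0.0:
        raise TrackError("constant input has no defined correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(stats.t.sf(abs(t), n - 2))
    return r, p


def write_outlier_tsv(loci: Sequence[OutlierLocus], path) -> None:
    """Outlier loci as TSV: location, fork direction, sign of divergence."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tdirection\tsign\tmean_ci\t"
                 "grubbs_stat\talpha\tn_replicates\n")
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.direction}\t"
                     f"{'>0' if l.sign > 0 else '<0'}\t{l.mean_ci:.6g}\t"
                     f"{l.grubbs_stat:.6g}\t{l.alpha:g}\t{l.n_replicates}\n")


def write_zones_bed(zones: Sequence[InitiationZone], path) -> None:
    """BED6 plus summit and area columns (tab-separated)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tsummit\tarea\n")
        for i, z in enumerate(zones):
            fh.write(f"{z.chrom}\t{z.start}\t{z.end}\tzone{i}\t0\t.\t"
                     f"{z.summit}\t{float(z.area)!r}\n")
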