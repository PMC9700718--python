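"""Stochastic replicon simulator.

Generates ground-truth replication fork directionality and per-strand
Pu-seq-like count tracks from a simple replicon model: origins fire
independently with per-origin efficiencies, all fired origins fire
simultaneously and forks progress at equal constant speed, so every locus
is replicated by whichever fired origin is nearest (rightward fork if that
origin lies to the left).  Cells in which no origin fired are redrawn —
every locus is replicated in every cell cycle.

Polymerase division of labour: Polε synthesises the leading strand and
Polα the lagging strand, so for a rightward-moving fork Polε tracks the
Watson strand and Polα the Crick strand.  A tunable ``residual`` fraction
of each polymerase's incorporation is attributed to the non-canonical
strand, and a uniform ``background`` adds library noise.  Leading-strand
uncoupling can be injected over an interval to emulate loci where leading
strand synthesis is impeded.

Counts are independent Poisson draws per bin per strand, mimicking the
per-1-kb-bin rNMP 5'-end counts of a Pu-seq library.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .tracks import GenomeLayout, StrandBinTrack, TrackError, write_strand_csv

__all__ = [
    "ReplicationModel",
    "LibraryModel",
    "UncouplingSpec",
    "ExpectedTracks",
    "fork_direction_probability",
    "expected_tracks",
    "expected_control",
    "inject_uncoupling",
    "sample_counts",
    "simulate_counts",
    "make_fixture",
    "default_model",
]

EXACT_MAX_ORIGINS = 20


@dataclass(frozen=True)
class ReplicationModel:
    """Origin positions (bp) and firing efficiencies per chromosome."""

    layout: GenomeLayout
    origins: Mapping[str, Sequence[Tuple[int, float]]]

    def __post_init__(self):
        for chrom in self.layout.names:
            ori = list(self.origins.get(chrom, ()))
            if not ori:
                raise TrackError(
                    f"chromosome {chrom!r} has no origins; every chromosome "
                    "needs at least one")
            pos = [p for p, _ in ori]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise TrackError("origin positions must be strictly increasing")
            if any(not (0.0 < e <= 1.0) for _, e in ori):
                raise TrackError("origin efficiencies must be in (0, 1]")
            if pos[0] < 0 or pos[-1] >= self.layout.length(chrom):
                raise TrackError("origin position outside chromosome")

    def positions(self, chrom: str) -> np.ndarray:
        return np.array([p for p, _ in self.origins[chrom]], dtype=float)

    def efficiencies(self, chrom: str) -> np.ndarray:
        return np.array([e for _, e in self.origins[chrom]], dtype=float)


@dataclass(frozen=True)
class LibraryModel:
    """Sequencing-library parameters for one simulated Pu-seq experiment.

    depth:
        Expected reads per bin (both strands combined) for a mutant library.
    residual:
        Fraction of a polymerase's incorporation attributed to the
        non-canonical strand (Polε on lagging / Polα on leading).  Default
        0.1: Polα also primes leading strands, but far less often than it
        primes Okazaki fragments.
    background:
        Uniform additive rate, as a fraction of ``depth`` per strand.
    control_depth:
        Expected reads per bin for the polymerase-proficient control.
    """

    depth: float = 200.0
    residual: float = 0.1
    background: float = 0.0
    control_depth: float = 200.0

    def __post_init__(self):
        if self.depth <= 0 or self.control_depth <= 0:
            raise TrackError("depths must be positive")
        if not (0.0 <= self.residual <= 1.0 and 0.0 <= self.background <= 1.0
                and self.residual + self.background < 1.0):
            raise TrackError("need residual, background >= 0 and "
                             "residual + background < 1")


@dataclass(frozen=True)
class UncouplingSpec:
    """Leading-strand (Polε) suppression over an interval.

    ``suppression`` u scales the Polε expectation attributable to forks of
    the given orientation by (1 - u) inside [start, end); with no residual
    or background the expected coupling index there is -u / (2 - u).
    """

    chrom: str
    start: int
    end: int
    direction: str  # 'rightward' | 'leftward'
    suppression: float

    def __post_init__(self):
        if self.direction not in ("rightward", "leftward"):
            raise TrackError("direction must be 'rightward' or 'leftward'")
        if not 0.0 <= self.suppression <= 1.0:
            raise TrackError("suppression must be in [0, 1]")
        if self.start >= self.end:
            raise TrackError("empty uncoupling interval")


# ---------------------------------------------------------------------------
# fork direction probability
# ---------------------------------------------------------------------------

def _subset_indicator(fired_pos: np.ndarray, x: np.ndarray) -> np.ndarray:
    """P(rightward) per bin centre given one set of fired origins.

    1 where the nearest fired origin is strictly to the left, 0 where
    strictly to the right, 0.5 on exact distance ties (including an origin
    exactly at the bin centre).
    """
    q = np.sort(fired_pos)
    ir = np.searchsorted(q, x, side="right")
    il = np.searchsorted(q, x, side="left")
    has_left = il > 0
    has_right = ir < q.size
    dl = np.where(has_left, x - q[np.maximum(il - 1, 0)], np.inf)
    dr = np.where(has_right, q[np.minimum(ir, q.size - 1)] - x, np.inf)
    at_origin = ir > il  # some fired origin exactly at x
    out = np.where(dl < dr, 1.0, 0.0)
    out[dl == dr] = 0.5
    out[at_origin] = 0.5
    return out


def _p_right_careful(pos: np.ndarray, eff: np.ndarray, x: float) -> float:
    """Exact P(rightward | >=1 fired) at one bin, with full tie handling."""
    d = np.abs(pos - x)
    order = np.argsort(d, kind="stable")
    d, p, e = d[order], pos[order], eff[order]
    total = 0.0
    none_closer = 1.0
    i, k = 0, len(d)
    while i < k:
        j = i
        while j < k and d[j] == d[i]:
            j += 1
        grp = slice(i, j)
        if d[i] == 0.0:
            p_any = 1.0 - np.prod(1.0 - e[grp])
            total += none_closer * p_any * 0.5
        else:
            left = p[grp] < x
            p_left = 1.0 - np.prod(1.0 - e[grp][left])
            p_rght = 1.0 - np.prod(1.0 - e[grp][~left])
            total += none_closer * (p_left * (1.0 - p_rght)
                                    + 0.5 * p_left * p_rght)
        none_closer *= np.prod(1.0 - e[grp])
        i = j
    z = 1.0 - np.prod(1.0 - eff)
    return total / z


def _p_right_analytic(pos: np.ndarray, eff: np.ndarray,
                      x: np.ndarray) -> np.ndarray:
    """Closed-form P(rightward) per bin: sum over 'nearest fired origin'.

    Origins are ranked by distance per bin; the probability that origin o
    is the nearest fired one is e_o * prod(1 - e) over strictly closer
    origins, and o sends the fork rightward iff it lies left of the bin.
    Bins with exact distance ties are recomputed with explicit tie terms.
    """
    dist = np.abs(x[:, None] - pos[None, :])
    is_left = pos[None, :] < x[:, None]
    order = np.argsort(dist, axis=1, kind="stable")
    d_ord = np.take_along_axis(dist, order, axis=1)
    e_ord = eff[order]
    l_ord = np.take_along_axis(is_left, order, axis=1)
    cp = np.cumprod(1.0 - e_ord, axis=1)
    cp_before = np.hstack([np.ones((x.size, 1)), cp[:, :-1]])
    p_first = e_ord * cp_before
    z = 1.0 - cp[:, -1]
    out = (p_first * l_ord).sum(axis=1) / z
    tied = (d_ord[:, 0] == 0.0)
    if d_ord.shape[1] > 1:
        tied |= (np.diff(d_ord, axis=1) == 0.0).any(axis=1)
    for i in np.nonzero(tied)[0]:
        out[i] = _p_right_careful(pos, eff, float(x[i]))
    return out


def fork_direction_probability(model: ReplicationModel, method: str = "exact",
                               n_cells: int = 10000,
                               seed: Optional[int] = None,
                               ) -> Dict[str, np.ndarray]:
    """Per-bin probability that a locus is replicated by a rightward fork.

    ``method``:

    * ``"exact"`` — enumerate all 2^k fired-origin subsets (k <= 20).
    * ``"analytic"`` — closed-form sum over nearest-fired-origin events;
      identical to ``exact`` but O(k^2) so usable for any origin count.
    * ``"montecarlo"`` — average over ``n_cells`` simulated cells.
    """
    out: Dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for chrom in model.layout.names:
        pos = model.positions(chrom)
        eff = model.efficiencies(chrom)
        x = model.layout.bin_centers(chrom)
        k = pos.size
        if method == "exact":
            if k > EXACT_MAX_ORIGINS:
                raise TrackError(
                    f"exact enumeration limited to {EXACT_MAX_ORIGINS} "
                    "origins per chromosome; use method='montecarlo' or "
                    "'analytic'")
            acc = np.zeros(x.size)
            z = 0.0
            for bits in range(1, 1 << k):
                sel = np.array([(bits >> i) & 1 for i in range(k)], dtype=bool)
                w = float(np.prod(np.where(sel, eff, 1.0 - eff)))
                acc += w * _subset_indicator(pos[sel], x)
                z += w
            out[chrom] = acc / z
        elif method == "analytic":
            out[chrom] = _p_right_analytic(pos, eff, x)
        elif method == "montecarlo":
            fired = rng.random((n_cells, k)) < eff
            empty = ~fired.any(axis=1)
            while empty.any():  # redraw cells with no fired origin
                fired[empty] = rng.random((int(empty.sum()), k)) < eff
                empty = ~fired.any(axis=1)
            acc = np.zeros(x.size)
            subsets, counts = np.unique(fired, axis=0, return_counts=True)
            for sel, cnt in zip(subsets, counts):
                acc += cnt * _subset_indicator(pos[sel], x)
            out[chrom] = acc / n_cells
        else:
            raise TrackError(f"unknown method {method!r}")
        np.clip(out[chrom], 0.0, 1.0, out=out[chrom])  # shed float round-off
    return out


# ---------------------------------------------------------------------------
# expected count tracks
# ---------------------------------------------------------------------------

@dataclass
class ExpectedTracks:
    """Per-strand Poisson expectations, decomposed by fork orientation.

    The decomposition (rightward- vs leftward-fork-attributable signal plus
    uniform background) is kept explicit so that uncoupling injection can
    scale exactly the component it targets.
    """

    layout: GenomeLayout
    polymerase: str  # 'eps' | 'alpha'
    watson_right: Dict[str, np.ndarray]
    watson_left: Dict[str, np.ndarray]
    crick_right: Dict[str, np.ndarray]
    crick_left: Dict[str, np.ndarray]
    background: float  # additive per-bin per-strand expectation

    def watson(self) -> Dict[str, np.ndarray]:
        return {c: self.watson_right[c] + self.watson_left[c] + self.background
                for c in self.layout.names}

    def crick(self) -> Dict[str, np.ndarray]:
        return {c: self.crick_right[c] + self.crick_left[c] + self.background
                for c in self.layout.names}


def expected_tracks(p_right: Mapping[str, np.ndarray], layout: GenomeLayout,
                    library: LibraryModel, polymerase: str) -> ExpectedTracks:
    """Expected per-strand counts for a mutant library given true p_R.

    Polε signal follows the leading strand (Watson for rightward forks);
    Polα mirrors it on the lagging strand.  ``residual`` swaps a fraction
    onto the non-canonical strand; ``background`` adds a uniform term.
    """
    if polymerase not in ("eps", "alpha"):
        raise TrackError("polymerase must be 'eps' or 'alpha'")
    d, r = library.depth, library.residual
    wr, wl, cr, cl = {}, {}, {}, {}
    for chrom in layout.names:
        p = np.asarray(p_right[chrom], dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise TrackError("p_right outside [0, 1]")
        if polymerase == "eps":
            wr[chrom] = d * (1 - r) * p          # leading, rightward forks
            wl[chrom] = d * r * (1 - p)          # residual on lagging
            cr[chrom] = d * r * p
            cl[chrom] = d * (1 - r) * (1 - p)
        else:
            wr[chrom] = d * r * p                # residual on leading
            wl[chrom] = d * (1 - r) * (1 - p)    # lagging, leftward forks
            cr[chrom] = d * (1 - r) * p
            cl[chrom] = d * r * (1 - p)
    return ExpectedTracks(layout, polymerase, wr, wl, cr, cl,
                          background=d * library.background)


def expected_control(layout: GenomeLayout,
                     library: LibraryModel) -> ExpectedTracks:
    """Uniform polymerase-proficient control expectations."""
    half = library.control_depth / 2.0
    z = layout.zeros
    return ExpectedTracks(layout, "eps",
                          {c: np.full(layout.n_bins(c), half)
                           for c in layout.names},
                          z(), z(),
                          {c: np.full(layout.n_bins(c), half)
                           for c in layout.names},
                          background=0.0)


def inject_uncoupling(expectations: ExpectedTracks,
                      spec: UncouplingSpec) -> ExpectedTracks:
    """Scale the leading-strand Polε signal of one orientation by (1 - u).

    Polα expectations pass through unchanged (uncoupling models an
    impediment to leading-strand synthesis only).
    """
    if expectations.polymerase != "eps":
        return expectations
    layout = expectations.layout
    if spec.chrom not in layout:
        raise TrackError(f"chromosome {spec.chrom!r} not in layout")
    if spec.end > layout.length(spec.chrom):
        raise TrackError("uncoupling interval beyond chromosome end")
    out = ExpectedTracks(
        layout, expectations.polymerase,
        {c: v.copy() for c, v in expectations.watson_right.items()},
        {c: v.copy() for c, v in expectations.watson_left.items()},
        {c: v.copy() for c, v in expectations.crick_right.items()},
        {c: v.copy() for c, v in expectations.crick_left.items()},
        expectations.background,
    )
    bs = layout.bin_size
    lo = spec.start // bs
    hi = -(-spec.end // bs)
    factor = 1.0 - spec.suppression
    # only the leading-strand synthesis of that orientation is impeded:
    # Watson for rightward forks, Crick for leftward; the residual Polε
    # incorporation on the opposite strand is a separate synthesis event
    if spec.direction == "rightward":
        out.watson_right[spec.chrom][lo:hi] *= factor
    else:
        out.crick_left[spec.chrom][lo:hi] *= factor
    return out


def sample_counts(expectations: ExpectedTracks,
                  seed: Optional[int] = None) -> StrandBinTrack:
    """Independent Poisson draws per bin per strand."""
    rng = np.random.default_rng(seed)
    layout = expectations.layout
    w_exp, c_exp = expectations.watson(), expectations.crick()
    watson = {c: rng.poisson(w_exp[c]).astype(float) for c in layout.names}
    crick = {c: rng.poisson(c_exp[c]).astype(float) for c in layout.names}
    return StrandBinTrack(layout, watson, crick)


# ---------------------------------------------------------------------------
# turnkey simulation and fixtures
# ---------------------------------------------------------------------------

def default_model(layout: GenomeLayout, n_origins: int = 20,
                  seed: Optional[int] = None,
                  min_efficiency: float = 0.05,
                  max_efficiency: float = 0.95,
                  symmetric: bool = True) -> ReplicationModel:
    """Jittered-grid origins with efficiencies spread over a wide range.

    One origin per equal slot of each chromosome, jittered by up to 20% of
    the slot width, keeps origins well separated (replicon-scale spacing)
    while remaining random.

    With ``symmetric`` (default), origin positions and efficiencies are
    mirror-symmetric about the chromosome midpoint.  A real genome hosts
    thousands of replicons, so rightward and leftward replication balance
    almost exactly (genome-mean p_R = 1/2); a desk-scale chromosome with a
    handful of random origins would drift several percent from that
    balance, which per-strand depth normalisation would turn into a
    spurious genome-wide RFD offset.  Mirroring preserves the large-genome
    balance in the scaled-down fixture.  ``symmetric`` requires an even
    ``n_origins``.
    """
    rng = np.random.default_rng(seed)
    origins = {}
    for chrom in layout.names:
        length = layout.length(chrom)
        slot = length / n_origins
        if symmetric:
            if n_origins % 2:
                raise TrackError("symmetric placement needs an even "
                                 "origin count")
            half = n_origins // 2
            base = ((np.arange(half) + 0.5) * slot
                    + rng.uniform(-0.2 * slot, 0.2 * slot, half))
            pos = np.concatenate([base, length - base[::-1]])
            eff_half = rng.uniform(min_efficiency, max_efficiency, half)
            eff = np.concatenate([eff_half, eff_half[::-1]])
        else:
            pos = ((np.arange(n_origins) + 0.5) * slot
                   + rng.uniform(-0.2 * slot, 0.2 * slot, n_origins))
            eff = rng.uniform(min_efficiency, max_efficiency, n_origins)
        pos = np.clip(np.round(pos).astype(int), 0, length - 1)
        origins[chrom] = list(zip(pos.tolist(), eff.tolist()))
    return ReplicationModel(layout, origins)


def simulate_counts(model: ReplicationModel, library: LibraryModel,
                    uncoupling: Sequence[UncouplingSpec] = (),
                    seed: Optional[int] = None,
                    p_right: Optional[Mapping[str, np.ndarray]] = None,
                    ) -> Dict[str, object]:
    """Run the full generator: truth p_R plus three sampled libraries.

    Returns a dict with keys ``p_right`` (truth), ``eps``, ``alpha``,
    ``control`` (:class:`StrandBinTrack` each).  Per-library seeds are
    derived from ``seed`` so libraries are independent but reproducible.
    """
    if p_right is None:
        p_right = fork_direction_probability(model, method="analytic")
    eps_exp = expected_tracks(p_right, model.layout, library, "eps")
    alpha_exp = expected_tracks(p_right, model.layout, library, "alpha")
    for spec in uncoupling:
        eps_exp = inject_uncoupling(eps_exp, spec)
        alpha_exp = inject_uncoupling(alpha_exp, spec)  # no-op, by design
    ctrl_exp = expected_control(model.layout, library)
    ss = np.random.SeedSequence(seed)
    s_eps, s_alpha, s_ctrl = ss.spawn(3)
    return {
        "p_right": {c: np.asarray(p_right[c]) for c in model.layout.names},
        "eps": sample_counts(eps_exp, s_eps),
        "alpha": sample_counts(alpha_exp, s_alpha),
        "control": sample_counts(ctrl_exp, s_ctrl),
    }


def _write_truth(path, layout: GenomeLayout,
                 p_right: Mapping[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbin_start\tp_right\n")
        for c in layout.names:
            for s, p in zip(layout.bin_starts(c), p_right[c]):
                fh.write(f"{c}\t{s}\t{float(p)!r}\n")


def write_fixture_sam(path, layout: GenomeLayout, n_pairs: int = 60,
                      n_ties: int = 5, seed: Optional[int] = None) -> dict:
    """Write a miniature SAM exercising the read-processing stage.

    Contains proper R1/R2 pairs on both strands, ``n_ties`` R1 records with
    AS == XS (multi-mapping ties, to be excluded) and a few non-tied
    XS-carrying records.  Returns the expected per-strand retained counts
    for verification.
    """
    import pysam

    rng = np.random.default_rng(seed)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": n} for c, n in layout.chromosomes]}
    expected = {"watson": 0, "crick": 0, "ties": 0}
    read_len = 50
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(n_pairs + n_ties):
            tid = int(rng.integers(0, len(layout.names)))
            chrom_len = layout.chromosomes[tid][1]
            pos = int(rng.integers(0, chrom_len - 2 * read_len))
            reverse = bool(rng.integers(0, 2))
            tie = i >= n_pairs
            a = pysam.AlignedSegment()
            a.query_name = f"pair{i}"
            a.query_sequence = "A" * read_len
            a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            a.reference_id = tid
            a.reference_start = pos
            a.cigarstring = f"{read_len}M"
            a.flag = 0x1 | 0x2 | 0x40 | (0x10 if reverse else 0x20)
            a.next_reference_id = tid
            a.next_reference_start = pos + read_len
            a.template_length = 2 * read_len
            tags = [("AS", -5)]
            if tie:
                tags.append(("XS", -5))
                expected["ties"] += 1
            elif rng.random() < 0.5:
                tags.append(("XS", -20))
            a.tags = tags
            out.write(a)
            if not tie:
                expected["crick" if reverse else "watson"] += 1
            # mate (R2) — ignored by the counting stage
            b = pysam.AlignedSegment()
            b.query_name = f"pair{i}"
            b.query_sequence = "A" * read_len
            b.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            b.reference_id = tid
            b.reference_start = pos + read_len
            b.cigarstring = f"{read_len}M"
            b.flag = 0x1 | 0x2 | 0x80 | (0x20 if reverse else 0x10)
            b.next_reference_id = tid
            b.next_reference_start = pos
            b.template_length = -2 * read_len
            out.write(b)
    return expected


def make_fixture(model: ReplicationModel, library: LibraryModel,
                 uncoupling: Sequence[UncouplingSpec] = (),
                 out_prefix: str = "fixture", seed: Optional[int] = None,
                 ) -> Dict[str, str]:
    """Write a complete simulated dataset to ``<out_prefix>.*`` files.

    Emits binned CSVs for the Polε mutant, Polα mutant and control
    libraries, truth tables (per-bin p_R, origin table, uncoupling
    intervals), the genome layout, and a miniature SAM fixture.
    Returns a dict of the paths written.
    """
    sim = simulate_counts(model, library, uncoupling, seed=seed)
    layout = model.layout
    paths = {}

    def p(suffix):
        path = f"{out_prefix}.{suffix}"
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        return path

    from .tracks import write_layout
    paths["layout"] = p("genome.tsv")
    write_layout(layout, paths["layout"])
    for name in ("eps", "alpha", "control"):
        paths[name] = p(f"{name}.csv")
        write_strand_csv(sim[name], paths[name])
    paths["p_right"] = p("p_right.tsv")
    _write_truth(paths["p_right"], layout, sim["p_right"])
    paths["origins"] = p("origins.tsv")
    with open(paths["origins"], "w") as fh:
        fh.write("chrom\tposition\tefficiency\n")
        for c in layout.names:
            for pos, eff in model.origins[c]:
                fh.write(f"{c}\t{pos}\t{float(eff)!r}\n")
    paths["uncoupling"] = p("uncoupling.tsv")
    with open(paths["uncoupling"], "w") as fh:
        fh.write("chrom\tstart\tend\tdirection\tsuppression\n")
        for s in uncoupling:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.direction}\t"
                     f"{float(s.suppression)!r}\n")
    paths["sam"] = p("reads.sam")
    write_fixture_sam(paths["sam"], layout,
                      seed=np.random.SeedSequence(seed).spawn(1)[0])
    return paths
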