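"""Derived replication signals from polymerase-usage profiles.

* RFD — replication fork directionality, the normalised difference between
  rightward- and leftward-fork-diagnostic usage, in [-1, 1]; computed from
  Polε alone, Polα alone, both pooled, or Okazaki-fragment strand counts.
* Ini — initiation index: the sign-gated sum of usage differentials, with
  positive values marking initiation zones and negative values marking
  termination of converging forks.
* Fk^R / Fk^L — orientation-resolved fork indices: the same logic applied
  to the two usage tracks diagnostic of one fork direction only.
* CI^R / CI^L — coupling indices: leading-minus-lagging usage for one fork
  orientation; 0 when synthesis of the two strands is balanced, negative
  when leading-strand (Polε) synthesis is under-represented.

Ini and Fk are Z-score normalised with Z(0) subtracted (a pure rescaling
by the genome-wide standard deviation) so that the sign structure is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .tracks import (IndexTrack, StrandBinTrack, TrackError, diff_track,
                     moving_average, znorm_shift_track)
from .usage import UsageProfile

__all__ = [
    "SmoothingPlan",
    "PLANS",
    "rfd",
    "rfd_okseq",
    "initiation_index",
    "fork_index",
    "coupling_index",
    "to_fork_proportion",
]


@dataclass(frozen=True)
class SmoothingPlan:
    """Moving-average half-widths for one analysis context.

    m_pre smooths usage before differencing, m_post smooths the
    differentials, m_rfd smooths RFD tracks.
    """

    m_pre: int
    m_post: int
    m_rfd: int = 3

    def __post_init__(self):
        if min(self.m_pre, self.m_post, self.m_rfd) < 0:
            raise TrackError("smoothing half-widths must be non-negative")


#: genome: whole-chromosome plots; meta: gene-anchored averages/heat maps
PLANS: Dict[str, SmoothingPlan] = {
    "genome": SmoothingPlan(m_pre=30, m_post=15, m_rfd=3),
    "meta": SmoothingPlan(m_pre=7, m_post=7, m_rfd=3),
}


def _ratio_index(num: Dict[str, np.ndarray], den: Dict[str, np.ndarray],
                 mask: Dict[str, np.ndarray], layout) -> IndexTrack:
    values, out_mask = {}, {}
    for c in layout.names:
        ok = np.asarray(mask[c], dtype=bool) & (den[c] > 0)
        v = np.zeros_like(den[c], dtype=float)
        v[ok] = num[c][ok] / den[c][ok]
        values[c], out_mask[c] = v, ok
    return IndexTrack(layout, values, out_mask)


def rfd(profile: UsageProfile, mode: str = "combined",
        m_rfd: int = 3) -> IndexTrack:
    """Replication fork directionality from usage, smoothed with ``m_rfd``.

    eps: (E_w - E_c)/(E_w + E_c); alpha: (-A_w + A_c)/(A_w + A_c);
    combined: (E_w - E_c - A_w + A_c)/(E_w + E_c + A_w + A_c).
    Values lie in [-1, 1] before smoothing; zero-denominator bins are
    masked.
    """
    L = profile.layout
    if mode == "eps":
        num = {c: profile.e_w[c] - profile.e_c[c] for c in L.names}
        den = {c: profile.e_w[c] + profile.e_c[c] for c in L.names}
        mask = profile.mask_eps
    elif mode == "alpha":
        num = {c: -profile.a_w[c] + profile.a_c[c] for c in L.names}
        den = {c: profile.a_w[c] + profile.a_c[c] for c in L.names}
        mask = profile.mask_alpha
    elif mode == "combined":
        num = {c: (profile.e_w[c] - profile.e_c[c]
                   - profile.a_w[c] + profile.a_c[c]) for c in L.names}
        den = {c: (profile.e_w[c] + profile.e_c[c]
                   + profile.a_w[c] + profile.a_c[c]) for c in L.names}
        mask = profile.mask
    else:
        raise TrackError(f"unknown RFD mode {mode!r}")
    return _ratio_index(num, den, mask, L).smoothed(m_rfd)


def rfd_okseq(ok_counts: StrandBinTrack, m_rfd: int = 3) -> IndexTrack:
    """RFD from Okazaki-fragment strand counts: (OK_C - OK_W)/(OK_C + OK_W).

    Okazaki fragments are lagging-strand products, so rightward forks
    deposit them on the Crick strand; the sign convention matches the
    usage-based RFDs.
    """
    L = ok_counts.layout
    num = {c: ok_counts.crick[c] - ok_counts.watson[c] for c in L.names}
    den = {c: ok_counts.crick[c] + ok_counts.watson[c] for c in L.names}
    return _ratio_index(num, den, ok_counts.mask, L).smoothed(m_rfd)


def _smoothed_diffs(profile: UsageProfile, plan: SmoothingPlan):
    """Usage -> smooth(m_pre) -> neighbour differential -> smooth(m_post)."""
    sm = profile.smoothed(plan.m_pre)
    out = {}
    for name, arr, msk in (("E_w", sm.e_w, sm.mask_eps),
                           ("E_c", sm.e_c, sm.mask_eps),
                           ("A_w", sm.a_w, sm.mask_alpha),
                           ("A_c", sm.a_c, sm.mask_alpha)):
        vals, mask = {}, {}
        for c in profile.layout.names:
            d, dm = diff_track(arr[c], msk[c])
            vals[c], mask[c] = moving_average(d, dm, plan.m_post)
        out[name] = (vals, mask)
    return out


def _gated_index(layout, terms, gate) -> IndexTrack:
    """Sum the differential terms where the sign gate holds, else 0.

    Gate-failing bins are set to 0 (not masked) so the Z-shift statistics
    cover the whole genome; only bins masked in any input differential are
    masked.  The result is Z-shifted genome-wide.
    """
    values, mask = {}, {}
    for c in layout.names:
        m = np.ones(layout.n_bins(c), dtype=bool)
        for _, term_mask in terms:
            m &= term_mask[c]
        g = gate(c) & m
        v = np.zeros(layout.n_bins(c))
        for term_vals, _ in terms:
            v += term_vals[c]
        values[c] = np.where(g, v, 0.0)
        mask[c] = m
    track = IndexTrack(layout, values, mask)
    return znorm_shift_track(track)


def initiation_index(profile: UsageProfile,
                     plan: SmoothingPlan) -> IndexTrack:
    """Ini(x) = dE_w - dE_c - dA_w + dA_c, gated on replicon sign patterns.

    Computed only where all four smoothed differentials show the pattern of
    bidirectional initiation (dE_w>0, dE_c<0, dA_w<0, dA_c>0) or of two
    merging forks (all four signs reversed); elsewhere 0.  Z-shifted so
    positive values mark initiation and negative values termination.
    """
    d = _smoothed_diffs(profile, plan)
    L = profile.layout

    def gate(c):
        ew, ec = d["E_w"][0][c], d["E_c"][0][c]
        aw, ac = d["A_w"][0][c], d["A_c"][0][c]
        ini = (ew > 0) & (ec < 0) & (aw < 0) & (ac > 0)
        ter = (ew < 0) & (ec > 0) & (aw > 0) & (ac < 0)
        return ini | ter

    terms = [
        (d["E_w"][0], d["E_w"][1]),
        ({c: -d["E_c"][0][c] for c in L.names}, d["E_c"][1]),
        ({c: -d["A_w"][0][c] for c in L.names}, d["A_w"][1]),
        (d["A_c"][0], d["A_c"][1]),
    ]
    return _gated_index(L, terms, gate)


def fork_index(profile: UsageProfile, plan: SmoothingPlan,
               direction: str) -> IndexTrack:
    """Orientation-resolved initiation/termination signal.

    rightward: Fk^R = dE_w + dA_c where the two differentials share sign
    (both positive: initiation of rightward forks; both negative: their
    termination).  leftward: Fk^L = -dE_c - dA_w where dE_c and dA_w share
    sign (both negative: initiation; both positive: termination).
    Z-shifted like the initiation index.
    """
    d = _smoothed_diffs(profile, plan)
    L = profile.layout
    if direction == "rightward":
        a_vals, a_mask = d["E_w"]
        b_vals, b_mask = d["A_c"]

        def gate(c):
            return ((a_vals[c] > 0) & (b_vals[c] > 0)) | \
                   ((a_vals[c] < 0) & (b_vals[c] < 0))

        terms = [(a_vals, a_mask), (b_vals, b_mask)]
    elif direction == "leftward":
        a_vals, a_mask = d["E_c"]
        b_vals, b_mask = d["A_w"]

        def gate(c):
            return ((a_vals[c] < 0) & (b_vals[c] < 0)) | \
                   ((a_vals[c] > 0) & (b_vals[c] > 0))

        terms = [({c: -a_vals[c] for c in L.names}, a_mask),
                 ({c: -b_vals[c] for c in L.names}, b_mask)]
    else:
        raise TrackError("direction must be 'rightward' or 'leftward'")
    return _gated_index(L, terms, gate)


def coupling_index(profile: UsageProfile, direction: str,
                   m: int = 30) -> IndexTrack:
    """Leading-minus-lagging usage for one fork orientation, in [-1, 1].

    CI^R = (E_w - A_c)/(E_w + A_c) for rightward forks, CI^L =
    (E_c - A_w)/(E_c + A_w) for leftward.  Usage is smoothed with ``m``
    first (30 genome-wide, 7 for gene-anchored averages).  Positive values
    mean a Polε (leading) bias, negative a Polα (lagging) bias.
    """
    sm = profile.smoothed(m)
    L = profile.layout
    if direction == "rightward":
        lead, lag = sm.e_w, sm.a_c
    elif direction == "leftward":
        lead, lag = sm.e_c, sm.a_w
    else:
        raise TrackError("direction must be 'rightward' or 'leftward'")
    num = {c: lead[c] - lag[c] for c in L.names}
    den = {c: lead[c] + lag[c] for c in L.names}
    return _ratio_index(num, den, sm.mask, L)


def to_fork_proportion(track: IndexTrack) -> IndexTrack:
    """Map an RFD track to a 0-100% rightward-fork proportion.

    The range [mean - 3 sd, mean + 3 sd] of the unmasked values — covering
    99.7% of Gaussian data — maps linearly to [0, 100]; values outside are
    clipped so proportions stay meaningful.
    """
    flat = track.unmasked_values()
    if flat.size < 2:
        raise TrackError("need at least 2 unmasked values")
    mu = float(flat.mean())
    sd = float(flat.std())
    if sd == 0.0:
        raise TrackError("zero variance RFD cannot be rescaled")
    values = {}
    for c in track.layout.names:
        v = (track.values[c] - (mu - 3 * sd)) / (6 * sd) * 100.0
        values[c] = np.clip(v, 0.0, 100.0)
    return IndexTrack(track.layout, values,
                      {c: m.copy() for c, m in track.mask.items()},
                      normalization=(mu, sd))
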