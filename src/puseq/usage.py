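"""Relative polymerase usage from mutant and control count tracks.

A Pu-seq experiment for one polymerase yields two libraries: the
rNMP-hypermutating polymerase mutant and a polymerase-proficient control.
Relative usage on each strand is the ratio of depth-normalised mutant to
control counts, e.g. E_w(x) = N'_w^eps(x) / N'_w^+(x) for Polε on the
Watson strand.  Bins where either library has fewer than ``threshold``
raw counts on both strands are masked out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .tracks import (GenomeLayout, IndexTrack, StrandBinTrack, TrackError,
                     moving_average)

__all__ = [
    "UsageProfile",
    "mask_low_count",
    "normalize_depth",
    "usage_ratio",
    "compute_usage",
    "SMOOTHING_PRESETS",
]

# moving-average half-widths used when plotting / downstream, by context
SMOOTHING_PRESETS = {"raw": 3, "genome": 30, "meta": 7}

LOW_COUNT_THRESHOLD = 5


def _require_same_layout(a, b):
    if a.layout != b.layout:
        raise TrackError("tracks have different genome layouts")


def mask_low_count(mutant: StrandBinTrack, control: StrandBinTrack,
                   threshold: int = LOW_COUNT_THRESHOLD,
                   ) -> Dict[str, np.ndarray]:
    """Validity mask: a bin fails if either library is below ``threshold``
    on *both* strands (a library with one well-covered strand passes)."""
    _require_same_layout(mutant, control)
    out = {}
    for c in mutant.layout.names:
        mut_low = (mutant.watson[c] < threshold) & (mutant.crick[c] < threshold)
        ctl_low = (control.watson[c] < threshold) & (control.crick[c] < threshold)
        out[c] = ~(mut_low | ctl_low) & mutant.mask[c] & control.mask[c]
    return out


def normalize_depth(track: StrandBinTrack) -> StrandBinTrack:
    """Divide each strand by its library total so each strand sums to 1.

    Totals are taken over all bins (masked included): sequencing depth is a
    property of the whole library, not of the bins that survive masking.
    """
    out = track.copy()
    for strand, arrays in (("watson", out.watson), ("crick", out.crick)):
        total = track.strand_total(strand)
        if total <= 0:
            raise TrackError(f"zero total on {strand} strand")
        for c in arrays:
            arrays[c] = arrays[c] / total
    return out


def usage_ratio(mutant_norm: StrandBinTrack, control_norm: StrandBinTrack,
                mask: Dict[str, np.ndarray],
                ) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray],
                           Dict[str, np.ndarray]]:
    """Per-bin mutant/control ratio per strand on unmasked bins.

    Returns (watson_ratio, crick_ratio, mask); bins where the normalised
    control is zero on either strand are masked.  No smoothing is applied
    here — each downstream consumer smooths with its own preset.
    """
    _require_same_layout(mutant_norm, control_norm)
    w_out, c_out, m_out = {}, {}, {}
    for c in mutant_norm.layout.names:
        ok = (np.asarray(mask[c], dtype=bool)
              & (control_norm.watson[c] > 0) & (control_norm.crick[c] > 0))
        w = np.zeros_like(mutant_norm.watson[c], dtype=float)
        k = np.zeros_like(w)
        w[ok] = mutant_norm.watson[c][ok] / control_norm.watson[c][ok]
        k[ok] = mutant_norm.crick[c][ok] / control_norm.crick[c][ok]
        w_out[c], c_out[c], m_out[c] = w, k, ok
    return w_out, c_out, m_out


@dataclass
class UsageProfile:
    """Relative usage of Polε (E_w, E_c) and Polα (A_w, A_c) per bin.

    The ε and α masks are tracked separately (the two experiments mask
    different bins) and intersected on demand via :attr:`mask`.
    """

    layout: GenomeLayout
    e_w: Dict[str, np.ndarray]
    e_c: Dict[str, np.ndarray]
    a_w: Dict[str, np.ndarray]
    a_c: Dict[str, np.ndarray]
    mask_eps: Dict[str, np.ndarray]
    mask_alpha: Dict[str, np.ndarray]

    @property
    def mask(self) -> Dict[str, np.ndarray]:
        return {c: self.mask_eps[c] & self.mask_alpha[c]
                for c in self.layout.names}

    def smoothed(self, m: int) -> "UsageProfile":
        """Moving average (half-width ``m`` bins) of all four usage tracks."""
        e_w, e_c, a_w, a_c = {}, {}, {}, {}
        m_e, m_a = {}, {}
        for c in self.layout.names:
            e_w[c], me1 = moving_average(self.e_w[c], self.mask_eps[c], m)
            e_c[c], me2 = moving_average(self.e_c[c], self.mask_eps[c], m)
            a_w[c], ma1 = moving_average(self.a_w[c], self.mask_alpha[c], m)
            a_c[c], ma2 = moving_average(self.a_c[c], self.mask_alpha[c], m)
            m_e[c] = me1 & me2
            m_a[c] = ma1 & ma2
        return UsageProfile(self.layout, e_w, e_c, a_w, a_c, m_e, m_a)

    def track(self, which: str) -> IndexTrack:
        """One usage component as an :class:`IndexTrack` (for I/O/plotting)."""
        arr = {"E_w": self.e_w, "E_c": self.e_c,
               "A_w": self.a_w, "A_c": self.a_c}[which]
        msk = self.mask_eps if which.startswith("E") else self.mask_alpha
        return IndexTrack(self.layout, {c: arr[c].copy() for c in arr},
                          {c: msk[c].copy() for c in msk})


def compute_usage(mutant_eps: StrandBinTrack, mutant_alpha: StrandBinTrack,
                  control: StrandBinTrack,
                  threshold: int = LOW_COUNT_THRESHOLD) -> UsageProfile:
    """Full usage computation: low-count masking, depth normalisation, ratio."""
    ctrl_norm = normalize_depth(control)
    eps_mask = mask_low_count(mutant_eps, control, threshold)
    alpha_mask = mask_low_count(mutant_alpha, control, threshold)
    e_w, e_c, m_e = usage_ratio(normalize_depth(mutant_eps), ctrl_norm,
                                eps_mask)
    a_w, a_c, m_a = usage_ratio(normalize_depth(mutant_alpha), ctrl_norm,
                                alpha_mask)
    return UsageProfile(mutant_eps.layout, e_w, e_c, a_w, a_c, m_e, m_a)
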