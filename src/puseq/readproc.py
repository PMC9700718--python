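"""Aligned Pu-seq reads to per-strand binned rNMP-position counts.

The 5' end of each R1 read marks the 5' end of the alkali-hydrolysed
single-stranded fragment, i.e. an incorporated rNMP position.  R1 records
are filtered for alignment-score ties (reads mapping equally well to
multiple loci), then their 5' ends are counted into fixed-width bins
separately for the Watson (forward-mapped) and Crick (reverse-mapped)
strands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator

import numpy as np
import pysam

from .tracks import GenomeLayout, StrandBinTrack, TrackError

__all__ = ["filter_ambiguous", "count_rnmp_ends", "count_bam", "CountSummary"]

log = logging.getLogger(__name__)


def _is_candidate_r1(rec: "pysam.AlignedSegment") -> bool:
    return (rec.is_read1 and not rec.is_unmapped and not rec.is_secondary
            and not rec.is_supplementary and rec.is_proper_pair)


def filter_ambiguous(records: Iterable["pysam.AlignedSegment"],
                     strict: bool = False,
                     ) -> Iterator["pysam.AlignedSegment"]:
    """Drop R1 records whose best alignment ties the second-best.

    A record with AS (best score) equal to or below XS (second-best score)
    mapped to multiple genomic locations equally well and is excluded;
    records without an XS tag are unique alignments and kept.  Streams
    lacking AS tags are passed through with a warning (or an error when
    ``strict``).  Unmapped, secondary, supplementary, non-proper-pair and
    R2 records are dropped silently.
    """
    warned = False
    for rec in records:
        if not _is_candidate_r1(rec):
            continue
        if not rec.has_tag("AS"):
            if strict:
                raise TrackError(
                    f"record {rec.query_name!r} lacks an AS score tag")
            if not warned:
                warnings.warn("alignment stream without AS score tags: "
                              "tie filtering disabled", stacklevel=2)
                warned = True
            yield rec
            continue
        if rec.has_tag("XS") and rec.get_tag("AS") <= rec.get_tag("XS"):
            continue
        yield rec


@dataclass
class CountSummary:
    retained: int = 0
    unplaced: int = 0
    per_strand: Dict[str, int] = field(default_factory=lambda:
                                       {"watson": 0, "crick": 0})


def count_rnmp_ends(records: Iterable["pysam.AlignedSegment"],
                    layout: GenomeLayout, flip_strands: bool = False,
                    ) -> tuple[StrandBinTrack, CountSummary]:
    """Count filtered R1 5' ends into per-strand bins.

    The 5' end is the leftmost reference coordinate for forward-mapped R1
    and the rightmost for reverse-mapped R1.  Forward-mapped reads count
    to the Watson strand and reverse-mapped to Crick; ``flip_strands``
    inverts that convention.  Reads on chromosomes absent from the layout
    go to an "unplaced" tally.
    """
    watson = layout.zeros()
    crick = layout.zeros()
    summary = CountSummary()
    for rec in records:
        summary.retained += 1
        chrom = rec.reference_name
        if chrom not in layout:
            summary.unplaced += 1
            continue
        end5 = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
        idx = layout.bin_index(chrom, end5)
        to_crick = rec.is_reverse != flip_strands
        if to_crick:
            crick[chrom][idx] += 1
            summary.per_strand["crick"] += 1
        else:
            watson[chrom][idx] += 1
            summary.per_strand["watson"] += 1
    log.info("counted %d R1 records (%d watson, %d crick, %d unplaced)",
             summary.retained, summary.per_strand["watson"],
             summary.per_strand["crick"], summary.unplaced)
    return StrandBinTrack(layout, watson, crick), summary


def count_bam(path, layout: GenomeLayout, flip_strands: bool = False,
              strict: bool = False) -> tuple[StrandBinTrack, CountSummary]:
    """Open a SAM/BAM file and run tie filtering plus 5'-end counting."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return count_rnmp_ends(filter_ambiguous(fh, strict=strict),
                               layout, flip_strands=flip_strands)
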