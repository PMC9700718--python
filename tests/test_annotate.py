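"""Gene-anchored profiles, stratification and zone-annotation overlap."""

import numpy as np
import pandas as pd
import pytest

from puseq.tracks import GenomeLayout, IndexTrack, TrackError
from puseq.annotate import (GeneRecord, directional_metaprofile, metaprofile,
                            read_genes, scaled_gene_profile, stratify,
                            window_sum_vs_feature, zone_overlap_partition)
from puseq.zones import InitiationZone


def track_from(values, chrom="c"):
    lay = GenomeLayout({chrom: len(values) * 1000})
    return IndexTrack(lay, {chrom: np.array(values, float)})


def gene(chrom="c", tss=50_000, tts=80_000, strand="+", fpkm=1.0,
         name="g", coding=True):
    return GeneRecord(chrom, tss, tts, strand, fpkm, name, coding)


class TestMetaprofile:
    def test_constant_track_flat_profile(self):
        tr = track_from([7.0] * 100)
        prof = metaprofile(tr, [gene()], flank=20_000)
        assert np.allclose(prof["mean"].dropna(), 7.0)

    def test_plus_gene_profile_is_track_slice(self):
        vals = np.arange(100.0)
        tr = track_from(vals)
        prof = metaprofile(tr, [gene(tss=50_000)], flank=10_000)
        assert prof["mean"].tolist() == vals[40:61].tolist()

    def test_minus_gene_mirrored(self):
        vals = np.arange(100.0)
        tr = track_from(vals)
        prof = metaprofile(tr, [gene(tss=50_000, tts=20_000, strand="-")],
                           flank=10_000)
        # positive offsets point downstream of transcription (leftwards)
        assert prof["mean"].tolist() == vals[40:61][::-1].tolist()

    def test_mirroring_is_involution(self):
        rng = np.random.default_rng(0)
        tr = track_from(rng.normal(size=100))
        g_minus = gene(tss=50_000, tts=20_000, strand="-")
        once = metaprofile(tr, [g_minus], flank=10_000)["mean"].to_numpy()
        twice = once[::-1][::-1]
        assert np.array_equal(once, twice)
        # and the minus-strand profile is the reverse of the plus view
        plus_view = metaprofile(tr, [g_minus], flank=10_000,
                                orient=False)["mean"].to_numpy()
        assert np.array_equal(once, plus_view[::-1])

    def test_no_anchors_errors(self):
        with pytest.raises(TrackError):
            metaprofile(track_from([1.0] * 10), [])

    def test_cd_cv_swap_for_minus_genes(self):
        right = track_from([1.0] * 100)
        left = track_from([-1.0] * 100)
        plus = [gene(strand="+")]
        minus = [gene(tss=80_000, tts=50_000, strand="-")]
        for genes in (plus, minus):
            prof = directional_metaprofile(right, left, genes,
                                           flank=10_000)
            # CD always reads from the co-directional track
            assert np.allclose(prof["CD"]["mean"].dropna(),
                               1.0 if genes is plus else -1.0)


class TestStratify:
    def _genes(self, fpkms, lengths=None):
        lengths = lengths or [30_000] * len(fpkms)
        return [gene(tss=i * 100_000, tts=i * 100_000 + l, fpkm=f,
                     name=f"g{i}")
                for i, (f, l) in enumerate(zip(fpkms, lengths))]

    def test_quartiles_of_eight(self):
        groups = stratify(self._genes([1, 5, 3, 7, 2, 8, 4, 6]), by="fpkm")
        assert [len(g) for g in groups] == [2, 2, 2, 2]
        assert [g.fpkm for g in groups[0]] == [1, 2]
        assert [g.fpkm for g in groups[3]] == [7, 8]

    def test_top_fraction_filter(self):
        genes = self._genes(list(range(10)))
        groups = stratify(genes, by="length", n_groups=1,
                          active_top_fraction=0.5)
        assert len(groups[0]) == 5
        assert all(g.fpkm >= 5 for g in groups[0])

    def test_ties_resolve_by_stable_order(self):
        genes = self._genes([1.0, 1.0, 1.0, 1.0])
        groups = stratify(genes, by="fpkm", n_groups=2)
        assert [g.name for g in groups[0]] == ["g0", "g1"]
        assert [g.name for g in groups[1]] == ["g2", "g3"]


class TestScaledGeneProfile:
    def test_uniform_rightward_proportion(self):
        tr = track_from([100.0] * 100)
        prof, skipped = scaled_gene_profile(tr, [gene()], nbins=10)
        assert skipped == 0
        assert np.allclose(prof["mean"], 100.0)

    def test_minus_gene_orientation_flip(self):
        tr = track_from([100.0] * 100)
        g = gene(tss=80_000, tts=50_000, strand="-")
        prof, _ = scaled_gene_profile(tr, [g], nbins=10, flip="proportion")
        assert np.allclose(prof["mean"], 0.0)

    def test_short_gene_skipped(self):
        tr = track_from([1.0] * 10)
        g = gene(tss=500, tts=900)
        _, skipped = scaled_gene_profile(tr, [g], nbins=5)
        assert skipped == 1

    def test_declining_proportion_across_body(self):
        # rightward proportion falls from 5' to 3' when initiation flanks
        # the gene: emulate with a linear ramp under a plus-strand gene
        vals = np.concatenate([np.full(20, 90.0),
                               np.linspace(90, 10, 30), np.full(50, 10.0)])
        tr = track_from(vals)
        prof, _ = scaled_gene_profile(tr, [gene(tss=20_000, tts=50_000)],
                                      nbins=10)
        assert prof["mean"].iloc[0] > prof["mean"].iloc[-1]
        assert np.all(np.diff(prof["mean"]) <= 0)


class TestWindowSums:
    def test_zero_window_stays_zero(self):
        vals = np.zeros(100)
        vals[70:75] = 2.0  # signal near the second gene only
        tr = track_from(vals)
        genes = [gene(tss=30_000, tts=40_000, name="quiet"),
                 gene(tss=80_000, tts=90_000, name="active")]
        df = window_sum_vs_feature(tr, genes, window=30_000)
        quiet = df[df["name"] == "quiet"].iloc[0]
        active = df[df["name"] == "active"].iloc[0]
        assert quiet["ini_sum_z"] == 0.0
        assert active["ini_sum_z"] > 0.0

    def test_z_shift_identity(self):
        vals = np.zeros(100)
        vals[25:30] = 1.0   # sum 5 upstream of gene A
        vals[65:70] = -1.0  # sum -5 upstream of gene B
        tr = track_from(vals)
        genes = [gene(tss=30_000, tts=40_000, name="a"),
                 gene(tss=70_000, tts=80_000, name="b")]
        df = window_sum_vs_feature(tr, genes, window=30_000)
        assert df["ini_sum_z"].tolist() == pytest.approx([1.0, -1.0])

    def test_strand_aware_upstream(self):
        vals = np.zeros(100)
        vals[37:42] = 3.0  # right of 36 kb: upstream only for a minus gene
        tr = track_from(vals)
        plus = gene(tss=30_000, tts=50_000, name="p")
        minus = gene(tss=36_000, tts=10_000, strand="-", name="m")
        df = window_sum_vs_feature(tr, [plus, minus], window=30_000)
        assert df[df["name"] == "p"]["ini_sum"].iloc[0] == 0.0
        assert df[df["name"] == "m"]["ini_sum"].iloc[0] == 15.0

    def test_fpkm_zero_floored_and_flagged(self):
        tr = track_from(np.random.default_rng(0).normal(size=100))
        genes = [gene(tss=30_000, tts=40_000, fpkm=0.0, name="off"),
                 gene(tss=60_000, tts=70_000, fpkm=5.0, name="on"),
                 gene(tss=80_000, tts=90_000, fpkm=9.0, name="on2")]
        df = window_sum_vs_feature(tr, genes, window=30_000)
        off = df[df["name"] == "off"].iloc[0]
        assert bool(off["fpkm_zero"])
        assert off["log_fpkm_z"] == df["log_fpkm_z"].min()


class TestZoneOverlapPartition:
    LAYOUT = GenomeLayout({"c": 300_000})

    def test_all_zones_inside_active_bodies(self):
        genes = [gene(tss=0, tts=300_000, fpkm=2.0)]
        zones = [InitiationZone("c", 50_000, 60_000, 55_000, 1.0)]
        frac = zone_overlap_partition(zones, genes, self.LAYOUT)
        assert frac["transcribed"] == pytest.approx(1.0)

    def test_half_flank_half_other(self):
        genes = [gene(tss=100_000, tts=200_000, fpkm=1.0)]
        # zone straddles the upstream-flank boundary at 70 kb
        zones = [InitiationZone("c", 60_000, 80_000, 65_000, 1.0)]
        frac = zone_overlap_partition(zones, genes, self.LAYOUT)
        assert frac["flank"] == pytest.approx(0.5)
        assert frac["other"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        genes = [gene(tss=int(s), tts=int(s) + 20_000,
                      fpkm=float(rng.integers(0, 3)), name=f"g{i}")
                 for i, s in enumerate(rng.integers(0, 250_000, 8))]
        zones = [InitiationZone("c", int(s), int(s) + 15_000,
                                int(s) + 1000, 1.0)
                 for s in rng.integers(0, 280_000, 6)]
        frac = zone_overlap_partition(zones, genes, self.LAYOUT)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(4)
        genes = [gene(tss=int(s), tts=int(s) + int(l),
                      strand=rng.choice(["+", "-"]),
                      fpkm=float(rng.integers(0, 2)), name=f"g{i}")
                 for i, (s, l) in enumerate(zip(
                     rng.integers(0, 250_000, 10),
                     rng.integers(5000, 40_000, 10)))]
        # minus-strand genes: swap tss/tts so transcription runs leftwards
        genes = [GeneRecord(g.chrom, g.tts, g.tss, g.strand, g.fpkm, g.name)
                 if g.strand == "-" else g for g in genes]
        zones = [InitiationZone("c", int(s), int(s) + 10_000, int(s), 1.0)
                 for s in rng.integers(0, 280_000, 5)]
        frac = zone_overlap_partition(zones, genes, self.LAYOUT,
                                      flank=30_000)

        # brute-force per-base classification with explicit precedence
        def classify(pos):
            cats = set()
            for g in genes:
                if g.start <= pos < g.end:
                    cats.add("transcribed" if g.fpkm > 0
                             else "non_transcribed")
                up = (g.tss - 30_000, g.tss) if g.strand == "+" \
                    else (g.tss, g.tss + 30_000)
                dn = (g.tts, g.tts + 30_000) if g.strand == "+" \
                    else (g.tts - 30_000, g.tts)
                for lo, hi in (up, dn):
                    if lo <= pos < hi:
                        cats.add("flank")
            for cat in ("transcribed", "flank", "non_transcribed"):
                if cat in cats:
                    return cat
            return "other"

        counts = {"transcribed": 0, "flank": 0, "non_transcribed": 0,
                  "other": 0}
        total = 0
        for z in zones:
            for pos in range(z.start, z.end):
                counts[classify(pos)] += 1
                total += 1
        for cat, c in counts.items():
            assert frac[cat] == pytest.approx(c / total, abs=1e-12)


class TestReadGenes:
    def test_bed_like_parsing(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("c\t1000\t5000\tgA\t2.5\t+\tprotein_coding\n"
                        "c\t8000\t9000\tgB\t0.0\t-\tlincRNA\n")
        genes = read_genes(path)
        assert genes[0].tss == 1000 and genes[0].tts == 5000
        assert genes[1].tss == 9000 and genes[1].tts == 8000
        assert genes[1].strand == "-" and not genes[1].protein_coding


class TestOnSimulator:
    def test_meta_initiation_peak_upstream_of_tss(self):
        # origins placed 20 kb upstream of every synthetic TSS: the
        # oriented meta initiation index peaks near offset -20 kb
        from puseq.indices import PLANS, initiation_index
        from puseq.simulate import (LibraryModel, ReplicationModel,
                                    simulate_counts)
        from puseq.usage import compute_usage

        lay = GenomeLayout({"c": 4_000_000})
        genes, origins = [], []
        for i in range(7):
            tss = 300_000 + i * 500_000
            strand = "+" if i % 2 == 0 else "-"
            if strand == "+":
                genes.append(gene(tss=tss, tts=tss + 100_000, strand="+",
                                  name=f"g{i}"))
                origins.append((tss - 20_000, 0.8))
            else:
                genes.append(gene(tss=tss, tts=tss - 100_000, strand="-",
                                  name=f"g{i}"))
                origins.append((tss + 20_000, 0.8))
        model = ReplicationModel(lay, {"c": sorted(origins)})
        sim = simulate_counts(model, LibraryModel(depth=300), seed=9)
        prof_usage = compute_usage(sim["eps"], sim["alpha"], sim["control"])
        ini = initiation_index(prof_usage, PLANS["meta"])
        meta = metaprofile(ini, genes, anchor_type="TSS", flank=100_000)
        peak_offset = meta.loc[meta["mean"].idxmax(), "offset"]
        assert abs(peak_offset - (-20_000)) <= 17_000  # m_pre + m_post + 3


def test_metaprofile_matrix_sorted_and_oriented():
    from puseq.annotate import metaprofile_matrix
    vals = np.arange(100.0)
    tr = track_from(vals)
    genes = [gene(tss=50_000, tts=90_000, name="long"),
             gene(tss=50_000, tts=30_000, strand="-", name="short")]
    mat = metaprofile_matrix(tr, genes, flank=5000, sort_by="length")
    assert list(mat.index) == ["short", "long"]
    assert mat.loc["long"].tolist() == vals[45:56].tolist()
    assert mat.loc["short"].tolist() == vals[45:56][::-1].tolist()
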