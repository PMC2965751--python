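"""Anchored offsets, profile aggregation and sliding-window smoothing."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import chiptile as ct
from chiptile.metagene import (
    MetageneConfig,
    MetageneProfile,
    aggregate_profile,
    anchored_offset,
    smooth_profile,
)
from chiptile.tracks_io import ValidationError


PLUS = ct.Gene("p", "chr1", 1000, 2000, "+")
MINUS = ct.Gene("m", "chr1", 1000, 2000, "-")


class TestAnchoredOffset:
    @pytest.mark.parametrize(
        "gene,mid,expected",
        [
            (PLUS, 1100, ("5p", 100)),    # 5' half of the gene
            (PLUS, 900, ("5p", -100)),    # upstream half-IG
            (MINUS, 1900, ("5p", 100)),   # strand flip
            (MINUS, 2100, ("5p", -100)),  # upstream of a '-' gene is rightward
            (PLUS, 1700, ("3p", -300)),   # 3' half, measured from the 3' end
            (PLUS, 2100, ("3p", 100)),    # downstream half-IG
            (MINUS, 1200, ("3p", -200)),
            (MINUS, 900, ("3p", 100)),
            (PLUS, 5000, None),           # far outside
        ],
    )
    def test_strand_aware_mapping(self, gene, mid, expected):
        got = anchored_offset(gene, mid, upstream_half=400,
                              downstream_half=400, extent=500)
        if expected is None:
            assert got is None
        else:
            assert got[0] == expected[0]
            assert got[1] == pytest.approx(expected[1])

    def test_half_ig_truncation_blocks_neighbor_probes(self):
        # upstream half-IG of 100: a probe 150bp upstream belongs to no arm
        assert anchored_offset(PLUS, 850, 100, 400, 500) is None
        # extent truncates even a wide IG
        assert anchored_offset(PLUS, 940, 400, 400, extent=50) is None

    def test_mid_gene_tie_break(self):
        # length 1000: position 1499 (offset 499 < 500) -> 5' arm;
        # position 1500 (offset 500) -> 3' arm
        assert anchored_offset(PLUS, 1499, 400, 400, 500)[0] == "5p"
        assert anchored_offset(PLUS, 1500, 400, 400, 500)[0] == "3p"


def constant_track(value, n=200, spacing=100):
    s = np.arange(n, dtype=np.int64) * spacing
    return ct.ProbeTrack("c", {"chr1": (s, s + 60,
                                        np.full(n, float(value)))})


class TestAggregateProfile:
    def setup_method(self):
        self.ann = ct.GeneAnnotation(
            [ct.Gene("g1", "chr1", 2000, 4000, "+"),
             ct.Gene("g2", "chr1", 6000, 9000, "-")],
            {"chr1": 20_000},
        )

    def test_constant_track_gives_constant_profile(self):
        prof = aggregate_profile(constant_track(1.0), self.ann.genes(),
                                 self.ann)
        present = prof.df.dropna(subset=["value"])
        assert not present.empty
        np.testing.assert_array_equal(present["value"], 1.0)

    def test_single_gene_profile_is_its_own_binned_signal(self, rng):
        n = 120
        s = np.arange(n, dtype=np.int64) * 100
        v = rng.normal(0, 1, n)
        track = ct.ProbeTrack("t", {"chr1": (s, s + 60, v)})
        cfg = MetageneConfig()
        prof = aggregate_profile(track, ["g1"], self.ann, cfg)
        # oracle: bin probes of g1 by hand on the 5' arm
        gene = self.ann.get("g1")
        mids = s + 30.0
        for offset in prof.arm("5p")["offset"]:
            sel = (mids >= gene.start + offset) & \
                  (mids < gene.start + offset + cfg.bin_width) & \
                  (mids - gene.start < gene.length / 2) & \
                  (mids - gene.start >= 0 if offset >= 0 else mids < gene.start)
            row = prof.arm("5p").set_index("offset").loc[offset]
            if offset >= 0 and sel.any():
                assert row["value"] == pytest.approx(float(v[sel].mean()))

    def test_gene_order_invariance(self):
        t = constant_track(2.0)
        a = aggregate_profile(t, ["g1", "g2"], self.ann)
        b = aggregate_profile(t, ["g2", "g1"], self.ann)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_identical_genes_aggregate_to_common_profile(self, rng):
        # two identical genes far apart over identical local signal
        ann = ct.GeneAnnotation(
            [ct.Gene("a", "chr1", 2000, 3000, "+"),
             ct.Gene("b", "chr1", 12_000, 13_000, "+")],
            {"chr1": 20_000},
        )
        s1 = np.arange(1000, 4000, 250, dtype=np.int64)
        v = rng.normal(0, 1, s1.size)
        s = np.concatenate([s1, s1 + 10_000])
        track = ct.ProbeTrack("t", {"chr1": (s, s + 60,
                                             np.concatenate([v, v]))})
        for stat in ("mean", "median"):
            cfg = MetageneConfig(stat=stat)
            both = aggregate_profile(track, ["a", "b"], ann, cfg)
            one = aggregate_profile(track, ["a"], ann, cfg)
            merged = both.df.merge(one.df, on=["arm", "offset"],
                                   suffixes=("_both", "_one"))
            np.testing.assert_allclose(
                merged["value_both"], merged["value_one"], atol=1e-12
            )
            assert (merged["n_both"] == 2 * merged["n_one"]).all()

    def test_counts_bounded_and_empty_bins_missing(self, study, ztracks):
        kept = ct.filter_genes(study.genome.annotation)
        prof = aggregate_profile(ztracks["rpd3"], kept.genes(),
                                 study.genome.annotation)
        assert (prof.df["n"] <= len(kept)).all()
        empty = prof.df[prof.df["n"] == 0]
        assert empty["value"].isna().all()

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValidationError, match="empty gene set"):
            aggregate_profile(constant_track(1.0), [], self.ann)


def profile_from(values, arm="5p", bin_width=50, n=None):
    offs = np.arange(len(values)) * bin_width
    df = pd.DataFrame({
        "arm": arm, "offset": offs, "value": values,
        "n": n if n is not None else [0 if math.isnan(v) else 5
                                      for v in values],
    })
    return MetageneProfile(df, bin_width, 5)


class TestSmoothProfile:
    def test_constant_profile_unchanged(self):
        prof = profile_from([2.0] * 20)
        out = smooth_profile(prof, MetageneConfig())
        np.testing.assert_allclose(out.df["value"], 2.0)

    def test_span_equal_to_bin_width_is_identity(self):
        vals = [0.1, -0.5, 2.0, 1.0, float("nan"), 3.0]
        prof = profile_from(vals)
        out = smooth_profile(prof, MetageneConfig(span=50))
        np.testing.assert_array_equal(out.df["value"], prof.df["value"])

    def test_unit_impulse_spreads_to_span_over_bin_bins(self):
        vals = [0.0] * 21
        vals[10] = 1.0
        out = smooth_profile(profile_from(vals), MetageneConfig())
        sm = out.df["value"].to_numpy()
        nonzero = np.nonzero(sm)[0]
        assert len(nonzero) == 6  # span/bin = 300/50
        np.testing.assert_allclose(sm[nonzero], 1.0 / 6.0)

    def test_extrema_within_raw_range(self, study, ztracks):
        kept = ct.filter_genes(study.genome.annotation)
        cfg = MetageneConfig()
        raw = aggregate_profile(ztracks["rco1"], kept.genes(),
                                study.genome.annotation, cfg)
        sm = smooth_profile(raw, cfg)
        assert np.nanmax(sm.df["value"]) <= np.nanmax(raw.df["value"]) + 1e-12
        assert np.nanmin(sm.df["value"]) >= np.nanmin(raw.df["value"]) - 1e-12

    def test_counts_propagate_as_window_minimum(self):
        prof = profile_from([1.0] * 8, n=[5, 4, 3, 2, 1, 2, 3, 4])
        out = smooth_profile(prof, MetageneConfig(span=150))  # 3-bin window
        assert out.df["n"].tolist() == [4, 3, 2, 1, 1, 1, 2, 3]


class TestPlantedShapes:
    def test_ramp_genes_peak_in_3prime_arm_inside_gene(self, study, ztracks):
        ramp_ids = [
            g for g, a in study.genome.archetype_ids.items()
            if a == "orf_ramp" and study.genome.annotation.get(g).length >= 500
        ]
        cfg = MetageneConfig()
        prof = smooth_profile(
            aggregate_profile(ztracks["rco1"], ramp_ids,
                              study.genome.annotation, cfg),
            cfg,
        )
        best = prof.df.loc[prof.df["value"].idxmax()]
        assert best["arm"] == "3p" and best["offset"] < 0

    def test_promoter_only_vs_orf_bound_contrast(self, study, ztracks):
        """Promoter-bound genes: promoter arm >> ORF bins; ORF-bound genes
        show the converse (the large-complex vs small-complex contrast)."""
        ann = study.genome.annotation
        ids_by_arch = lambda a: [
            g for g, x in study.genome.archetype_ids.items()
            if x == a and ann.get(g).length >= 500
        ]
        cfg = MetageneConfig()

        def arm_means(track, ids):
            prof = smooth_profile(
                aggregate_profile(track, ids, ann, cfg), cfg
            )
            df = prof.df
            prom = df[(df["arm"] == "5p") & (df["offset"] < 0)]["value"]
            orf = df[((df["arm"] == "5p") & (df["offset"] >= 0))
                     | ((df["arm"] == "3p") & (df["offset"] < 0))]["value"]
            return float(np.nanmean(prom)), float(np.nanmean(orf))

        prom_mean, orf_mean = arm_means(ztracks["rpd3"],
                                        ids_by_arch("promoter_only"))
        assert prom_mean > orf_mean + 0.5
        prom2, orf2 = arm_means(ztracks["rco1"], ids_by_arch("promoter_orf"))
        assert orf2 > prom2 + 0.5


class TestMetageneConfig:
    def test_invariants(self):
        with pytest.raises(ValidationError):
            MetageneConfig(span=70)  # not a multiple of 50
        with pytest.raises(ValidationError):
            MetageneConfig(bin_width=0)
        with pytest.raises(ValidationError):
            MetageneConfig(stat="mode")
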