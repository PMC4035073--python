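import numpy as np
import pandas as pd
import pytest

import introscan as sc
from introscan.ancestry import (
    INDICA_SKEWED,
    JAPONICA_SKEWED,
    NEUTRAL,
    call_skewed_regions,
    window_summary,
)

from conftest import geno_from_rows


def parents_panel(n_po=10, n_pd=10, n_hy=10):
    ids = (
        [f"po{i}" for i in range(n_po)]
        + [f"pd{i}" for i in range(n_pd)]
        + [f"hy{i}" for i in range(n_hy)]
    )
    groups = (
        {f"po{i}": sc.Group.PO_INDICA for i in range(n_po)}
        | {f"pd{i}": sc.Group.PD for i in range(n_pd)}
        | {f"hy{i}": sc.Group.HY for i in range(n_hy)}
    )
    return ids, sc.PopulationPanel(groups)


class TestDiscriminatingSNPs:
    def test_threshold_is_strict_and_allele_oriented(self):
        n = 20  # 20 per group
        ids, panel = parents_panel(20, 20, 20)
        # m0: PD ref-freq 0.95 vs PO 0.10 -> diff 0.85, indica allele = ref? no:
        #   PO major allele is alt (alt freq 0.9) -> indica allele = alt
        # m1: diff exactly 0.70 -> excluded
        rows = []
        for i in range(20):  # PO-indica
            rows.append(("A" if i < 18 else "R") + ("A" if i < 14 else "R"))
        for i in range(20):  # PD
            rows.append(("A" if i < 1 else "R") + ("R" * 1 if i < 20 else "A"))
        for i in range(20):  # HY
            rows.append("AR")
        g = geno_from_rows(rows, cultivar_ids=ids)
        disc = sc.find_discriminating_snps(g, panel, threshold=0.7)
        assert list(disc["marker_id"]) == ["m0"]
        row = disc.iloc[0]
        assert row.indica_allele == "G"  # alt symbol
        assert row.maf_diff == pytest.approx(0.85)
        assert row.freq_po_indica == pytest.approx(0.9)
        assert row.freq_pd == pytest.approx(0.05)

    def test_matches_brute_force_oracle_on_synthetic_parents(self, default_bundle):
        g, panel = default_bundle.geno, default_bundle.panel
        disc = set(sc.find_discriminating_snps(g, panel, 0.7)["marker_id"])
        po, pd_, hy = (
            panel.members(sc.Group.PO_INDICA),
            panel.members(sc.Group.PD),
            panel.members(sc.Group.HY),
        )
        for j, mid in enumerate(g.markers.marker_ids[:300]):
            freqs = []
            for members in (po, pd_, hy):
                f = sc.allele_frequency(g, members, mid)
                freqs.append(None if f is None else f[g.alleles[j][1]])
            if any(f is None for f in freqs):
                assert mid not in disc
            else:
                assert (mid in disc) == (abs(freqs[1] - freqs[0]) > 0.7)


class TestAdjustedHY:
    @pytest.mark.parametrize(
        "hy,pd_,po,expect",
        [(1.0, 0.0, 1.0, 1.0), (0.0, 0.0, 1.0, 0.0), (0.5, 0.1, 0.9, 0.3)],
    )
    def test_arithmetic(self, hy, pd_, po, expect):
        assert sc.adjusted_hy_frequency(hy, pd_, po) == pytest.approx(expect)

    def test_pool_swap_with_allele_relabel_reflects_statistic(self, rng):
        # with fully diverged parents (PO=1, PD=0 for the indica allele),
        # tracking the japonica allele with the pools' roles swapped gives
        # 1 - adjusted_hy: the statistic reflects about the band midpoint,
        # so indica- and japonica-skew calls exchange
        hy = rng.random(50)
        fwd = sc.adjusted_hy_frequency(hy, 0.0, 1.0)
        swapped = sc.adjusted_hy_frequency(1.0 - hy, 0.0, 1.0)
        assert np.allclose(swapped, 1.0 - fwd, atol=1e-12)


class TestWindows:
    def make_disc(self, values, chrom="chr1"):
        return pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(len(values))],
                "chromosome": chrom,
                "position_bp": np.arange(1, len(values) + 1) * 1000,
                "adjusted_hy": values,
            }
        )

    def test_identical_values_collapse_quantiles(self):
        w, _ = window_summary(self.make_disc([0.4] * 5), window=5)
        row = w.iloc[0]
        assert row["median"] == row.q25 == row.q75 == 0.4
        assert not row.partial

    def test_known_median_and_partial_flag(self):
        w, marker_window = window_summary(
            self.make_disc([0.1, 0.2, 0.3, 0.4, 0.5, 0.9, 1.0]), window=5
        )
        assert w.iloc[0]["median"] == pytest.approx(0.3)
        assert bool(w.iloc[1]["partial"]) and w.iloc[1]["n_snps"] == 2
        assert list(marker_window) == [0, 0, 0, 0, 0, 1, 1]

    def test_quantiles_match_sorted_interpolation_oracle(self, rng):
        vals = rng.random(25)
        w, _ = window_summary(self.make_disc(vals), window=5)
        for i in range(5):
            chunk = np.sort(vals[i * 5 : (i + 1) * 5])
            # for 5 points the interpolated quantiles land on order statistics:
            # index 0.25*(5-1)=1, 0.5*(5-1)=2, 0.75*(5-1)=3
            assert w.iloc[i].q25 == pytest.approx(chunk[1])
            assert w.iloc[i]["median"] == pytest.approx(chunk[2])
            assert w.iloc[i].q75 == pytest.approx(chunk[3])

    def test_invariant_q25_le_median_le_q75(self, default_bundle):
        prof = sc.ancestry_profile(default_bundle.geno, default_bundle.panel)
        w = prof.windows
        assert (w.q25 <= w["median"] + 1e-12).all()
        assert (w["median"] <= w.q75 + 1e-12).all()


class TestSkewCalls:
    def windows_from_medians(self, medians, chrom="chr1"):
        return pd.DataFrame(
            {
                "window_id": range(len(medians)),
                "chromosome": chrom,
                "start_bp": np.arange(len(medians)) * 10_000 + 1,
                "end_bp": np.arange(len(medians)) * 10_000 + 5_000,
                "n_snps": 5,
                "median": medians,
                "q25": medians,
                "q75": medians,
                "partial": False,
            }
        )

    def test_degenerate_band_is_all_neutral(self):
        w, iv, band = call_skewed_regions(self.windows_from_medians([0.3] * 6))
        assert (w["skew_class"] == NEUTRAL).all()
        assert iv.empty

    def test_single_outlier_window_called_indica(self):
        w, iv, _ = call_skewed_regions(
            self.windows_from_medians([0.0, 0.01, -0.01, 0.0, 1.0, 0.0])
        )
        assert w.loc[4, "skew_class"] == INDICA_SKEWED

    def test_calls_invariant_to_constant_shift(self, rng):
        medians = rng.random(30)
        w1, _, _ = call_skewed_regions(self.windows_from_medians(medians))
        w2, _, _ = call_skewed_regions(self.windows_from_medians(medians + 5.0))
        assert list(w1["skew_class"]) == list(w2["skew_class"])

    def test_adjacent_same_class_windows_merge(self):
        w, iv, _ = call_skewed_regions(
            self.windows_from_medians([0.0, 0.9, 0.95, 0.0, -0.9, 0.02, 0.0, 0.01])
        )
        ind = iv[iv["skew_class"] == INDICA_SKEWED]
        assert len(ind) == 1 and ind.iloc[0].n_windows == 2
        assert ind.iloc[0].start_bp == 10_001 and ind.iloc[0].end_bp == 25_000

    def test_planted_regions_all_overlapped(self, default_bundle):
        prof = sc.ancestry_profile(default_bundle.geno, default_bundle.panel)
        iv = prof.intervals
        for region in default_bundle.truth.skew_regions:
            hit = (
                (iv["chromosome"] == region.chromosome)
                & (iv["start_bp"] <= region.end_bp)
                & (iv["end_bp"] >= region.start_bp)
                & (iv["skew_class"] == INDICA_SKEWED)
            )
            assert hit.any(), region


class TestGenomeTypes:
    def test_pure_and_mixed_classifications(self):
        ids, panel = parents_panel(4, 4, 3)
        # 10 discriminating markers; hy0 = all indica, hy1 = all japonica,
        # hy2 = half and half
        rows = []
        for _ in range(4):
            rows.append("A" * 10)  # PO-indica parents, alt = indica allele
        for _ in range(4):
            rows.append("R" * 10)
        rows.append("A" * 10)
        rows.append("R" * 10)
        rows.append("A" * 5 + "R" * 5)
        g = geno_from_rows(rows, cultivar_ids=ids)
        disc = sc.find_discriminating_snps(g, panel)
        calls = sc.classify_genome_types(g, disc, ["hy0", "hy1", "hy2"])
        as_dict = calls.set_index("cultivar_id")
        assert as_dict.loc["hy0"].genome_type == "IN"
        assert as_dict.loc["hy0"].indica_fraction == 1.0
        assert as_dict.loc["hy1"].genome_type == "JA"
        assert as_dict.loc["hy2"].genome_type == "MX"
        assert as_dict.loc["hy2"].indica_fraction == 0.5

    def test_mosaic_fractions_match_truth_tracks(self, default_bundle, hy_cultivars):
        b = default_bundle
        prof = sc.ancestry_profile(b.geno, b.panel)
        calls = sc.classify_genome_types(b.geno, prof.discriminating, hy_cultivars)
        tracks = b.truth.origin_tracks.loc[
            hy_cultivars, prof.discriminating["marker_id"]
        ]
        true_frac = tracks.mean(axis=1).to_numpy()
        est = calls.set_index("cultivar_id").loc[hy_cultivars, "indica_fraction"]
        # small discrepancy from het/missing noise and partial-divergence copy noise
        assert np.abs(est.to_numpy() - true_frac).mean() < 0.05
        assert len(calls) == len(hy_cultivars)

    def test_graphical_genotype_tracks(self):
        ids, panel = parents_panel(2, 2, 1)
        rows = ["AA", "AA", "RR", "RR", "AH"]
        g = geno_from_rows(rows, cultivar_ids=ids)
        disc = sc.find_discriminating_snps(g, panel)
        gg = sc.graphical_genotypes(g, disc, ["hy0"])
        assert list(gg.loc["hy0"]) == ["I", "H"]
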