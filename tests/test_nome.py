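"""Methylation tables, the chi-squared LNDR caller, regions and profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from nucsteric.nome import (
    METH_COLUMNS,
    aggregate_profile,
    complement_hndr,
    define_regions,
    detect_lndr,
    filter_coverage,
    ndr_boundary_histogram,
    read_annotation,
    read_methylation,
    write_methylation,
)
from nucsteric.simulate import write_gtf


def _meth_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "strand", "context", "n_meth", "n_total"])
    df["end"] = df["start"] + 1
    return df[METH_COLUMNS]


class TestMethylationIO:
    def test_read_recomputes_level(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_methylation(
            _meth_df([("chr1", 10, "+", "HCG", 3, 4), ("chr1", 5, "-", "GCH", 0, 6)]),
            path,
        )
        df = read_methylation(path)
        # sorted by position, level from counts
        assert df["start"].tolist() == [5, 10]
        assert df.loc[1, "level"] == 75.0

    def test_context_filter(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_methylation(
            _meth_df([("chr1", 1, "+", "HCG", 1, 2), ("chr1", 2, "+", "GCH", 1, 2)]),
            path,
        )
        assert read_methylation(path, context="GCH")["context"].tolist() == ["GCH"]

    def test_malformed_counts_reported_with_row(self, tmp_path):
        path = tmp_path / "m.tsv"
        write_methylation(_meth_df([("chr1", 1, "+", "HCG", 5, 2)]), path)
        with pytest.raises(ValueError, match="row 1"):
            read_methylation(path)

    def test_generator_output_round_trips(self, tmp_path, sim_bundle):
        path = tmp_path / "gch.tsv"
        write_methylation(sim_bundle["gch"], path)
        back = read_methylation(path, context="GCH")
        pd.testing.assert_frame_equal(
            back[METH_COLUMNS].reset_index(drop=True),
            sim_bundle["gch"][METH_COLUMNS].reset_index(drop=True),
        )


class TestCoverageFilter:
    def test_threshold_is_strict(self):
        df = _meth_df(
            [("chr1", 1, "+", "GCH", 2, 4), ("chr1", 2, "+", "GCH", 2, 3)]
        )
        kept = filter_coverage(df, min_reads=3)
        assert kept["start"].tolist() == [1]  # coverage 4 kept, coverage 3 removed

    def test_matches_direct_recount(self):
        rng = np.random.default_rng(0)
        cov = rng.poisson(6, size=1000)
        df = _meth_df(
            [("chr1", i, "+", "GCH", 0, int(c)) for i, c in enumerate(cov)]
        )
        df = df[df["n_total"] > 0]
        kept = filter_coverage(df, 3)
        assert len(kept) == int(np.count_nonzero(df["n_total"] > 3))


def _site_block(start, n, spacing, level, cov=20, chrom="chr1"):
    rows = []
    for k in range(n):
        pos = start + k * spacing
        rows.append((chrom, pos, "+", "GCH", int(round(cov * level / 100)), cov))
    return rows


class TestDetectLndr:
    def test_enriched_window_called_and_chi2_matches_oracle(self):
        """A block of fully methylated GCHs over a lowly methylated genome
        must be significant; the window p-value is cross-checked against
        scipy's contingency-table test without continuity correction."""
        rows = _site_block(0, 500, 20, 10)  # background ~10% over 10 kb
        rows += _site_block(4000, 10, 20, 100)  # 200-bp hot block
        sites = _meth_df(rows).sort_values("start").reset_index(drop=True)
        sites = sites.assign(
            n_unmeth=sites.n_total - sites.n_meth,
            level=100.0 * sites.n_meth / sites.n_total,
        )
        calls, qc = detect_lndr(sites, {"chr1": 10_200})
        assert len(calls) == 1
        call = calls.iloc[0]
        assert call["start"] <= 4000 and call["end"] >= 4180

        # oracle: rebuild the fully-covered window's 2x2 table by hand
        w = sites[(sites.start >= 4000) & (sites.start < 4200)]
        a, b = w.n_meth.sum(), (w.n_total - w.n_meth).sum()
        c, d = sites.n_meth.sum(), (sites.n_total - sites.n_meth).sum()
        stat, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
        assert p < 1e-5
        assert call["p_value"] <= p * 1.0000001

    def test_background_proportion_not_significant(self):
        rows = _site_block(0, 500, 20, 30)
        sites = _meth_df(rows)
        sites = sites.assign(
            n_unmeth=sites.n_total - sites.n_meth,
            level=100.0 * sites.n_meth / sites.n_total,
        )
        calls, _ = detect_lndr(sites, {"chr1": 10_000})
        assert len(calls) == 0

    def test_depleted_window_not_called(self):
        """Significance requires the window level ABOVE background: a
        depleted window (opposite direction) must not become an LNDR."""
        rows = _site_block(0, 500, 20, 50)
        rows += _site_block(4000, 10, 20, 0)
        sites = _meth_df(rows).sort_values("start").reset_index(drop=True)
        sites = sites.assign(
            n_unmeth=sites.n_total - sites.n_meth,
            level=100.0 * sites.n_meth / sites.n_total,
        )
        calls, _ = detect_lndr(sites, {"chr1": 10_200})
        assert not ((calls["start"] < 4200) & (calls["end"] > 4000)).any()

    def test_low_coverage_windows_skipped_and_qc_counted(self):
        rows = [("chr1", 100, "+", "GCH", 2, 2)]  # 2 reads < min 5
        sites = _meth_df(rows).assign(n_unmeth=0, level=100.0)
        # isolated site cannot form a background by itself vs the rest
        sites2 = pd.concat(
            [sites, _meth_df(_site_block(5000, 100, 20, 10)).assign(
                n_unmeth=lambda d: d.n_total - d.n_meth,
                level=lambda d: 100.0 * d.n_meth / d.n_total)],
            ignore_index=True,
        ).sort_values("start").reset_index(drop=True)
        calls, qc = detect_lndr(sites2, {"chr1": 10_000})
        assert qc["n_skipped_low_reads"] > 0
        assert not ((calls["start"] <= 100) & (calls["end"] > 100)).any()

    def test_significance_monotone_in_methylated_reads(self):
        """Adding methylated observations to a positively significant
        window must not lose significance (holding background fixed)."""
        from nucsteric.nome import _chi2_2x2
        from scipy.stats import chi2 as chi2_dist

        bg_m, bg_u = 1000.0, 9000.0
        base_m, base_u = 40.0, 10.0
        p_prev = chi2_dist.sf(_chi2_2x2(np.array([base_m]), np.array([base_u]), bg_m, bg_u), 1)[0]
        for extra in range(1, 50, 5):
            p = chi2_dist.sf(
                _chi2_2x2(np.array([base_m + extra]), np.array([base_u]), bg_m, bg_u), 1
            )[0]
            assert p <= p_prev * 1.0000001
            p_prev = p


class TestComplementHndr:
    def test_partition_conservation(self, sim_bundle):
        lndrs, hndrs = sim_bundle["lndrs"], sim_bundle["hndrs"]
        size = sim_bundle["sizes"]["chrS"]
        covered = int((lndrs.end - lndrs.start).sum() + (hndrs.end - hndrs.start).sum())
        assert covered == size
        both = pd.concat([lndrs[["start", "end"]], hndrs[["start", "end"]]])
        both = both.sort_values("start")
        assert (both["start"].iloc[1:].to_numpy() >= both["end"].iloc[:-1].to_numpy()).all()

    def test_no_lndrs_whole_chromosome(self):
        hndrs = complement_hndr(pd.DataFrame(columns=["chrom", "start", "end"]), {"c": 1000})
        assert hndrs[["start", "end"]].values.tolist() == [[0, 1000]]


class TestRegions:
    def test_plus_strand_promoter_arithmetic(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c", "strand": "+", "start": 10_000,
              "end": 12_000, "exons": [(10_000, 12_000)]}]
        )
        regions = define_regions(genes)
        prom = regions[regions.region_class == "promoter_tss"].iloc[0]
        assert (prom.start, prom.end) == (8000, 11001)

    def test_minus_strand_promoter_mirrored(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c", "strand": "-", "start": 8_000,
              "end": 10_001, "exons": [(8_000, 10_001)]}]
        )
        regions = define_regions(genes)
        prom = regions[regions.region_class == "promoter_tss"].iloc[0]
        # TSS at 10000; -2000..+1000 transcription-oriented
        assert (prom.start, prom.end) == (9000, 12001)

    def test_two_exon_gene_lacks_intron2(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c", "strand": "+", "start": 0,
              "end": 20_000, "exons": [(0, 100), (10_000, 10_100)]}]
        )
        kinds = set(define_regions(genes)["region_class"])
        assert kinds == {"promoter_tss", "intron1_start", "intron1_end"}

    def test_intronless_gene_promoter_only(self):
        genes = pd.DataFrame(
            [{"gene_id": "g", "chrom": "c", "strand": "+", "start": 0,
              "end": 5000, "exons": [(0, 5000)]}]
        )
        assert define_regions(genes)["region_class"].tolist() == ["promoter_tss"]

    def test_window_length_and_count(self, sim_bundle):
        regions = sim_bundle["regions"]
        assert len(regions) == 4 * len(sim_bundle["genes"])
        assert ((regions.end - regions.start) == 3001).all()

    def test_gtf_round_trip_through_gffutils(self, tmp_path, sim_bundle):
        path = tmp_path / "ann.gtf"
        write_gtf(sim_bundle["genes"], path)
        back = read_annotation(path)
        assert len(back) == len(sim_bundle["genes"])
        orig = sim_bundle["genes"].sort_values("gene_id").reset_index(drop=True)
        back = back.sort_values("gene_id").reset_index(drop=True)
        assert back["start"].tolist() == orig["start"].tolist()
        assert [list(map(tuple, e)) for e in back["exons"]] == [
            list(map(tuple, e)) for e in orig["exons"]
        ]


class TestProfilesAndHistograms:
    def _region(self, anchor=5000, strand="+"):
        start = anchor - 2000 if strand == "+" else anchor - 1000
        end = anchor + 1001 if strand == "+" else anchor + 2001
        return pd.DataFrame(
            [{"chrom": "c", "start": start, "end": end, "region_class": "promoter_tss",
              "gene_id": "g", "strand": strand, "anchor_pos": anchor, "clipped": False}]
        )

    def test_single_site_at_anchor(self):
        sites = pd.DataFrame(
            [{"chrom": "c", "start": 5000, "end": 5001, "level": 40.0}]
        )
        prof = aggregate_profile(sites, self._region(), value="100_minus_level")
        at0 = prof[prof.rel_pos == 0]
        assert at0["mean_100_minus_level"].iloc[0] == 60.0
        assert at0["n_sites"].iloc[0] == 1

    def test_empty_positions_are_nan(self):
        sites = pd.DataFrame(
            [{"chrom": "c", "start": 5000, "end": 5001, "level": 40.0}]
        )
        prof = aggregate_profile(sites, self._region())
        assert prof[prof.rel_pos == 5]["mean_level"].isna().all()

    def test_minus_strand_orientation(self):
        sites = pd.DataFrame(
            [{"chrom": "c", "start": 4900, "end": 4901, "level": 10.0}]
        )
        prof = aggregate_profile(sites, self._region(strand="-"))
        assert prof[prof.rel_pos == 100]["n_sites"].iloc[0] == 1

    def test_planted_ndr_dip_visible(self, sim_bundle):
        """The 100-minus-GpC curve dips inside the planted span
        (accessible DNA is heavily GpC methylated)."""
        regions = sim_bundle["regions"]
        expressed = set(sim_bundle["tpm"].loc[sim_bundle["tpm"].tpm > 0, "gene_id"])
        prom = regions[
            (regions.region_class == "promoter_tss") & regions.gene_id.isin(expressed)
        ]
        prof = aggregate_profile(sim_bundle["gch"], prom, value="100_minus_level")
        inside = prof[(prof.rel_pos >= -180) & (prof.rel_pos < 80)]["mean_100_minus_level"]
        outside = prof[(prof.rel_pos >= -1500) & (prof.rel_pos < -500)]["mean_100_minus_level"]
        assert inside.mean() < outside.mean() - 20

    def test_boundary_histogram_single_ndr(self):
        ndrs = pd.DataFrame([{"chrom": "c", "start": 4800, "end": 5100}])
        hist = ndr_boundary_histogram(ndrs, self._region())
        assert hist[hist.rel_pos == -200]["n_starts"].iloc[0] == 1
        assert hist[hist.rel_pos != -200]["n_starts"].sum() == 0
        assert hist[hist.rel_pos == 99]["n_ends"].iloc[0] == 1

    def test_planted_lndr_boundary_mode(self, sim_bundle):
        """Called LNDR start positions concentrate near the planted
        -200 bp edge (within the caller's window resolution)."""
        regions = sim_bundle["regions"]
        expressed = set(sim_bundle["tpm"].loc[sim_bundle["tpm"].tpm > 0, "gene_id"])
        prom = regions[
            (regions.region_class == "promoter_tss") & regions.gene_id.isin(expressed)
        ]
        hist = ndr_boundary_histogram(sim_bundle["lndrs"], prom)
        mode = hist.loc[hist.n_starts.idxmax(), "rel_pos"]
        assert -400 <= mode <= -150
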