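import numpy as np
import pandas as pd
import pytest

from varscape.datasources import DEFAULT_SCORE_REGISTRY, PopulationCount
from varscape.genemodel import GenomicInterval, TranscriptModel, scale_exon_layout
from varscape.groupstats import GroupedScores, compare_groups
from varscape.scoremodel import PositionScoreSet, fit_profile
from varscape.vizexport import (
    PlotCapacityError,
    ProteinFeature,
    SelectedVariant,
    build_af_hist,
    build_clinvar_density,
    build_protein_plot,
    build_score_model,
    build_utp,
    build_violins,
    export_plot,
    export_table,
    read_protein_features,
)
from varscape.datasources import ClinVarRecord


def _two_exon_transcript():
    e1 = GenomicInterval("chr1", 101, 200, "+")
    e2 = GenomicInterval("chr1", 501, 600, "+")
    return TranscriptModel("TX", "G", exons=[e1, e2],
                           cds=[GenomicInterval("chr1", 110, 190, "+")])


def _clinvar(pos, sig="pathogenic"):
    return ClinVarRecord("chr1", pos, "A", "G", "missense", sig)


class TestUtp:
    def test_bare_structure_renders(self):
        t = _two_exon_transcript()
        fig = build_utp(t, scale_exon_layout(t))
        assert fig._varscape_n_lollipops == 0

    def test_intronic_lollipop_lands_in_intron_segment(self):
        t = _two_exon_transcript()
        layout = scale_exon_layout(t, 0.2)
        fig = build_utp(t, layout, lollipops=[_clinvar(350)])
        assert fig._varscape_n_lollipops == 1
        intron = next(s for s in layout.segments if s.kind == "intron")
        x = layout.to_plot(350)
        assert intron.x0 <= x <= intron.x1

    def test_out_of_span_variant_skipped(self, caplog):
        t = _two_exon_transcript()
        with caplog.at_level("WARNING"):
            fig = build_utp(t, scale_exon_layout(t), lollipops=[_clinvar(9000)])
        assert fig._varscape_n_lollipops == 0

    def test_lollipop_count_conserved(self):
        t = _two_exon_transcript()
        recs = [_clinvar(p) for p in (120, 150, 350, 550)]
        fig = build_utp(t, scale_exon_layout(t), lollipops=recs)
        assert fig._varscape_n_lollipops == len(recs)


class TestProteinPlot:
    def test_backbone_only(self):
        fig = build_protein_plot([], length=100)
        assert fig._varscape_n_lanes == 0

    def test_overlapping_domains_use_separate_lanes(self):
        feats = [ProteinFeature("domain", "A", 10, 60),
                 ProteinFeature("region", "B", 50, 90)]
        fig = build_protein_plot(feats, length=100)
        assert fig._varscape_n_lanes == 2

    def test_marker_positions_equal_selection(self):
        sel = [SelectedVariant(0, 12, "p.A12G"),
               SelectedVariant(0, 80, "p.R80W", source="simulated")]
        fig = build_protein_plot([], 100, selected=sel)
        assert fig._varscape_marker_positions == [12, 80]

    def test_feature_beyond_length_clipped(self, caplog):
        with caplog.at_level("WARNING"):
            build_protein_plot([ProteinFeature("domain", "X", 90, 140)], 100)
        assert "clipped" in caplog.text

    def test_reader_round_trip(self, bundle_plus):
        feats = read_protein_features(bundle_plus["features"])
        assert len(feats) == 3
        assert all(f.start <= f.end for f in feats)


class TestDensity:
    def test_planted_cluster_mode_recovered(self):
        rng = np.random.default_rng(12)
        plp = rng.integers(260, 281, size=30)       # hotspot AA 260-280
        blb = rng.integers(1, 413, size=40)
        fig = build_clinvar_density(list(plp), list(blb), 412)
        assert 260 <= fig._varscape_density_modes["P/LP"] <= 280

    def test_single_variant_group_rug_only(self, caplog):
        with caplog.at_level("WARNING"):
            fig = build_clinvar_density([100, 120, 140], [50], 200)
        assert "B/LB" not in fig._varscape_density_modes
        assert "P/LP" in fig._varscape_density_modes

    def test_curves_integrate_to_one(self):
        rng = np.random.default_rng(13)
        fig = build_clinvar_density(list(rng.integers(50, 150, 25)),
                                    list(rng.integers(1, 200, 25)), 200)
        ax = fig.axes[0]
        for line in ax.lines[:2]:
            x, y = line.get_data()
            if len(x) > 2:          # density curves, not rug lines
                assert np.trapezoid(y, x) == pytest.approx(1.0, abs=1e-2)


class TestAfHist:
    def _pop(self, pos, af, ds):
        an = 100000
        return PopulationCount("chr1", pos, "A", "G", ds,
                               ac=max(1, int(af * an)), an=an)

    def test_bar_counts_match_records(self):
        ex = [self._pop(p, 1e-3, "exomes") for p in (10, 20, 30)]
        ge = [self._pop(p, 1e-4, "genomes") for p in (15, 25)]
        fig = build_af_hist(ex, ge)
        assert fig.axes[0]._varscape_n_bars == 3
        assert fig.axes[1]._varscape_n_bars == 2

    def test_empty_genomes_panel_ok(self):
        fig = build_af_hist([self._pop(10, 1e-3, "exomes")], [])
        assert fig.axes[1]._varscape_n_bars == 0

    def test_log_axis_monotone_in_af(self):
        ex = [self._pop(10, 1e-3, "exomes"), self._pop(20, 1e-4, "exomes")]
        fig = build_af_hist(ex, [])
        bars = fig.axes[0].patches
        assert bars[0].get_height() > bars[1].get_height()


@pytest.fixture(scope="module")
def profiles():
    rng = np.random.default_rng(21)
    out = []
    for name in ("REVEL_score", "CADD_phred", "SIFT_score"):
        pos = rng.integers(1, 101, 600)
        y = 0.5 + 0.2 * np.sin(pos / 10) + rng.normal(0, 0.05, 600)
        out.append(fit_profile(PositionScoreSet(name, list(zip(pos, y))),
                               protein_length=100))
    return out


class TestScoreModel:
    def test_three_profiles_three_panel_pairs(self, profiles):
        fig = build_score_model(profiles, DEFAULT_SCORE_REGISTRY)
        assert len(fig.axes) == 6        # curve + strip per score

    def test_fourth_profile_rejected(self, profiles):
        with pytest.raises(PlotCapacityError, match="3"):
            build_score_model(profiles + profiles[:1])

    def test_heat_strip_columns_equal_protein_length(self, profiles):
        fig = build_score_model(profiles[:1], DEFAULT_SCORE_REGISTRY)
        strip_ax = fig.axes[1]
        img = strip_ax.get_images()[0]
        assert img.get_array().shape == (1, 100)

    def test_shared_position_axis(self, profiles):
        fig = build_score_model(profiles[:2], DEFAULT_SCORE_REGISTRY)
        xlims = {ax.get_xlim() for ax in fig.axes}
        assert len(xlims) == 1


class TestViolins:
    def _grouped(self, shift=0.0):
        rng = np.random.default_rng(30)
        gs = GroupedScores("REVEL_score")
        gs.groups["ClinVar_pathogenic"] = list(rng.normal(0.7 + shift, 0.1, 30))
        gs.groups["ClinVar_benign"] = list(rng.normal(0.3, 0.1, 30))
        gs.groups["gnomAD"] = list(rng.normal(0.35, 0.15, 50))
        gs.groups["InSilico"] = list(rng.normal(0.5, 0.2, 200))
        return gs

    def test_quartile_lines_match_oracle(self):
        gs = self._grouped()
        fig = build_violins(compare_groups(gs), gs)
        for g, (q1, q2, q3) in fig._varscape_quartiles.items():
            expected = np.percentile(gs.groups[g], [25, 50, 75])
            assert (q1, q2, q3) == pytest.approx(tuple(expected))

    def test_separated_groups_show_triple_star(self):
        gs = self._grouped()
        tests = compare_groups(gs)
        pb = next(t for t in tests if t.group_a == "ClinVar_pathogenic"
                  and t.group_b == "ClinVar_benign")
        assert pb.stars == "***"
        texts = [t.get_text() for ax in build_violins(tests, gs).axes
                 for t in ax.texts]
        assert "***" in texts

    def test_identical_groups_draw_no_stars(self):
        rng = np.random.default_rng(31)
        v = list(rng.normal(0.5, 0.1, 40))
        gs = GroupedScores("REVEL_score")
        for g in gs.groups:
            gs.groups[g] = list(v)
        fig = build_violins(compare_groups(gs), gs)
        star_texts = [t.get_text() for ax in fig.axes for t in ax.texts
                      if "*" in t.get_text()]
        assert star_texts == []


class TestExport:
    def test_svg_and_png_signatures(self, tmp_path, profiles):
        fig = build_score_model(profiles[:1])
        svg = export_plot(fig, tmp_path / "f.svg")
        png = export_plot(fig, tmp_path / "f.png")
        head_svg = open(svg, "rb").read(200)
        assert head_svg.startswith(b"<?xml") and b"<svg" in head_svg
        assert open(png, "rb").read(8) == b"\x89PNG\r\n\x1a\n"

    def test_dimensions_in_svg_metadata(self, tmp_path, profiles):
        fig = build_score_model(profiles[:1])
        svg = export_plot(fig, tmp_path / "s.svg", width=10, height=5)
        text = open(svg).read(2000)
        assert 'width="720pt"' in text and 'height="360pt"' in text

    def test_unknown_format_rejected(self, tmp_path, profiles):
        with pytest.raises(ValueError):
            export_plot(build_score_model(profiles[:1]), tmp_path / "f.pdf")

    def test_identical_inputs_byte_identical_svg(self, tmp_path):
        rng = np.random.default_rng(40)
        pos, y = rng.integers(1, 51, 200), rng.random(200)
        def render(path):
            prof = fit_profile(PositionScoreSet("REVEL_score",
                                                list(zip(pos, y))), 50)
            return open(export_plot(build_score_model([prof]), path), "rb").read()
        assert render(tmp_path / "a.svg") == render(tmp_path / "b.svg")

    def test_table_round_trip_csv_and_xlsx(self, tmp_path):
        df = pd.DataFrame({"chrom": ["chr1"] * 27, "pos": range(27),
                           "REVEL_score": np.linspace(0, 1, 27)})
        for fmt, reader in (("csv", pd.read_csv), ("xlsx", pd.read_excel)):
            p = export_table(df, tmp_path / f"t.{fmt}", fmt)
            back = reader(p)
            assert len(back) == 27
            assert np.allclose(back["REVEL_score"], df["REVEL_score"])

    def test_damaging_tag_by_cutoff_and_orientation(self, tmp_path):
        df = pd.DataFrame({"REVEL_score": [0.93, 0.1, np.nan],
                           "SIFT_score": [0.01, 0.9, 0.05]})
        p = export_table(df, tmp_path / "t.csv", "csv",
                         registry=DEFAULT_SCORE_REGISTRY)
        back = pd.read_csv(p)
        assert list(back["REVEL_score_class"][:2]) == ["damaging", "tolerated"]
        assert list(back["SIFT_score_class"]) == ["damaging", "tolerated",
                                                  "damaging"]

    def test_empty_table_header_only(self, tmp_path):
        p = export_table(pd.DataFrame(columns=["a", "b"]), tmp_path / "e.csv")
        lines = open(p).read().strip().splitlines()
        assert lines == ["a,b"]

    def test_unknown_table_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_table(pd.DataFrame({"a": [1]}), tmp_path / "t.parquet")
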