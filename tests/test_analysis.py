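"""Summaries, heatmaps, chirality reports, and the CLI surface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from khovlap import chirality_report, fixtures, full_summary, heatmap_table, mirror
from khovlap.analysis import _HARMONIC_ONLY
from khovlap.cli import main
from khovlap.spectral import spectrum_table


class TestFullSummary:
    def test_trefoil_bins_match_nonempty_chain_groups(self, trefoil, trefoil_cx):
        summary = full_summary(trefoil, "trefoil_R", cx=trefoil_cx)
        assert set(summary.spectra.entries) == set(trefoil_cx.gradings)
        assert (0, 3) in summary.spectra.entries and (1, 5) in summary.spectra.entries

    def test_unknot_has_two_bins(self, unknot):
        summary = full_summary(unknot, "unknot")
        assert len(summary.spectra.entries) == 2

    def test_json_roundtrip_is_stable(self, trefoil):
        s1 = full_summary(trefoil, "t").to_json()
        s2 = full_summary(trefoil, "t").to_json()
        assert s1 == s2
        payload = json.loads(s1)
        assert payload["spectra"]["0,3"]["eigenvalues"] == ["0", "6"]
        assert payload["spectra"]["0,3"]["betti"] == 1
        assert payload["jones_normalized"] == {"2": 1, "6": 1, "8": -1}

    def test_csv_export_has_all_eigenvalues(self, trefoil, trefoil_cx):
        csv = full_summary(trefoil, "t", cx=trefoil_cx).spectra_csv()
        lines = csv.strip().splitlines()
        assert lines[0] == "r,q,index,eigenvalue"
        assert len(lines) - 1 == trefoil_cx.total_dim()

    def test_8_12_has_zero_with_multiplicity_one_at_3_7(self, k8_12_spectra):
        sp = k8_12_spectra[(3, 7)]
        assert sp.zero_multiplicity == 1
        spm = k8_12_spectra[(-3, -7)]
        assert spm.zero_multiplicity == 1


class TestChirality:
    def test_8_12_spectral_asymmetry_despite_symmetric_homology(self, k8_12, k8_12_spectra):
        report = chirality_report(k8_12, "k8_12", spectra=k8_12_spectra)
        assert report.homology_symmetric
        assert (3, 7) in report.asymmetric_pairs
        assert not report.spectra_symmetric

    def test_8_12_symmetric_pairs_include_0_5(self, k8_12, k8_12_spectra):
        report = chirality_report(k8_12, "k8_12", spectra=k8_12_spectra)
        assert (0, 5) in report.pairs and (0, 5) not in report.asymmetric_pairs
        assert np.allclose(k8_12_spectra[(0, 5)].eigenvalues, [4, 4])
        assert np.allclose(k8_12_spectra[(0, -5)].eigenvalues, [4, 4])

    def test_trefoil_homology_is_already_asymmetric(self, trefoil):
        report = chirality_report(trefoil, "trefoil_R")
        assert not report.homology_symmetric

    def test_spectra_match_mirror_at_negated_gradings(self):
        for name in ("trefoil_R", "figure8", "hopf+", "trefoil_xy5"):
            d = fixtures(name)
            a = spectrum_table(d)
            b = spectrum_table(mirror(d))
            for (r, q), sp in a.items():
                other = b.entries[(-r, -q)]
                assert len(other.eigenvalues) == len(sp.eigenvalues)
                if sp.dim:
                    assert np.max(np.abs(sp.eigenvalues - other.eigenvalues)) < 1e-6

    def test_figure8_spectra_are_symmetric(self, figure8):
        # the standard figure-eight diagram is amphichiral on the nose
        report = chirality_report(figure8, "figure8")
        assert report.homology_symmetric and report.spectra_symmetric


class TestHeatmap:
    def test_trefoil_cell_0_3(self, trefoil):
        table = heatmap_table(trefoil)
        assert table.cell(0, 3) == pytest.approx(6.0)

    def test_empty_vs_harmonic_only_cells(self, trefoil):
        table = heatmap_table(trefoil)
        assert table.cell(1, 1) == "empty"  # no chain group there
        assert table.cell(3, 9) == _HARMONIC_ONLY  # kernel only
        assert "harmonic-only" in table.to_csv()

    def test_three_trefoil_diagrams_same_harmonic_cells_different_values(self):
        from khovlap import betti_table

        names = ("trefoil_R", "trefoil_xy5", "trefoil_xy7")
        tables = {name: heatmap_table(fixtures(name)) for name in names}
        # the gradings carrying homology coincide across all three diagrams
        harmonic = {name: set(betti_table(fixtures(name))) for name in names}
        assert harmonic["trefoil_R"] == harmonic["trefoil_xy5"] == harmonic["trefoil_xy7"]
        # but the non-harmonic least eigenvalues differ between diagrams
        a = tables["trefoil_R"].cell(0, 3)
        b = tables["trefoil_xy5"].cell(0, 3)
        assert isinstance(a, float) and isinstance(b, float) and abs(a - b) > 1e-6


class TestCli:
    def test_compute_fixture_json(self):
        result = CliRunner().invoke(main, ["compute", "--fixture", "trefoil_R"])
        assert result.exit_code == 0
        payload = json.loads(result.output)
        assert payload["spectra"]["1,5"]["eigenvalues"] == ["3", "6", "6"]

    def test_spectra_subcommand(self):
        result = CliRunner().invoke(
            main, ["spectra", "--fixture", "trefoil_R", "--r", "0", "--q", "3"]
        )
        assert result.exit_code == 0
        assert result.output.split() == ["0", "6"]

    def test_dirac_subcommand_prints_eight_eigenvalues(self):
        result = CliRunner().invoke(
            main, ["dirac", "--fixture", "trefoil_R", "--r", "1", "--q", "3"]
        )
        assert result.exit_code == 0
        eigs = result.output.strip().splitlines()[-1].split(":")[1].split()
        assert len(eigs) == 8

    def test_jones_subcommand(self):
        result = CliRunner().invoke(main, ["jones", "--fixture", "unknot"])
        assert result.exit_code == 0
        assert result.output.strip() == "1*q^0"

    def test_chirality_subcommand_lists_3_7(self):
        result = CliRunner().invoke(main, ["chirality", "--fixture", "k8_12"])
        assert result.exit_code == 0
        payload = json.loads(result.output)
        assert [3, 7] in payload["asymmetric_pairs"]
        assert payload["homology_symmetric"] is True

    def test_project_subcommand(self, tmp_path):
        out = tmp_path / "pd.txt"
        result = CliRunner().invoke(
            main,
            ["project", "--curve", "eq3", "--plane", "xz", "--samples", "1024",
             "--out", str(out)],
        )
        assert result.exit_code == 0
        from khovlap import parse_pd

        assert parse_pd(out.read_text()).n == 3

    def test_validation_error_exit_code(self, tmp_path):
        bad = tmp_path / "bad.pd"
        bad.write_text("X[1,2,3,4] X[1,2,3,5]")
        result = CliRunner().invoke(main, ["compute", "--pd-file", str(bad)])
        assert result.exit_code == 2
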