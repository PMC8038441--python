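"""Format round-trips, validation errors, and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest
import yaml

from emtquad import (
    SimConfig,
    align_samples,
    read_clinical_table,
    read_dependency_table,
    read_drug_table,
    read_expression_table,
    read_qpcr_plate,
    run_pipeline,
    simulate_cell_lines,
    simulate_cohort,
    simulate_qpcr,
)
from emtquad.dataio import (
    write_clinical_table,
    write_dependency_table,
    write_drug_table,
)
from emtquad.errors import ConfigurationError, FormatError


class TestExpressionIO:
    def test_round_trip(self, cohort, tmp_path):
        expr, _, _ = cohort
        path = tmp_path / "expr.tsv"
        expr.write_tsv(path)
        back = read_expression_table(path)
        assert back.sample_ids == expr.sample_ids
        assert back.feature_ids == expr.feature_ids
        np.testing.assert_allclose(back.values, expr.values, rtol=1e-5)

    def test_negative_value_names_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tG1\tG2\nS1\t1.0\t2.0\nS2\t-0.5\t1.0\n")
        with pytest.raises(FormatError, match=r"S2.*G1"):
            read_expression_table(path)

    def test_non_numeric_cell_names_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tG1\nS1\t1.0\nS2\txyz\n")
        with pytest.raises(FormatError, match=r"S2.*G1"):
            read_expression_table(path)

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tG1\nS1\t1.0\nS1\t2.0\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_expression_table(path)


class TestClinicalIO:
    def test_round_trip(self, cohort, tmp_path):
        _, clinical, _ = cohort
        path = tmp_path / "clin.tsv"
        write_clinical_table(clinical, path)
        back = read_clinical_table(path)
        assert list(back["sample_id"]) == list(clinical["sample_id"])
        np.testing.assert_allclose(back["time"], clinical["time"], rtol=1e-5)
        assert (back["event"] == clinical["event"]).all()
        assert (back["stage"] == clinical["stage"]).all()

    def test_non_binary_event_rejected(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text("sample_id\ttime\tevent\nS1\t3.0\t2\n")
        with pytest.raises(FormatError, match="event"):
            read_clinical_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text("sample_id\ttime\nS1\t3.0\n")
        with pytest.raises(FormatError, match="event"):
            read_clinical_table(path)

    def test_nonpositive_time_rejected(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text("sample_id\ttime\tevent\nS1\t0\t1\n")
        with pytest.raises(FormatError, match="time"):
            read_clinical_table(path)


class TestOtherTables:
    def test_drug_round_trip(self, cell_panel, tmp_path):
        _, drugs, _, _ = cell_panel
        path = tmp_path / "drugs.csv"
        write_drug_table(drugs, path)
        back = read_drug_table(path)
        np.testing.assert_allclose(back["ic50"], drugs["ic50"], rtol=1e-5)
        assert (back["drug"] == drugs["drug"]).all()

    def test_dependency_round_trip(self, cell_panel, tmp_path):
        _, _, dep, _ = cell_panel
        path = tmp_path / "dep.tsv"
        write_dependency_table(dep, path)
        back = read_dependency_table(path)
        np.testing.assert_allclose(back["raw_effect"], dep["raw_effect"], rtol=1e-5)
        assert (back["control_label"] == dep["control_label"]).all()

    def test_qpcr_round_trip(self, tmp_path):
        plate = simulate_qpcr(SimConfig(seed=2))
        path = tmp_path / "plate.csv"
        plate.write_csv(path)
        back = read_qpcr_plate(path)
        assert back.reference_sample_id == plate.reference_sample_id
        assert back.housekeeping == plate.housekeeping
        np.testing.assert_allclose(back.data[back.rep_columns],
                                   plate.data[plate.rep_columns], rtol=1e-5)


class TestAlignment:
    def test_intersection_join_counts_dropped(self):
        expr, clinical, _ = simulate_cohort(SimConfig(seed=13, n_tumors=5))
        clinical = clinical.iloc[:-1]  # one clinical row missing
        sub_expr, sub_clin, n_dropped = align_samples(expr, clinical)
        assert sub_expr.n_samples == 4
        assert n_dropped == 1
        assert sub_expr.sample_ids == list(sub_clin["sample_id"])

    def test_tiny_overlap_is_an_error(self):
        expr, clinical, _ = simulate_cohort(SimConfig(seed=13, n_tumors=5))
        with pytest.raises(FormatError, match="overlap"):
            align_samples(expr, clinical.iloc[:2])


@pytest.fixture(scope="module")
def config_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("cfg") / "cfg.yaml"
    path.write_text(yaml.safe_dump({
        "simulate": {"seed": 7, "n_tumors": 60, "n_cell_lines": 30},
        "analysis": {"feature": "ZNF71_KRAB", "cutoff": 1.5},
    }))
    return path


class TestPipeline:
    def test_artifacts_and_byte_identical_rerun(self, config_file, tmp_path):
        out1 = run_pipeline(config_file, tmp_path / "run1")
        out2 = run_pipeline(config_file, tmp_path / "run2")
        expected = {"emt_calls.tsv", "survival_report.json", "drug_response.tsv",
                    "dependency_calls.tsv", "qpcr_foldchanges.tsv", "run.log"}
        produced = {p.name for p in out1.iterdir()}
        assert expected <= produced
        for p in sorted(out1.iterdir()):
            assert p.read_bytes() == (out2 / p.name).read_bytes(), p.name

    def test_report_structure(self, config_file, tmp_path):
        import json

        out = run_pipeline(config_file, tmp_path / "run")
        report = json.loads((out / "survival_report.json").read_text())
        assert set(report["by_phenotype"]) == {
            "Epithelial", "Mesenchymal", "HighOverlap", "LowOverlap"}
        assert report["feature"] == "ZNF71_KRAB"
        calls = pd.read_csv(out / "emt_calls.tsv", sep="\t")
        assert len(calls) == 60

    def test_config_without_inputs_or_simulate_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"analysis": {"cutoff": 1.5}}))
        with pytest.raises(ConfigurationError):
            run_pipeline(path, tmp_path / "out")

    def test_unknown_simulate_field_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"simulate": {"seed": 1, "bogus": 2}}))
        with pytest.raises(ConfigurationError, match="bogus"):
            run_pipeline(path, tmp_path / "out")


class TestCli:
    def test_run_and_classify_commands(self, tmp_path):
        from click.testing import CliRunner

        from emtquad.cli import cli

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({"simulate": {"seed": 3, "n_tumors": 40,
                                                    "n_cell_lines": 20}}))
        runner = CliRunner()
        res = runner.invoke(cli, ["run", "--config", str(cfg),
                                  "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli, ["classify",
                                  "--expr", str(tmp_path / "out" / "expression.tsv"),
                                  "--out", str(tmp_path / "calls.tsv")])
        assert res.exit_code == 0, res.output
        calls = pd.read_csv(tmp_path / "calls.tsv", sep="\t")
        assert len(calls) == 40

    def test_validation_error_exits_2(self, tmp_path, monkeypatch, capsys):
        import sys

        from emtquad.cli import main

        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump({"simulate": {"seed": 1, "n_tumors": 2}}))
        monkeypatch.setattr(sys, "argv", ["emtquad", "run", "--config", str(bad),
                                          "--out", str(tmp_path / "o")])
        with pytest.raises(SystemExit) as exc:
            main()
        assert exc.value.code == 2
        assert "n_tumors" in capsys.readouterr().err
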