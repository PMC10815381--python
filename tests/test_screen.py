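import json

import numpy as np
import pandas as pd
import pytest

from csfmr.screen import (
    ProteinInput,
    ScreenConfig,
    SecondaryOutcome,
    make_report,
    run_screen,
)
from csfmr.synthetic_data import ScenarioConfig, simulate_panel


@pytest.fixture(scope="module")
def small_panel():
    """4-protein panel: protein 0 causal (theta = 0.4), rest null."""
    cfg = ScenarioConfig(n_exposure=835, n_outcome=8000, m_variants=16,
                         ld_rho=0.5, var_explained_cis=0.1)
    return simulate_panel([0.4, 0.0, 0.0, 0.0], cfg, seed=5)


def _run(panel_data, secondary=None, **cfg_kw):
    panel = [ProteinInput(pid, exp, region, ld)
             for pid, exp, region, ld in panel_data.proteins]
    return run_screen(panel, panel_data.outcome,
                      ScreenConfig(seed=1, **cfg_kw), secondary)


class TestRunScreen:
    def test_causal_protein_flagged_and_colocalized(self, small_panel):
        result = _run(small_panel)
        by_id = {r.protein_id: r for r in result.proteins}
        assert by_id["P00"].fdr_significant
        assert by_id["P00"].coloc_pass
        assert by_id["P00"].mr.theta == pytest.approx(0.4, abs=0.12)

    def test_coloc_computed_only_for_fdr_significant(self, small_panel):
        result = _run(small_panel)
        for r in result.proteins:
            if not r.fdr_significant:
                assert r.coloc is None

    def test_coloc_all_override_computes_everywhere(self, small_panel):
        result = _run(small_panel, coloc_all=True)
        assert all(r.coloc is not None for r in result.proteins if r.mr)

    def test_fdr_family_counts_proteins_with_instruments(self, small_panel):
        result = _run(small_panel)
        with_inst = sum(1 for r in result.proteins if r.n_instruments > 0)
        assert result.fdr_family_size == with_inst
        assert sum(result.multiplicity.values()) == with_inst

    def test_no_instrument_protein_reported_with_reason(self, small_panel):
        # cripple one null protein by shifting its region off-chromosome
        panel = [ProteinInput(pid, exp, region, ld)
                 for pid, exp, region, ld in small_panel.proteins]
        from csfmr.gwas_io import GeneRegion
        crippled = panel[2]
        panel[2] = ProteinInput(crippled.protein_id, crippled.exposure,
                                GeneRegion(crippled.protein_id, "21", 10, 20),
                                crippled.ld)
        result = run_screen(panel, small_panel.outcome, ScreenConfig(seed=1))
        by_id = {r.protein_id: r for r in result.proteins}
        assert by_id["P02"].reason == "no_instruments"
        assert result.fdr_family_size == 3

    def test_secondary_only_for_coloc_passing(self, small_panel):
        secondary = [SecondaryOutcome("brain_volume", small_panel.outcome,
                                      unit="mm3")]
        result = _run(small_panel, secondary=secondary)
        for r in result.proteins:
            if not r.coloc_pass:
                assert r.secondary == {}
            else:
                est = r.secondary["brain_volume"]
                assert est.nsnp >= 1

    def test_secondary_missing_instruments_reported(self, small_panel):
        other = small_panel.outcome
        empty = SecondaryOutcome(
            "empty", type(other)(trait_id="empty",
                                 table=other.table.iloc[0:0]), unit="SD")
        result = _run(small_panel, secondary=[empty])
        causal = next(r for r in result.proteins if r.coloc_pass)
        assert causal.secondary["empty"] == "no_instruments"

    def test_duplicate_protein_ids_rejected(self, small_panel):
        panel = [ProteinInput("same", exp, region, ld)
                 for _, exp, region, ld in small_panel.proteins[:2]]
        with pytest.raises(ValueError):
            run_screen(panel, small_panel.outcome, ScreenConfig())


class TestMakeReport:
    def test_report_files_written_and_deterministic(self, small_panel, tmp_path):
        result = _run(small_panel)
        paths_a = make_report(result, tmp_path / "a")
        paths_b = make_report(_run(small_panel), tmp_path / "b")
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes()

    def test_results_table_structure(self, small_panel, tmp_path):
        paths = make_report(_run(small_panel), tmp_path)
        df = pd.read_csv(paths["results"], sep="\t", keep_default_na=False)
        assert set(df["protein"]) == {"P00", "P01", "P02", "P03"}
        wald_rows = df.loc[df["method"].isin(["wald", "ivw_re"])]
        assert len(wald_rows) == 4
        # single-instrument hits carry no weighted-median row
        assert "weighted_median" not in set(df["method"])

    def test_provenance_roundtrip(self, small_panel, tmp_path):
        result = _run(small_panel)
        paths = make_report(result, tmp_path)
        prov = json.loads(paths["provenance"].read_text())
        assert prov["n_proteins"] == 4
        assert prov["fdr_family_size"] == result.fdr_family_size
        assert prov["instrument_multiplicity"]
        assert prov["coloc_priors"] == {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5}

    def test_exploratory_coloc_table_includes_subthreshold(self, small_panel,
                                                           tmp_path):
        result = _run(small_panel, coloc_all=True)
        paths = make_report(result, tmp_path)
        coloc_df = pd.read_csv(paths["coloc"], sep="\t")
        assert len(coloc_df) == sum(1 for r in result.proteins
                                    if r.coloc is not None)
        assert (coloc_df["pph4"] < 0.70).any()  # null proteins reported too


class TestCLI:
    def test_simulate_then_mr_roundtrip(self, tmp_path):
        from click.testing import CliRunner
        from csfmr.cli import main

        runner = CliRunner()
        out = tmp_path / "sim"
        res = runner.invoke(main, [
            "simulate", "--n-exposure", "400", "--n-outcome", "2000",
            "--m-variants", "12", "--theta", "0.4", "--seed", "3",
            "--out-dir", str(out)])
        assert res.exit_code == 0, res.output
        for name in ("exposure.tsv", "outcome.tsv", "ld.tsv", "regions.bed",
                     "truth.json"):
            assert (out / name).exists()

        res2 = runner.invoke(main, [
            "mr", "--exposure", str(out / "exposure.tsv"),
            "--outcome", str(out / "outcome.tsv"),
            "--regions", str(out / "regions.bed"),
            "--ld", str(out / "ld.tsv"),
            "--out", str(tmp_path / "mr.tsv")])
        assert res2.exit_code == 0, res2.output
        df = pd.read_csv(tmp_path / "mr.tsv", sep="\t")
        est = df.loc[df["method"].isin(["wald", "ivw_re"]), "beta"].iloc[0]
        assert est == pytest.approx(0.4, abs=0.25)

    def test_screen_cli_from_config(self, tmp_path):
        from click.testing import CliRunner
        from csfmr.cli import main
        from csfmr import gwas_io
        from csfmr.synthetic_data import ScenarioConfig, simulate_panel

        panel_data = simulate_panel([0.4, 0.0],
                                    ScenarioConfig(n_exposure=600,
                                                   n_outcome=4000,
                                                   m_variants=10,
                                                   ld_rho=0.5), seed=9)
        regions = []
        protein_entries = []
        for pid, exp, region, ld in panel_data.proteins:
            gwas_io.write_sumstats(exp, tmp_path / f"{pid}.tsv")
            gwas_io.write_ld_matrix(ld, tmp_path / f"{pid}_ld.tsv")
            regions.append(region)
            protein_entries.append({"protein_id": pid,
                                    "sumstats": str(tmp_path / f"{pid}.tsv"),
                                    "ld": str(tmp_path / f"{pid}_ld.tsv")})
        gwas_io.write_gene_regions(regions, tmp_path / "regions.bed")
        gwas_io.write_sumstats(panel_data.outcome, tmp_path / "outcome.tsv")
        config = {"proteins": protein_entries,
                  "regions": str(tmp_path / "regions.bed"),
                  "outcome": str(tmp_path / "outcome.tsv")}
        import yaml
        (tmp_path / "screen.yaml").write_text(yaml.safe_dump(config))

        runner = CliRunner()
        res = runner.invoke(main, ["screen", "--config",
                                   str(tmp_path / "screen.yaml"),
                                   "--seed", "1",
                                   "--out-dir", str(tmp_path / "report")])
        assert res.exit_code == 0, res.output
        results = pd.read_csv(tmp_path / "report" / "results.tsv", sep="\t")
        assert {"P00", "P01"} <= set(results["protein"])
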