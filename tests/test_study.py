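import json
import warnings

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from ivivckit.cli import main
from ivivckit.io import RunConfig, default_components
from ivivckit.study import StageError, run_full_study


def small_config(seed=3):
    comps = [c for c in default_components()
             if c.name in ("tetrahydropalmatine", "corydaline")]
    return RunConfig(components=comps,
                     media=["acetate_pH4.5", "HCl_0.1M"], seed=seed)


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # noisy vessel overshoot
        reports = run_full_study(small_config(), out_dir=out)
    return reports, out


class TestRunFullStudy:
    def test_bundle_is_complete(self, bundle):
        reports, out = bundle
        for key in ("bcs", "dissolution_models", "pk_nca", "ivivc",
                    "selected", "integrated_dissolution"):
            assert key in reports
            assert (out / f"{key}.csv").exists()
        assert (out / "run.json").exists()

    def test_one_medium_selected_per_component(self, bundle):
        reports, _ = bundle
        sel = reports["selected"]
        assert sorted(sel["component"]) == ["corydaline",
                                            "tetrahydropalmatine"]
        assert set(sel["medium"]).issubset({"acetate_pH4.5", "HCl_0.1M"})

    def test_bcs_group_integration_present(self, bundle):
        reports, _ = bundle
        assert "integrated_group_I" in reports
        group = reports["integrated_group_I"]
        assert sum(group["weights"].values()) == pytest.approx(1.0)

    def test_reports_round_trip_through_readers(self, bundle):
        _, out = bundle
        df = pd.read_csv(out / "bcs.csv")
        assert list(df["bcs_class"]) == ["I", "I"]
        json.loads((out / "run.json").read_text())

    def test_empty_config_rejected(self):
        with pytest.raises(StageError):
            run_full_study(RunConfig(components=[]))

    def test_unknown_component_names_the_offender(self):
        cfg = small_config()
        bad = cfg.model_copy(update={"components": [
            cfg.components[0].model_copy(update={"name": "nonexistent"})]})
        with pytest.raises(StageError, match="nonexistent"):
            run_full_study(bad)

    def test_rerun_same_seed_is_byte_identical(self, tmp_path):
        cfg = RunConfig(components=default_components()[:1],
                        media=["acetate_pH4.5"], seed=11)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        run_full_study(cfg, out_dir=d1)
        run_full_study(cfg, out_dir=d2)
        for f1 in sorted(d1.iterdir()):
            assert (d2 / f1.name).read_bytes() == f1.read_bytes()


class TestConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(Exception):
            RunConfig.model_validate({"seed": 1, "bogus": True})

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps(cfg.model_dump()))
        assert RunConfig.from_file(path) == cfg

    def test_digest_stable(self):
        assert small_config().digest() == small_config().digest()
        assert small_config(seed=4).digest() != small_config().digest()


class TestCLI:
    def test_classify_bcs_subcommand(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "bcs.csv"
        result = runner.invoke(main, ["classify-bcs", "--out", str(out)])
        assert result.exit_code == 0, result.output
        df = pd.read_csv(out)
        assert len(df) == 5 and set(df["bcs_class"]) == {"I"}

    def test_nca_subcommand(self, tmp_path):
        t = np.arange(0, 500.0, 10.0)
        pd.DataFrame({"time": t, "conc": 20 * np.exp(-0.01 * t)}).to_csv(
            tmp_path / "iv.csv", index=False)
        runner = CliRunner()
        out = tmp_path / "nca.json"
        result = runner.invoke(main, ["nca", "--input",
                                      str(tmp_path / "iv.csv"), "--route",
                                      "iv", "--dose", "100", "--out",
                                      str(out)])
        assert result.exit_code == 0, result.output
        res = json.loads(out.read_text())
        assert res["t_half"] == pytest.approx(69.31, rel=1e-3)

    def test_fit_uir_and_deconvolve_pipeline(self, tmp_path):
        from ivivckit.pk import UnitImpulseResponse
        t = np.arange(5, 721.0, 5.0)
        uir = UnitImpulseResponse.from_params([(0.05, 0.008)])
        iv = 100 * uir.evaluate(t)
        ka = 0.03
        oral = (100 * 0.05 * ka / (ka - 0.008)
                * (np.exp(-0.008 * t) - np.exp(-ka * t)))
        pd.DataFrame({"time": t, "conc": iv}).to_csv(tmp_path / "iv.csv",
                                                     index=False)
        pd.DataFrame({"time": t, "conc": oral}).to_csv(
            tmp_path / "oral.csv", index=False)
        runner = CliRunner()
        r1 = runner.invoke(main, ["fit-uir", "--input",
                                  str(tmp_path / "iv.csv"), "--dose", "100",
                                  "--terms", "1", "--out",
                                  str(tmp_path / "uir.json")])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(main, ["deconvolve", "--oral",
                                  str(tmp_path / "oral.csv"), "--uir",
                                  str(tmp_path / "uir.json"), "--step", "5",
                                  "--out", str(tmp_path / "fabs.csv")])
        assert r2.exit_code == 0, r2.output
        fabs = pd.read_csv(tmp_path / "fabs.csv")
        truth = 1 - np.exp(-ka * fabs["time_min"].to_numpy())
        assert np.max(np.abs(fabs["fabs"].to_numpy() - truth)) < 0.01
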