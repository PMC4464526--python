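import pytest

from idpriority.pipeline import PipelineConfig, run_pipeline
from idpriority.synthetic import published_ranking_fixture, study_scenario


@pytest.fixture(scope="session")
def study():
    """The deterministic study-structure bundle and its construction truth."""
    return study_scenario()


@pytest.fixture(scope="session")
def published_clusters():
    """The 15 printed ranking-table rows as cluster summaries."""
    return published_ranking_fixture()


@pytest.fixture(scope="session")
def study_run(study, tmp_path_factory):
    """A full pipeline run over the study bundle (inputs, outputs, result)."""
    bundle, truth = study
    root = tmp_path_factory.mktemp("study_run")
    paths = bundle.write(root / "inputs")
    config = PipelineConfig.from_dict(
        {
            "inputs": {k: str(v) for k, v in paths.items()},
            "output_dir": str(root / "out"),
            "accumulation": {"n_permutations": 199, "seed": 11},
        }
    )
    result, top = run_pipeline(config)
    return {
        "bundle": bundle,
        "truth": truth,
        "config": config,
        "outdir": root / "out",
        "result": result,
        "top": top,
    }
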