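import pytest

import fusionlink as fl


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-gene cohort with the default planted 6-fold modules."""
    return fl.generate_cohort(fl.SimConfig(n_genes=400, seed=11))


@pytest.fixture(scope="session")
def noise_free_cohort():
    return fl.generate_cohort(fl.SimConfig(n_genes=200, noise_sd=0.0, seed=5))


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two full pipeline runs with the same seed on the default cohort."""
    base = tmp_path_factory.mktemp("pipeline")
    first = fl.run_pipeline(
        fl.PipelineConfig(outdir=str(base / "run1"), seed=7, simulate=fl.SimConfig())
    )
    second = fl.run_pipeline(
        fl.PipelineConfig(outdir=str(base / "run2"), seed=7, simulate=fl.SimConfig())
    )
    return first, second
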