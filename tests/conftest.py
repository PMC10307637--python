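import pytest

from enhancerkit.pipeline import simulate_bundle, run_pipeline
from enhancerkit.simulate import SyntheticTruth


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """A small simulated input bundle plus its pipeline results."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = simulate_bundle(11, outdir, "tiny")
    summary = run_pipeline(config)
    truth = SyntheticTruth.from_json(outdir / "truth.json")
    return {"dir": outdir, "config": config, "summary": summary, "truth": truth}
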