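import numpy as np
import pytest

from junctionscreen.synthetic import (
    MonolayerSpec,
    ScreenSimSpec,
    generate_monolayer_images,
    generate_screen_table,
)


@pytest.fixture(scope="session")
def default_well():
    """One confluent synthetic well with ground truth (session-cached)."""
    return generate_monolayer_images(MonolayerSpec(seed=1))


@pytest.fixture(scope="session")
def screen156():
    """A 156-gene screen at the default study conditions, with truth."""
    spec = ScreenSimSpec(within_cluster_sd=0.5, plate_shift=5.0, seed=2)
    table, labels = generate_screen_table(spec)
    return spec, table, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny(tmp_path_factory):
    """The tiny end-to-end preset (images + tables + graph + annotations)."""
    from junctionscreen.pipeline import make_fixtures

    out = tmp_path_factory.mktemp("fixtures") / "tiny"
    info = make_fixtures("tiny", out, seed=7)
    return out, info


@pytest.fixture(scope="session")
def tiny_run(tiny, tmp_path_factory):
    """A full pipeline run over the tiny preset, shared across tests."""
    from junctionscreen.pipeline import RunConfig, run_pipeline

    src, _ = tiny
    outdir = tmp_path_factory.mktemp("runs") / "full"
    config = RunConfig(
        outdir=str(outdir),
        images_dir=str(src / "images"),
        platemap=str(src / "platemap.csv"),
        edges=str(src / "edges.tsv"),
        annotations=str(src / "annotations.csv"),
        n_random=300,
        seed=7,
    )
    manifest = run_pipeline(config)
    return outdir, config, manifest
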