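import pytest

from adnet import GeneNetwork, SynthConfig, write_bundle
from adnet.pipeline import PipelineConfig, run_pipeline


@pytest.fixture
def triangle() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def k4() -> GeneNetwork:
    nodes = ["A", "B", "C", "D"]
    edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
    return GeneNetwork.from_edges(edges)


@pytest.fixture
def star4() -> GeneNetwork:
    """K_{1,4}: hub H with leaves L1..L4."""
    return GeneNetwork.from_edges([("H", f"L{i}") for i in range(1, 5)])


@pytest.fixture
def two_triangles() -> GeneNetwork:
    return GeneNetwork.from_edges(
        [("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y"), ("Y", "Z"), ("Z", "X")]
    )


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A reduced synthetic bundle for fast integration tests."""
    return SynthConfig(
        n_genes=90,
        module_sizes=(15, 15, 15),
        n_samples=40,
        n_pathways=12,
        n_complexes=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return small_cfg, write_bundle(small_cfg, outdir)


@pytest.fixture(scope="session")
def default_cfg() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def default_pipeline(default_cfg, tmp_path_factory):
    """Full pipeline run on the default synthetic bundle."""
    simdir = tmp_path_factory.mktemp("sim")
    paths = write_bundle(default_cfg, simdir)
    cfg = PipelineConfig(
        ppi=[str(paths["ppi"])],
        expr=str(paths["expression"]),
        gmt=str(paths["pathways"]),
        complexes=str(paths["complexes"]),
        diseases=str(paths["diseases"]),
        total_genes=default_cfg.n_genes,
        seed=default_cfg.seed,
    )
    outdir = tmp_path_factory.mktemp("run")
    report = run_pipeline(cfg, outdir)
    return default_cfg, report, outdir
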