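import pytest

from acetylsite import fixtures
from acetylsite.seqio import Fragment


def make_fragment(window: str, pid: str = "P1", center: int | None = None,
                  label: str = "unknown") -> Fragment:
    if center is None:
        center = len(window) // 2 + 1
    return Fragment(pid, center, window, label)


@pytest.fixture(scope="session")
def default_benchmark():
    """The fixtures-default synthetic study at seed 0."""
    proteins, annotations, truth = fixtures.generate_benchmark(seed=0)
    pos, neg = fixtures.benchmark_fragments(proteins, annotations)
    return {
        "proteins": proteins,
        "annotations": annotations,
        "truth": truth,
        "positives": pos,
        "negatives": neg,
    }


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced planted-motif dataset for slower end-to-end checks."""
    motifs = tuple(
        fixtures.MotifSpec(spec.name, spec.positions, 25)
        for spec in fixtures.DEFAULT_MOTIFS
    )
    config = fixtures.BenchmarkConfig(
        motif_specs=motifs, n_negatives=50, n_proteins=30, protein_length=150
    )
    proteins, annotations, truth = fixtures.generate_benchmark(config, seed=3)
    pos, neg = fixtures.benchmark_fragments(proteins, annotations)
    return {
        "config": config,
        "proteins": proteins,
        "annotations": annotations,
        "truth": truth,
        "positives": pos,
        "negatives": neg,
    }
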