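"""Shared fixtures: a toy annotated genome and the default synthetic study."""

import numpy as np
import pytest

import primatx
from primatx.genome_model import GeneFeature, GenomeAnnotation, Replicon


def random_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """10 kb replicon with forward/reverse CDSs and a tRNA.

    Layout: cdsF (+) 2001..2900, cdsF2 (+) 3100..3600, cdsR (-) 4001..4500,
    trnaF (+) 6001..6076.
    """
    seq = random_sequence(10_000, seed=11)
    genes = [
        GeneFeature("cdsF", "chr", 2001, 2900, "+", "CDS"),
        GeneFeature("cdsF2", "chr", 3100, 3600, "+", "CDS"),
        GeneFeature("cdsR", "chr", 4001, 4500, "-", "CDS"),
        GeneFeature("trnaF", "chr", 6001, 6076, "+", "tRNA"),
    ]
    return GenomeAnnotation([Replicon("chr", 10_000, seq)], genes)


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study (seed 42): annotation, truth, tracks."""
    config = primatx.SimulationConfig(seed=42)
    annotation, truth, tracks = primatx.simulate_bundle(config)
    return config, annotation, truth, tracks


@pytest.fixture(scope="session")
def default_calls(default_bundle):
    _, _, _, tracks = default_bundle
    return primatx.detect_tss(tracks, primatx.DetectionConfig())


@pytest.fixture(scope="session")
def default_records(default_bundle, default_calls):
    _, annotation, _, tracks = default_bundle
    rnaseq = next(t for t in tracks if t.meta.treatment == "RNASEQ")
    config = primatx.ClassificationConfig(use_coverage_extension=True)
    return primatx.classify_all(default_calls, annotation, config, rnaseq)
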