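import pytest

from sinescope import calibration, splicing, synthetic


@pytest.fixture(scope="session")
def spec():
    return synthetic.ConsensusSpec()


@pytest.fixture(scope="session")
def consensus(spec):
    return synthetic.build_consensus(spec, seed=0)


@pytest.fixture(scope="session")
def dual_sites(spec):
    return splicing.find_dual_sites(spec)[0]


@pytest.fixture(scope="session")
def implant_genome(consensus, dual_sites):
    """Medium genome with 40 implants (mixed classes), low divergence."""
    bg = synthetic.generate_background(260_000, 0.41, seed=11)
    genome, truth = synthetic.implant_elements(
        bg,
        consensus,
        40,
        sub_rate=0.01,
        spliced_prob=0.25,
        splice_sites=dual_sites,
        seed=12,
    )
    return genome, truth


@pytest.fixture(scope="session")
def calibrated(implant_genome, consensus):
    genome, truth = implant_genome
    hits = calibration.scan_hits(genome, consensus)
    elements, _ = calibration.calibrate_all(genome, hits)
    return genome, truth, elements


@pytest.fixture(scope="session")
def annotated(implant_genome, spec):
    genome, truth = implant_genome
    genes = synthetic.synthesize_annotation(
        genome, truth, 10, exon_in_element_prob=0.5, seed=13, consensus_spec=spec
    )
    return genome, truth, genes
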