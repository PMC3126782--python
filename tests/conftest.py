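import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chemoseq import (
    SimulationConfig,
    build_index,
    build_transcriptome,
    simulate_expression,
    simulate_reads,
)


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(
        n_genes=40,
        n_paralog_families=2,
        paralog_divergence=0.02,
        transcript_length_range=(150, 400),
        library_size=4000,
        read_length=43,
        error_rate=0.002,
        seed=11,
        enhanced_design={"FA": {i: 8.0 for i in range(8, 14)}, "MP": {20: 16.0}},
        family_design={"Or": [8, 9, 10], "Ir": [11, 12]},
        pfam_design={"PF02949": [8, 9, 10], "PF00060": [11, 12]},
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    """Transcriptome, annotation, truth and an index for the tiny design."""
    transcriptome, annotation = build_transcriptome(tiny_config)
    truth = simulate_expression(tiny_config)
    index = build_index(transcriptome.isoforms())
    return {
        "config": tiny_config,
        "transcriptome": transcriptome,
        "annotation": annotation,
        "truth": truth,
        "index": index,
    }


@pytest.fixture(scope="session")
def tiny_reads(tiny_world):
    cfg = tiny_world["config"]
    return {
        s: simulate_reads(tiny_world["truth"], tiny_world["transcriptome"], cfg, s)
        for s in ("FA", "FB")
    }
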