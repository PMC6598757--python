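import numpy as np
import pytest

import ngdtools as ngd


@pytest.fixture(scope="session")
def reporter():
    return ngd.build_reporter("NGD-CGA")


@pytest.fixture(scope="session")
def opt_reporter():
    return ngd.build_reporter("OPT")


@pytest.fixture(scope="session")
def rfp():
    return ngd.build_rfp_control()


@pytest.fixture(scope="session")
def index(reporter, rfp):
    return ngd.TranscriptomeIndex(
        {reporter.name: reporter.transcript_seq, rfp.name: rfp.transcript_seq}
    )


@pytest.fixture(scope="session")
def ngd_library(reporter, rfp):
    """Default dom34d ski2d monosome library, 20k reads, fixed seed."""
    scenario = ngd.make_scenario("dom34d ski2d", n_reads=20_000, seed=42)
    return ngd.simulate_ngd_library([rfp], reporter, scenario)


@pytest.fixture(scope="session")
def aligned_library(tmp_path_factory, ngd_library, index):
    from ngdtools.pipeline import process_library

    path = tmp_path_factory.mktemp("lib") / "lib.fastq"
    ngd_library.write_fastq(path)
    alignments, trimmed, accounting = process_library(path, index)
    return alignments, trimmed, accounting


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
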