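"""Shared fixtures: small geometric shapes and one full default pipeline run."""

import numpy as np
import pytest

from powdermorph import pipeline


def regular_polygon(n: int, radius: float = 50.0) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])


@pytest.fixture(scope="session")
def square():
    return np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])


@pytest.fixture(scope="session")
def fine_circle():
    return regular_polygon(720)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full end-to-end run of the default synthetic study (seed 0).

    Session-scoped: this is the stated-world benchmark that the
    acceptance and pipeline tests all read from.
    """
    import time

    outdir = tmp_path_factory.mktemp("default_run")
    config = pipeline.RunConfig(seed=0, outdir=str(outdir))
    start = time.perf_counter()
    report = pipeline.run(config)
    report["elapsed_seconds"] = time.perf_counter() - start
    return config, report
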