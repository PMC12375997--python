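import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lcconsensus as lc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def round_to_printed(value: float, printed: str) -> float:
    """Round ``value`` to the precision of the printed string ``printed``.

    Decimal strings round to their decimal places; integer strings round
    to their significant figures (trailing zeros treated as padding, so
    "100" means 1 s.f.).
    """
    printed = printed.strip()
    if "." in printed:
        decimals = len(printed.split(".")[1])
        return round(value, decimals)
    sig = max(len(printed.rstrip("0")), 1)
    if value == 0:
        return 0.0
    from math import floor, log10

    magnitude = floor(log10(abs(value)))
    return round(value, -magnitude + sig - 1)


@pytest.fixture(scope="session")
def germline():
    return lc.make_synthetic_germline("IGSYN1-1", seed=11)


@pytest.fixture(scope="session")
def registry(germline):
    reg = lc.GermlineRegistry()
    reg.add(germline)
    return reg


@pytest.fixture(scope="session")
def small_cohort(germline):
    config = lc.SimulationConfig(
        germline=germline, cohort="AL", n_sequences=40, seed=101
    )
    seq_set, truth = lc.simulate_repertoire(config)
    return seq_set, truth, config


@pytest.fixture(scope="session")
def reference_cohort(germline):
    config = lc.SimulationConfig(
        germline=germline, cohort="OAS", n_sequences=2000, seed=101
    )
    seq_set, _ = lc.simulate_repertoire(config)
    return seq_set


@pytest.fixture(scope="session")
def reference_matrix(reference_cohort):
    return lc.build_consensus(reference_cohort)


def make_chain(residues, id="seq", gene="IGSYN1-1", cohort="AL", allele=None):
    return lc.AlignedLightChain(
        id=id, gene=gene, cohort=cohort, residues="".join(residues), allele=allele
    )


def mutated_copy(germline, changes, **kwargs):
    """Chain equal to the germline except at {position: residue}."""
    residues = list(germline.residues)
    for pos, res in changes.items():
        residues[pos - 1] = res
    return make_chain(residues, gene=germline.gene, **kwargs)
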