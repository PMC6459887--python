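import numpy as np
import pytest

from ivmr import HarmonizedInstrument, MRModel, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_instruments(table1):
    exposure, outcome = table1
    return MRModel.from_datasets(exposure, outcome).instruments


def make_instrument(
    variant_id="rs1",
    chromosome="1",
    position_bp=1000,
    beta_exposure=0.1,
    se_exposure=0.01,
    p_exposure=1e-10,
    beta_outcome=0.01,
    se_outcome=0.01,
    p_outcome=0.5,
    flipped=False,
):
    return HarmonizedInstrument(
        variant_id=variant_id,
        chromosome=chromosome,
        position_bp=position_bp,
        beta_exposure=beta_exposure,
        se_exposure=se_exposure,
        p_exposure=p_exposure,
        beta_outcome=beta_outcome,
        se_outcome=se_outcome,
        p_outcome=p_outcome,
        flipped=flipped,
    )


def random_instruments(rng: np.random.Generator, k: int):
    """Random valid instrument sets for property tests."""
    bx = rng.uniform(0.05, 0.5, k) * rng.choice([-1.0, 1.0], k)
    by = rng.normal(0.0, 0.1, k)
    sex = rng.uniform(0.005, 0.05, k)
    sey = rng.uniform(0.005, 0.05, k)
    return [
        make_instrument(
            variant_id=f"rs{i}",
            chromosome=str(i % 22 + 1),
            position_bp=int(1e6 + i * 1e7),
            beta_exposure=float(bx[i]),
            se_exposure=float(sex[i]),
            beta_outcome=float(by[i]),
            se_outcome=float(sey[i]),
        )
        for i in range(k)
    ]
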