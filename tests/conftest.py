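import numpy as np
import pytest

from screenrisk import ScreeningScenario, TestPerformance, variant_test


@pytest.fixture(scope="session")
def stre_test() -> TestPerformance:
    return variant_test("STRE")


@pytest.fixture(scope="session")
def snv_test() -> TestPerformance:
    return variant_test("SNV")


@pytest.fixture(scope="session")
def pcr_test() -> TestPerformance:
    return TestPerformance(0.95, 0.98, label="repeat-primed PCR")


@pytest.fixture(scope="session")
def htt_screening(stre_test) -> ScreeningScenario:
    return ScreeningScenario(0.000410, 1.0, 1.0, stre_test, label="HTT (screening)", variant_type="STRE")


@pytest.fixture(scope="session")
def htt_targeted(stre_test) -> ScreeningScenario:
    return ScreeningScenario(0.500, 1.0, 1.0, stre_test, label="HTT (targeted)", variant_type="STRE")


@pytest.fixture(scope="session")
def c9_screening(stre_test) -> ScreeningScenario:
    return ScreeningScenario(0.00333, 0.0635, 0.439, stre_test, label="C9orf72 (screening)", variant_type="STRE")


@pytest.fixture(scope="session")
def pah_scenario(snv_test) -> ScreeningScenario:
    return ScreeningScenario(0.000100, 0.743, 0.892, snv_test, label="PAH", variant_type="SNV")


def random_valid_scenarios(n: int, seed: int) -> list[ScreeningScenario]:
    """Seeded draws of scenarios satisfying every model constraint.

    Penetrance is drawn first and the prior scaled below it, which
    guarantees P(D)·P(M|D) ≤ P(D|M), P(M) < 1 and P(D|M') ≤ 1 (the marker
    is never protective, so no warning fires).
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        pen = rng.uniform(1e-3, 1.0)
        prior = pen * rng.uniform(1e-6, 0.999)
        mfa = rng.uniform(0.0, 1.0)
        sens = rng.uniform(0.0, 1.0)
        spec = rng.uniform(1e-3, 1.0 - 1e-3)
        out.append(ScreeningScenario(prior, mfa, pen, TestPerformance(sens, spec)))
    return out
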