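import pytest

import zfarray as z


@pytest.fixture(scope="session")
def sim_catalog():
    """Small homologous-finger catalog with random-unit-string alleles."""
    return z.simulate_catalog(n_fingers=12, n_alleles=10, seed=101)


@pytest.fixture(scope="session")
def typed_catalog():
    """Two-family catalog (A-like / C-like references plus variants)."""
    catalog, ref_a, ref_c = z.simulate_typed_catalog(n_a=12, n_c=8, seed=7)
    return catalog, ref_a, ref_c


@pytest.fixture(scope="session")
def anchors():
    return z.FlankAnchors()


@pytest.fixture()
def two_fingers():
    """Two concrete fingers on the simulator scaffold, plus their catalog."""
    base = z.simulate_catalog(n_fingers=2, n_alleles=2, length_range=(2, 3), seed=5)
    codes = list(base.fingers)
    return base, codes


def units_of(dna: str) -> list[str]:
    return [dna[i : i + z.ZF_UNIT_NT] for i in range(0, len(dna), z.ZF_UNIT_NT)]
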