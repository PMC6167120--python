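import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from clampwise.seqcore import bundled_panel  # noqa: E402


@pytest.fixture(scope="session")
def panel():
    """Bundled six-primer clamping-PCR panel, keyed by name."""
    return {p.name: p for p in bundled_panel()}


@pytest.fixture(scope="session")
def small_synthetic():
    """A small three-phylum synthetic collection with hand-picked planted
    rates, shared across tests (seed-fixed, so order-independent)."""
    from clampwise.synthetic import SyntheticSpec, generate_reference_set

    rates = {
        ("Alphaproteobacteria", 65): 0.4,
        ("Planctomycetes", 60): 0.5,
        ("Planctomycetes", 65): 0.6,
    }
    spec = SyntheticSpec(
        taxa=(("Alphaproteobacteria", 300), ("Planctomycetes", 300),
              ("Firmicutes", 300)),
        rates=rates, background_rate=0.01, seed=11,
    )
    rs, truth = generate_reference_set(spec)
    return spec, rs, truth
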