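import pytest
from hypothesis import HealthCheck, settings

from siap.formulary import Formulary, Prescription, StandardFormula
from siap.synthetic import GeneratorConfig, generate

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def formula(name, c1=(), c2=(), c3=(), c4=(), extra=()):
    levels = {"C1": frozenset(c1), "C2": frozenset(c2), "C3": frozenset(c3), "C4": frozenset(c4)}
    full = frozenset().union(*levels.values(), frozenset(extra))
    return StandardFormula(name=name, levels=levels, full_set=full)


@pytest.fixture(scope="session")
def toy_formulary():
    """Three small hand-built formulas with overlapping drugs."""
    return Formulary.from_iterable(
        [
            formula("decoction-a", c1=("a",), c2=("b",), c3=("c", "d")),
            formula("decoction-b", c1=("e",), c2=("b", "f"), c4=("g",)),
            formula("powder-c", c1=("h", "i"), extra=("j",)),
        ]
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A small but fully featured synthetic corpus (formulary + labelled rx)."""
    config = GeneratorConfig(
        n_formulas=40, vocabulary_size=140, n_prescriptions=150, seed=11
    )
    return generate(config)


@pytest.fixture
def labelled(small_corpus):
    _, prescriptions = small_corpus
    return prescriptions


def make_prescription(pid, drugs, labels=None):
    return Prescription(id=pid, drugs=frozenset(drugs), labels=None if labels is None else frozenset(labels))
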