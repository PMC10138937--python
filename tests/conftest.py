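import pytest

from kintext import builtin_problems


@pytest.fixture(scope="session")
def problems():
    """The four builtin test problems, keyed by name."""
    return {p.name: p for p in builtin_problems()}


@pytest.fixture(scope="session")
def models(problems):
    """Each builtin problem translated and built once per session."""
    return {name: p.build() for name, p in problems.items()}
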