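import pytest

from ucd.registry import Registry


@pytest.fixture
def meta():
    """Minimal metadata satisfying the default mandatory fields."""
    return {"project": "P1", "scientist": "alice"}


@pytest.fixture
def registry():
    """Registry with one user per role (teams A/B for access tests)."""
    reg = Registry()
    reg.add_user("vera", "viewer", team="B")
    reg.add_user("alice", "submitter", team="A")
    reg.add_user("ruth", "registrar", team="A")
    return reg


def register(reg, structure, meta, composition=None, mixture_ratio=None, **kwargs):
    """Submit as alice and approve as ruth; returns the registered batch."""
    sub = reg.submit(
        "alice", structure, composition=composition,
        mixture_ratio=mixture_ratio, metadata=meta, **kwargs
    )
    return reg.decide_submission("ruth", sub.id, True)


@pytest.fixture
def do_register():
    return register
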