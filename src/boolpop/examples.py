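"""Bundled fixture networks.

``example_network()`` is the 3-node worked example whose closure from {A}
produces the six canonical product-basis equations.  ``ladder_network()`` is
a 6-node feedforward toy with a delayed inhibitor, sized so that even its
wild-type-augmented double (12 variables) fits the exact state-space oracle.

No T-cell receptor network ships with the package: its logic table lives in
the original publication describing that model and must be transcribed by
the user into the rules dialect (any path accepted by the CLI or
:func:`boolpop.bnet.load_network`).
"""

from __future__ import annotations

from importlib import resources

from .bnet import parse_network
from .network import BooleanNetwork


def _load(name: str) -> BooleanNetwork:
    text = resources.files("boolpop.data").joinpath(name).read_text()
    return parse_network(text)


def example_network() -> BooleanNetwork:
    """3-node network: A ← !B, B ← A & C, C ← A | B."""
    return _load("example3.bnet")


def ladder_network() -> BooleanNetwork:
    """6-node feedforward ladder with a self-sustaining input and an inhibitor."""
    return _load("ladder6.bnet")
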