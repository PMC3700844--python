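"""Shared fixtures: the worked-example graph and an independent replay
oracle that reconstructs genotypes purely from root labels and the recorded
operations, never consulting cached labels or the library's decompression
path."""

from __future__ import annotations

import pytest

from ogsim import genotype_models as gm
from ogsim.fixtures import build_example_og
from ogsim.operation_graph import OperationGraph


def replay_from_roots(og: OperationGraph, x: int, _memo=None):
    """Brute-force oracle: re-apply the full event history from the root(s),
    ignoring every label except root labels."""
    if _memo is None:
        _memo = {}
    if x in _memo:
        return _memo[x]
    node = og.nodes[x]
    if node.is_root:
        assert node.label is not None, "oracle needs explicit roots"
        _memo[x] = node.label
        return node.label
    vals = [replay_from_roots(og, p, _memo) for p in node.parents]
    result = gm.apply(node.op, *vals)
    _memo[x] = result
    return result


@pytest.fixture
def example_og():
    return build_example_og()


@pytest.fixture
def replay():
    return replay_from_roots
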