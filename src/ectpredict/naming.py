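"""Feature and node naming conventions shared across the pipeline.

Nodes are either atlas ROIs (``R001`` ... ``R202``, ids = atlas integer
labels) or ICA-derived resting-state networks (``N01`` ...).  Features are
named ``<metric>:<node>`` for per-node metrics and ``<metric>:<idA>-<idB>``
with ``idA < idB`` for pairwise metrics, so every feature name is unique
across blocks and encodes its own provenance.
"""

from __future__ import annotations

ROI_PREFIX = "R"
RSN_PREFIX = "N"


def roi_node(roi_id: int) -> str:
    return f"{ROI_PREFIX}{roi_id:03d}"


def rsn_node(rsn_id: int) -> str:
    return f"{RSN_PREFIX}{rsn_id:02d}"


def pair_feature(metric: str, node_a: str, node_b: str) -> str:
    """Unordered pair feature name; endpoints sorted so idA < idB."""
    a, b = sorted((node_a, node_b))
    return f"{metric}:{a}-{b}"


def node_feature(metric: str, node: str) -> str:
    return f"{metric}:{node}"


def parse_pair_feature(name: str) -> tuple[str, str, str]:
    """Split ``metric:a-b`` into (metric, a, b)."""
    metric, _, pair = name.partition(":")
    a, _, b = pair.partition("-")
    if not (metric and a and b):
        raise ValueError(f"not a pair feature name: {name!r}")
    return metric, a, b
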