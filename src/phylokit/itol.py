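"""Plain-text iTOL annotation datasets.

Only the simple-bar dataset is emitted: one numeric value per taxon,
drawn as bars alongside the tree when the file is dropped onto an iTOL
canvas. This is the companion output of the per-taxon statistics
(long-branch scores, root-to-tip lengths).
"""

from __future__ import annotations

import math

__all__ = ["write_itol_simplebar"]

_HEADER = """DATASET_SIMPLEBAR
SEPARATOR COMMA
DATASET_LABEL,{title}
COLOR,{color}
DATA
"""


def write_itol_simplebar(values: dict[str, float], title: str, color: str = "#4477aa") -> str:
    """Render a taxon -> value map as an iTOL simple-bar dataset."""
    if not values:
        raise ValueError("no values to write")
    for taxon, value in values.items():
        if not math.isfinite(value):
            raise ValueError(f"non-finite value for taxon {taxon!r}")
    lines = [_HEADER.format(title=title, color=color)]
    for taxon, value in values.items():
        lines.append(f"{taxon},{value:.6g}\n")
    return "".join(lines)
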