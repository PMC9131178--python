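"""Canonical nine-class tissue label set for colorectal H&E tiles.

The labels follow the public nine-class colorectal patch collections:
ADI (adipose), BACK (background), DEB (debris), LYM (lymphocyte
aggregates), MUC (mucus), MUS (smooth muscle), NORM (normal colon
mucosa), STR (cancer-associated stroma), TUM (tumor epithelium).
Indices 0-8 are fixed in alphabetical order and are part of the public
contract: probability vectors, serialized models and prediction tables
all use this ordering.
"""

from __future__ import annotations

CLASS_LABELS: tuple[str, ...] = (
    "ADI",
    "BACK",
    "DEB",
    "LYM",
    "MUC",
    "MUS",
    "NORM",
    "STR",
    "TUM",
)

LABEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CLASS_LABELS)}

ADI_INDEX: int = LABEL_INDEX["ADI"]
BACK_INDEX: int = LABEL_INDEX["BACK"]

N_CLASSES: int = len(CLASS_LABELS)


def check_label(label: str) -> str:
    """Return *label* if it is one of the nine canonical classes, else raise."""
    if label not in LABEL_INDEX:
        raise ValueError(
            f"unknown tissue class {label!r}; expected one of {CLASS_LABELS}"
        )
    return label
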