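"""Fixed registry of the 93 map features.

Names are ``family.Feature`` (e.g. ``firstorder.Median``, ``glcm.Contrast``)
in a fixed order: 18 first-order, 24 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM and
5 NGTDM features. Map stacks, extraction tables and report CSVs all index
features by these names in this order.
"""

from __future__ import annotations

import csv
from pathlib import Path

from ._firstorder import FIRSTORDER_NAMES
from ._glcm import GLCM_NAMES
from ._gldm import GLDM_NAMES
from ._glrlm import GLRLM_NAMES
from ._glszm import GLSZM_NAMES
from ._ngtdm import NGTDM_NAMES

FAMILIES: dict[str, list[str]] = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "gldm": GLDM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

FEATURE_NAMES: list[str] = [
    f"{family}.{name}" for family, names in FAMILIES.items() for name in names
]

N_FEATURES = len(FEATURE_NAMES)  # 93

FEATURE_INDEX: dict[str, int] = {name: i for i, name in enumerate(FEATURE_NAMES)}


def family_of(feature: str) -> str:
    return feature.split(".", 1)[0]


def export_registry_csv(path: str | Path) -> Path:
    """Write the registry as (name, family, index) rows for report joins."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "family", "index"])
        for i, name in enumerate(FEATURE_NAMES):
            writer.writerow([name, family_of(name), i])
    return path
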