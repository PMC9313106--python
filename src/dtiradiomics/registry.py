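"""Versioned registry of the per-class feature lists.

Keeping the lists in a data file (rather than scattered through code) makes
the printed totals auditable: 23 + 24 + 16 + 16 + 13 = 92 features per image
form, 25 forms per map, 2300 per map, 4600 per subject.

Feature identifiers are ``mapKind|transform|class|name``, e.g.
``FA|wavelet.LHL|GLCM|Imc1``.
"""
from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Dict, List

CLASS_ORDER = ("Histogram", "GLCM", "GLRLM", "GLSZM", "GLDM")


@lru_cache(maxsize=1)
def feature_registry() -> Dict[str, List[str]]:
    with resources.files("dtiradiomics.data").joinpath("feature_registry.json").open() as f:
        reg = json.load(f)
    classes = {k: list(v) for k, v in reg["classes"].items()}
    assert tuple(classes) == CLASS_ORDER
    return classes


def features_per_form() -> int:
    return sum(len(v) for v in feature_registry().values())


def feature_id(map_kind: str, transform: str, cls: str, name: str) -> str:
    return f"{map_kind}|{transform}|{cls}|{name}"


def parse_feature_id(fid: str):
    map_kind, transform, cls, name = fid.split("|")
    return map_kind, transform, cls, name
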