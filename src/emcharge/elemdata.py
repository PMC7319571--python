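"""Bundled physicochemical element tables (covalent radii, Pauling
electronegativities, valence-electron counts)."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .errors import EmchargeError


@lru_cache(maxsize=1)
def _tables() -> dict:
    text = resources.files("emcharge").joinpath("data/elements.json").read_text()
    return json.loads(text)


def covalent_radius(element: str) -> float:
    """Covalent radius in Å (Cordero et al. 2008)."""
    try:
        return _tables()["covalent_radius"][element]
    except KeyError:
        raise EmchargeError(f"no covalent radius tabulated for {element!r}") from None


def pauling_electronegativity(element: str) -> float:
    try:
        return _tables()["pauling_en"][element]
    except KeyError:
        raise EmchargeError(f"no electronegativity tabulated for {element!r}") from None


def valence_electrons(element: str) -> int:
    try:
        return _tables()["valence_electrons"][element]
    except KeyError:
        raise EmchargeError(f"no valence-electron count tabulated for {element!r}") from None
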