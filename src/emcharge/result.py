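"""Charge-result container shared by all methods and writers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class ChargeResult:
    """Per-atom partial charges plus provenance.

    charges are in elementary-charge units, one per atom, in input atom
    order. ``strategy`` records how the underlying solve was carried out:
    ``full`` (exact dense solve), ``cutoff``/``cover`` (local-subsystem
    approximations for macromolecules) or ``iterative`` (PEOE-family and
    other non-linear-system schemes).
    """

    molecule: str
    method: str
    parameter_set: str            # parameter-set id or "none"
    strategy: str                 # full | cutoff | cover | iterative
    charges: np.ndarray
    converged: bool = True
    iterations: int = 0
    chi_bar: Optional[float] = None   # molecular electronegativity, where defined
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        if not np.all(np.isfinite(self.charges)):
            raise ValueError(f"{self.molecule}: non-finite charges")
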