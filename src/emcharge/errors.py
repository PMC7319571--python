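"""Exception hierarchy.

Everything raised on purpose derives from :class:`EmchargeError`, so callers
(CLI, batch runner) can distinguish structured failures from genuine bugs.
"""


class EmchargeError(Exception):
    """Base class for all structured errors."""


class FormatError(EmchargeError):
    """Input file cannot be parsed as the detected/declared format."""


class MissingCoordinatesError(EmchargeError):
    """A 3D operation was requested on a molecule lacking coordinates."""

    def __init__(self, atom_desc: str):
        super().__init__(f"atom {atom_desc} has no coordinates")
        self.atom_desc = atom_desc


class CoverageError(EmchargeError):
    """A parameter set does not cover one or more atom types."""

    def __init__(self, parameter_set: str, missing):
        self.parameter_set = parameter_set
        self.missing = sorted(set(missing))
        keys = ", ".join("/".join(k) for k in self.missing)
        super().__init__(f"parameter set '{parameter_set}' lacks entries for: {keys}")


class SchemaError(EmchargeError):
    """A parameter-set file violates the JSON schema."""


class GeometryError(EmchargeError):
    """Degenerate geometry (e.g. coincident atoms)."""


class SingularSystemError(EmchargeError):
    """The equalization linear system is singular or numerically hopeless."""


class UnknownMethodError(EmchargeError):
    """Method id not in the registry."""
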