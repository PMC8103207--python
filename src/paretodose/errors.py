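"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented contract (shape, range, emptiness...)."""


class GridParseError(IOError):
    """A grid file could not be parsed as NIfTI-1."""


class DegenerateDirectionError(ValueError):
    """Average projected distance is undefined: mean displacement is ~zero
    while individual displacements are not."""
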