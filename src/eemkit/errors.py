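"""Exception hierarchy.

Data/format problems and numerical problems are kept on separate branches so
the command-line layer can map them to distinct exit codes (2 and 3).
"""


class EemError(Exception):
    """Base class for all eemkit errors."""


class DataError(EemError):
    """A problem with input data or file formats (CLI exit code 2)."""


class SdfParseError(DataError):
    """Malformed SDF/molfile input; message names the record and line."""


class ChargeFileError(DataError):
    """Malformed or inconsistent reference-charge file."""


class ParameterFileError(DataError):
    """Malformed parameter-set file (missing kappa, duplicate type, B <= 0...)."""


class AtomTypingError(DataError):
    """Atom typing failed, e.g. aromatic bond order 4 in strict mode."""


class UncoveredMoleculeError(DataError):
    """A molecule contains atom types absent from the parameter set."""


class DegenerateGeometryError(DataError):
    """Two atoms (near-)coincide, so kappa/R would blow up."""


class NumericalError(EemError):
    """A numerical failure (CLI exit code 3)."""


class SingularSystemError(NumericalError):
    """The EEM linear system is numerically singular or produced an
    unreliable solution."""


class IdentifiabilityError(NumericalError):
    """A regression design is not identifiable (degenerate atom type)."""


class FitError(NumericalError):
    """Parameterization failed (rank deficiency beyond the gauge null space,
    every candidate failed, ...)."""


class IdentifiabilityWarning(UserWarning):
    """Fitted parameters are suspect (e.g. non-positive hardness B)."""
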