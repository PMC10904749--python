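"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`MemprobeError`
so callers (and the CLI) can distinguish analysis errors from bugs.
"""


class MemprobeError(Exception):
    """Base class for all package errors."""


class FormatError(MemprobeError):
    """Input file malformed or inconsistent (e.g. atom-count mismatch)."""


class TypingError(MemprobeError):
    """Molecule/atom typing failed (unknown residue, missing atoms)."""


class ConfigError(MemprobeError):
    """Invalid configuration value."""


class DegenerateBilayerError(MemprobeError):
    """Bilayer geometry unusable (e.g. a leaflet with zero lipids)."""


class DegenerateGeometryError(MemprobeError):
    """A geometric construction is undefined (zero-length axis, vertical helix)."""


class ArityError(MemprobeError):
    """Wrong number of peptides for a pairwise operation."""


class EmptySampleError(MemprobeError):
    """No frames/samples left after weighting or masking."""


class CoverageError(MemprobeError):
    """Required (frame, peptide, residue) entries are missing."""


class ConvergenceError(MemprobeError):
    """Iterative solver failed to converge within the iteration budget."""
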