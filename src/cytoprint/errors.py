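"""Exception taxonomy used across the pipeline.

Every stage raises one of these so a failing run aborts with a
stage-attributable diagnostic instead of a bare ValueError from numpy.
"""


class ConfigurationError(ValueError):
    """Required run configuration is missing or inconsistent (e.g. no voxel size)."""


class FormatError(ValueError):
    """An input file does not have the declared layout (e.g. page count mismatch)."""


class ChannelLookupError(KeyError):
    """A named channel does not exist in the stack."""


class UnitError(ValueError):
    """A mesh is in the wrong unit for the requested operation (double scaling etc.)."""


class GeometryError(RuntimeError):
    """A geometric operation produced or received an unusable solid."""


class PhantomSpecError(ValueError):
    """A phantom specification violates its invariants (e.g. nucleus outside cell)."""
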