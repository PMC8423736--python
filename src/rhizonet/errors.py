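"""Exception types shared across the package."""


class RhizonetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RhizonetError, ValueError):
    """An input file violates the documented format contract."""


class AlignmentError(RhizonetError, ValueError):
    """Abundance and genotype tables share no hosts."""


class ConfigError(RhizonetError, ValueError):
    """An invalid parameter or simulation/run configuration."""


class DimensionError(RhizonetError, ValueError):
    """Mismatched dimensions between paired inputs."""


class UndefinedPairError(RhizonetError, ValueError):
    """A microbe pair for which the descriptors are undefined (tied or
    zero abundance)."""


class UndefinedTestError(RhizonetError, ValueError):
    """A statistical test whose groups are empty or degenerate."""


class StructureError(RhizonetError, ValueError):
    """A graph that violates a required structural property (e.g. a cycle
    where a DAG is expected)."""
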