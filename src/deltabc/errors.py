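"""Exception hierarchy for the deltabc pipeline.

Every stage raises a subclass of :class:`DeltaBCError`; the CLI maps these to
a nonzero exit status with a stage-named message.
"""


class DeltaBCError(Exception):
    """Base class for all pipeline errors."""


class MitabError(DeltaBCError):
    """Unreadable or structurally invalid MITAB input."""


class SeedListError(DeltaBCError):
    """Seed-list file empty or unreadable."""


class SamplingError(DeltaBCError):
    """No seed of a list is present in the background network."""


class ConsistencyError(DeltaBCError):
    """Centrality tables disagree about network membership."""


class GenerationError(DeltaBCError):
    """Synthetic-network generation failed to produce a usable instance."""


class ConfigError(DeltaBCError):
    """Run configuration fails validation."""
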