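"""Exception hierarchy for the legflux package.

Every error raised on a user-facing path derives from :class:`LegfluxError`
so callers (and the CLI) can distinguish data problems from bugs.
"""


class LegfluxError(Exception):
    """Base class for all legflux errors."""


class SchemaError(LegfluxError):
    """An input table is missing a mandatory column or has a bad dtype."""


class IntegrityError(LegfluxError):
    """Duplicate keys or cross-table references that do not resolve."""


class ValidationError(LegfluxError):
    """A field value lies outside its stated physiological/domain range."""


class IncompleteOccasionError(LegfluxError):
    """Fewer timepoints than required to average a study occasion."""


class InvalidReadingError(LegfluxError):
    """A plethysmography reading that cannot represent an occlusion slope."""


class InsufficientDataError(LegfluxError):
    """Not enough readings/observations for the requested computation."""


class DegenerateEnrichmentError(LegfluxError):
    """A tracer enrichment of zero (or below) where the algebra divides by it."""


class OrderingError(LegfluxError):
    """Enrichment ordering Em < Ev < Ea violated beyond tolerance."""


class ConfigError(LegfluxError):
    """An invalid configuration value or combination."""


class GenerationError(LegfluxError):
    """A synthetic-truth draw violated a forward-model validity constraint."""


class ConvergenceError(LegfluxError):
    """A statistical model failed to converge."""
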