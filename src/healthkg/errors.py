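"""Exception hierarchy shared across the pipeline."""


class HealthKGError(Exception):
    """Base class for all pipeline errors."""


class SchemaParseError(HealthKGError):
    """The schema document is not well-formed RDF or violates the dialect."""


class SchemaConfigError(HealthKGError):
    """The schema parses but is unusable (e.g. no Subject class marked)."""


class GenerationError(HealthKGError):
    """Artifact derivation failed (e.g. a column-name collision after prefixing)."""


class IngestionError(HealthKGError):
    """Input data could not be normalized into patient bundles."""

    def __init__(self, message: str, paths: list[str] | None = None):
        super().__init__(message)
        self.paths = paths or []


class DeidConfigError(HealthKGError):
    """The de-identification configuration is invalid (bad range, bad regex)."""


class ReplayError(HealthKGError):
    """A replay was requested but no log exists (logging was disabled)."""


class MintingError(HealthKGError):
    """A local identifier is not IRI-safe and cannot be minted."""


class TransformationError(HealthKGError):
    """A bundle could not be transformed to RDF (e.g. dangling link)."""


class SerializationError(HealthKGError):
    """Unsupported serialization format or single-graph constraint violated."""


class ValidationSetupError(HealthKGError):
    """Shapes and data come from different schema model versions."""


class StoreError(HealthKGError):
    """Release-store operation failed (e.g. revoking an unknown patient graph)."""
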