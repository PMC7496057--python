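"""Exception hierarchy.

Every reader/validator rejects malformed input with one of these rather than
silently repairing it; the CLI maps them to distinct exit codes.
"""


class BreedGWASError(Exception):
    """Base class for all package errors."""


class ConfigError(BreedGWASError):
    """Invalid simulation/QC/pipeline configuration; message names the field."""


class ParseError(BreedGWASError):
    """Malformed PED/MAP content; message carries the line number or SNP id."""


class SchemaError(BreedGWASError):
    """Tabular input missing a required column or violating a type invariant."""


class MappingError(BreedGWASError):
    """Sample breed labels that cannot be matched to the phenotype table."""


class DegenerateFitError(BreedGWASError):
    """A regression with zero residual variance or a rank-deficient design."""


class InsufficientDataError(BreedGWASError):
    """Too few observations for the requested statistic."""


class QCStageError(BreedGWASError):
    """A QC stage emptied the data set; message names the stage."""
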