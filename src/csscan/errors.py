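"""Exception hierarchy for the scan pipeline.

Every stage raises a subclass of :class:`CsscanError` so the CLI can tag
failures with the stage that produced them.
"""


class CsscanError(Exception):
    """Base class for all package errors."""


class FormatError(CsscanError):
    """Malformed or inconsistent input file."""


class PhasingError(CsscanError):
    """Unphased genotypes where phased haplotypes are required."""


class ContrastError(CsscanError):
    """Invalid cohort contrast (overlap, empty set, unknown sample)."""


class EmptyPanelError(CsscanError):
    """QC removed every marker."""


class SampleLookupError(CsscanError):
    """Sample identifier not present in the panel."""


class MarkerLookupError(CsscanError):
    """Marker identifier not present in the map."""


class ConfigError(CsscanError):
    """Invalid configuration value."""


class ContractError(CsscanError):
    """A documented precondition was violated."""


class ThresholdError(CsscanError):
    """Empirical quantile thresholds cannot be derived (too few SNPs or a
    degenerate constant track)."""


class DegenerateDistributionError(CsscanError):
    """Standardization impossible: zero variance."""


class NamespaceError(CsscanError):
    """Chromosome naming mismatch between inputs (e.g. annotation vs map)."""


class StageError(CsscanError):
    """Pipeline failure wrapped with the name of the failing stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")
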