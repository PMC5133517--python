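"""Exception hierarchy for ibdqt."""


class IbdqtError(Exception):
    """Base class for all ibdqt errors."""


class ConfigError(IbdqtError):
    """A simulation or analysis configuration value is invalid.

    Carries the name of the offending field in ``field``.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class IbdParseError(IbdqtError):
    """A Refined-IBD segment file could not be parsed; carries the line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class GeneticMapError(IbdqtError):
    """A genetic map is empty, unsorted, or otherwise unusable."""


class PairAlignmentError(IbdqtError):
    """Pair sets of an IBD matrix and a pair-statistics table do not match."""

    def __init__(self, missing_in_stats, missing_in_matrix):
        self.missing_in_stats = sorted(missing_in_stats)
        self.missing_in_matrix = sorted(missing_in_matrix)
        parts = []
        if self.missing_in_stats:
            parts.append(f"pairs missing from trait statistics: {self.missing_in_stats[:10]}")
        if self.missing_in_matrix:
            parts.append(f"pairs missing from IBD matrix: {self.missing_in_matrix[:10]}")
        super().__init__("; ".join(parts) or "pair sets do not match")


class CollinearityError(IbdqtError):
    """The covariate design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")
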