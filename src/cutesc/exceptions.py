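"""Exception hierarchy for cutesc."""


class CutescError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(CutescError, ValueError):
    """Point set is too small or affinely degenerate for triangulation."""


class DuplicatePointsError(DegenerateInputError):
    """Point set contains coincident points (zero-length edges would result)."""

    def __init__(self, duplicate_indices):
        self.duplicate_indices = list(duplicate_indices)
        super().__init__(
            f"duplicate points at indices {self.duplicate_indices}; "
            "deduplicate the input before clustering"
        )


class StatisticsUndefinedError(CutescError, ValueError):
    """Edge statistics requested over an empty or edgeless scope."""


class UndefinedMetricError(CutescError, ValueError):
    """A validation criterion is undefined for the given input."""


class UndefinedScoreError(CutescError, ValueError):
    """Calinski-Harabasz score undefined (fewer than 2 clusters or zero scatter)."""


class ParseError(CutescError, ValueError):
    """Malformed point or label file."""
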