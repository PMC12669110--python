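"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent.

    Examples: retinal layers that overflow the image height, an unknown
    exclusion flag, or an annealing schedule longer than training.
    """


class MatchingError(RuntimeError):
    """Raised when case-control matching cannot be completed.

    Carries the list of case ids that could not be matched so callers can
    report them; partial matchings are never returned silently.
    """

    def __init__(self, unmatched_cases, message=None):
        self.unmatched_cases = list(unmatched_cases)
        if message is None:
            message = (
                "insufficient controls within caliper for cases: "
                + ", ".join(str(c) for c in self.unmatched_cases)
            )
        super().__init__(message)
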