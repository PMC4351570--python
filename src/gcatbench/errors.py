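"""Exception hierarchy shared across the toolkit."""


class GcatBenchError(Exception):
    """Base class for all errors raised by this package."""


class InputError(GcatBenchError, ValueError):
    """Invalid user-supplied parameter or malformed input data."""


class ReadNameError(InputError):
    """A read name could not be decoded into a simulated read origin."""


class EvaluationError(GcatBenchError, RuntimeError):
    """An internal consistency problem detected while scoring results."""
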