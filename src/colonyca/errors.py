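"""Exception hierarchy.

The CLI maps these onto distinct exit codes (config 2, simulation 3, I/O 4),
so library code should raise the most specific class that applies.
"""


class ColonycaError(Exception):
    """Base class for all package errors."""


class ConfigError(ColonycaError):
    """Invalid configuration: missing/unknown key, type mismatch, or a
    parameter outside its admissible range. The message names the key and
    the constraint violated."""


class ValidationError(ColonycaError):
    """A simulation state or inoculum specification violates an invariant."""


class SimulationError(ColonycaError):
    """A scenario or tuning run could not produce the required outcome
    (e.g. empty feasible set in a threshold grid search)."""


class PartialTraceError(SimulationError):
    """Classification was requested for a trace that never terminated
    (generation cap hit before all occupied sites matured)."""


class TraceIOError(ColonycaError):
    """Malformed trace/report file; the message carries the line number
    where parsing failed when available."""
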