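"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`InputError` -> 2,
:class:`DegenerateModelError` -> 3, anything else -> 1.
"""


class MtDemuxError(Exception):
    """Base class for all package errors."""


class InputError(MtDemuxError):
    """Malformed, missing or inconsistent input (files, matrices, labels)."""


class ParameterError(MtDemuxError):
    """A parameter combination that cannot be satisfied."""


class CapacityError(ParameterError):
    """More variants requested than mitochondrial positions available."""


class DegenerateModelError(MtDemuxError):
    """The fitted model collapsed (e.g. a cluster with no specific variants)."""
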