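"""Error taxonomy shared across the pipeline.

Every failure mode that callers are expected to handle carries a stable
short ``code`` (e.g. ``"empty_roi"``) so that scripted pipelines and tests
can dispatch on it without string-matching messages.
"""

from __future__ import annotations


class AnalysisError(ValueError):
    """Base class for all domain errors raised by nbdyn.

    Parameters
    ----------
    code:
        Stable machine-readable identifier of the failure mode.
    message:
        Human-readable detail; defaults to the code itself.
    """

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)


def err(code: str, message: str | None = None) -> AnalysisError:
    """Convenience constructor: ``raise err("empty_roi", "...")``."""
    return AnalysisError(code, message)
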