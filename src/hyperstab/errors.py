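"""Exception hierarchy shared across the package."""


class HyperstabError(Exception):
    """Base class for all package errors."""


class ParameterError(HyperstabError, ValueError):
    """An argument violates a documented precondition."""


class CapabilityError(HyperstabError, RuntimeError):
    """A backend lacks a capability (OOB error, an importance mode) the caller requires."""


class BackendError(HyperstabError, RuntimeError):
    """A backend failed during fit/predict; carries the backend id."""

    def __init__(self, backend_id: str, message: str):
        self.backend_id = backend_id
        super().__init__(f"[{backend_id}] {message}")


class GridExecutionError(HyperstabError, RuntimeError):
    """A cell of the model grid failed; names (signature, partition, replicate)."""
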