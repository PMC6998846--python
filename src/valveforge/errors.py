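"""Exception hierarchy shared across valveforge modules."""


class ValveForgeError(Exception):
    """Base class for all valveforge errors."""


class ParameterError(ValveForgeError, ValueError):
    """Invalid configuration parameter; ``field`` names the offending entry."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class GeometryError(ValveForgeError):
    """Mesh construction failed (self-intersection, incompatible dimensions)."""


class InputError(ValveForgeError, ValueError):
    """Operation input outside the supported domain."""


class FormatError(ValveForgeError):
    """Malformed file on import."""

    def __init__(self, message: str, byte_offset: int | None = None):
        self.byte_offset = byte_offset
        if byte_offset is not None:
            message = f"{message} (byte offset {byte_offset})"
        super().__init__(message)
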