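"""I/O error types."""


class ParseError(ValueError):
    """Malformed record in a structure or trajectory file.

    Carries the file path and 1-based line number where parsing failed.
    Parsers reject malformed mandatory fields; they never repair them.
    """

    def __init__(self, path, lineno: int | None, message: str) -> None:
        loc = f"{path}" if lineno is None else f"{path}:{lineno}"
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.lineno = lineno


class UnsupportedBoxError(ValueError):
    """Triclinic (non-orthorhombic) cells are not supported."""
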