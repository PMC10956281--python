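"""Exception types shared across the package."""


class SpecificationError(ValueError):
    """A generative or run specification is internally inconsistent."""


class DegenerateInputError(ValueError):
    """An input is structurally valid but statistically degenerate
    (e.g. an empty margin of a contingency table, single-class truth)."""


class SchemaError(KeyError):
    """A required column is missing from a table."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"required column missing: {column!r}")
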