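"""Exception hierarchy for facecolor."""


class FaceColorError(Exception):
    """Base class for all facecolor errors."""


class GeometryError(FaceColorError, ValueError):
    """Degenerate or out-of-bounds geometry (quads, splines, circles)."""


class DataError(FaceColorError, ValueError):
    """Invalid, missing or non-finite input data."""


class CollinearityError(DataError):
    """Singular regression design; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"singular design matrix; offending columns: {self.columns}")
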