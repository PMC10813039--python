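"""Exception types shared across the package."""


class VitrehazeError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(VitrehazeError):
    """Layer boundaries are not strictly increasing or fall outside the depth range."""


class ContrastStateError(VitrehazeError):
    """An operation received a volume in the wrong contrast state.

    Raw-data operations (ILM segmentation, haze scoring) refuse
    display-transformed volumes; the contrast transform refuses to be
    applied twice.
    """


class UndefinedScoreError(VitrehazeError):
    """The haze ratio is undefined (empty vitreous or vanishing denominator)."""


class ConfigError(VitrehazeError):
    """A configuration object failed validation."""


class CollinearDesignError(VitrehazeError):
    """The regression design matrix is rank-deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is singular; collinear columns: " + ", ".join(self.columns)
        )
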