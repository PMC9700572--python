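"""Exception hierarchy for the boxfd pipeline.

Every error that a pipeline stage can raise intentionally derives from
:class:`BoxfdError` so that the CLI can distinguish expected per-image
failures (logged and skipped) from programming errors (propagated).
"""


class BoxfdError(Exception):
    """Base class for all intentional pipeline errors."""


class InvalidParameterError(BoxfdError, ValueError):
    """A caller-supplied parameter violates a precondition."""


class InvalidContourError(BoxfdError, ValueError):
    """A contour is degenerate, open where closure is required, or self-intersecting."""


class GenerationFailureError(BoxfdError, RuntimeError):
    """Synthetic contour generation failed repeatedly (self-intersection)."""


class CalibrationError(BoxfdError, RuntimeError):
    """The compass ring could not be found or fitted; supply mm_per_pixel explicitly."""


class SeedError(BoxfdError, ValueError):
    """The segmentation seed point does not lie in a lumen-intensity region."""


class OpenBoundaryError(BoxfdError, RuntimeError):
    """The detected lumen component touches the image frame; the border would be clipped."""


class FragmentationError(BoxfdError, RuntimeError):
    """No single closed border enclosing the seed could be traced."""


class DegenerateCaliberError(BoxfdError, ValueError):
    """A box caliber exceeds the contour's bounding-box diagonal."""


class InsufficientScalesError(BoxfdError, ValueError):
    """Fewer than three box-count entries; no slope can be fitted."""


class DegenerateInputError(BoxfdError, ValueError):
    """A statistical input is constant or otherwise carries no information."""


class InsufficientDataError(BoxfdError, ValueError):
    """Too few subjects per group remain after missing-data exclusion."""
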