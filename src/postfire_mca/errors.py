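"""Exception hierarchy for the post-fire MCA toolkit."""


class PostfireMCAError(Exception):
    """Base class for all package errors."""


class IncompleteJudgmentsError(PostfireMCAError):
    """A pairwise-comparison set is missing at least one (i, j) judgment."""


class JudgmentDomainError(PostfireMCAError, ValueError):
    """A pairwise judgment is nonpositive or outside the allowed scale."""


class UnsupportedMatrixSizeError(PostfireMCAError):
    """No random-index value is available for a matrix of this size."""


class CriteriaOrderError(PostfireMCAError):
    """Weight vectors or score tables disagree on criteria names/order."""


class GridShapeError(PostfireMCAError, ValueError):
    """Co-registered grids have mismatched shapes."""


class GridAlignmentError(PostfireMCAError):
    """Grids are not on the same georeferenced grid."""


class NoOverlapError(PostfireMCAError):
    """Layer extents do not intersect."""


class NoSceneError(PostfireMCAError):
    """No satellite scene satisfies the cloud/date filters within the
    maximum time buffer.  ``side`` names the failing side(s)."""

    def __init__(self, side: str, message: str = ""):
        self.side = side
        super().__init__(message or f"no qualifying {side} scene(s)")


class ScoreLookupError(PostfireMCAError, KeyError):
    """A value falls outside the domain of a discrete score table."""


class UndefinedRCError(PostfireMCAError):
    """Regeneration capacity is undefined (zero total cover)."""


class VocabularyError(PostfireMCAError, ValueError):
    """An erosion observation code is not in the scoring vocabulary."""


class DegenerateBandsError(PostfireMCAError):
    """Quantile banding requested on a constant map."""


class PipelineStageError(PostfireMCAError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
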