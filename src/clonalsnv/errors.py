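"""Exception hierarchy used across the package."""


class ClonalSNVError(Exception):
    """Base class for all package-specific errors."""


class NoCoverageError(ClonalSNVError):
    """A site has zero sequencing depth, so no VAF genotype can be assigned."""


class UndefinedTestError(ClonalSNVError):
    """A bias test was requested on data where the test is undefined."""


class IncompleteSiteError(ClonalSNVError):
    """Site filtering requires an observation for every clone."""


class InvariantSiteError(ClonalSNVError):
    """All clones are homozygous reference: the site is not a variant."""


class InfeasiblePanelError(ClonalSNVError):
    """The requested marker panel cannot be filled from the candidates."""


class UndefinedDistanceError(ClonalSNVError):
    """Two profiles share no comparable (non-missing) loci."""


class PipelineDependencyError(ClonalSNVError):
    """A pipeline stage was enabled without its upstream output."""
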