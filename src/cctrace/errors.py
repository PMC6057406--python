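"""Exception hierarchy for the cctrace pipeline."""


class CCTraceError(Exception):
    """Base class for all cctrace errors."""


class GeometryError(CCTraceError):
    """Invalid mask geometry (empty, multi-component, degenerate moments...)."""


class ShapeContextError(CCTraceError):
    """Shape-context descriptor or endpoint-model error."""


class CenterlineError(CCTraceError):
    """Distance-map or active-contour evolution error."""


class EvaluationError(CCTraceError):
    """Reconstruction / distance evaluation error."""


class SyntheticError(CCTraceError):
    """Synthetic mask generation error."""
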