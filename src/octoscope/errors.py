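"""Exception hierarchy.

Each error carries a stable snake_case token in its message so CLI callers
and tests can match on it regardless of the human-readable detail.
"""


class OctoscopeError(Exception):
    token = "octoscope_error"

    def __init__(self, detail: str = ""):
        msg = self.token if not detail else f"{self.token}: {detail}"
        super().__init__(msg)


class InvalidPhantomSpec(OctoscopeError):
    token = "invalid_phantom_spec"


class UnsupportedImage(OctoscopeError):
    token = "unsupported_image"


class InvalidWindow(OctoscopeError):
    token = "invalid_window"


class InvalidSigma(OctoscopeError):
    token = "invalid_sigma"


class SegmentationFailure(OctoscopeError):
    token = "segmentation_failure"


class InsufficientTrainingClasses(OctoscopeError):
    token = "insufficient_training_classes"


class InvalidFeatureVector(OctoscopeError):
    token = "invalid_feature_vector"


class InvalidFoldCount(OctoscopeError):
    token = "invalid_fold_count"
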