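"""Exception hierarchy shared across the pipeline stages."""


class TrustEEGError(Exception):
    """Base class for package errors."""


class ConfigError(TrustEEGError):
    """Invalid configuration: unknown SCL level, bad window, unknown parcel."""


class DataError(TrustEEGError):
    """Invalid or degenerate data: empty case, single-class training set."""


class GeometryError(TrustEEGError):
    """Invalid head-model geometry: dipole outside the sphere, empty parcel."""
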