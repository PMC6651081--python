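__version__ = "0.1.0"


def version_dict() -> dict:
    """Versions of this package and its numerical dependencies, for provenance."""
    import numpy
    import pywt
    import scipy

    return {
        "ewtwt": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pywavelets": pywt.__version__,
    }
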