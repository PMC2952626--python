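"""Bundled reference tables."""

from importlib import resources

import pandas as pd


def load_chr16_isochores() -> pd.DataFrame:
    """Published isochore calls for pig chromosome 16 (assembly Sscrofa9).

    The 24 isochores reported for pig chromosome 16, with 1-based
    inclusive coordinates, length, GC percent, family label and
    homogeneity index h.  Used as a fixed worked example: lengths follow
    from the coordinates, family labels follow from the GC column under
    the family boundaries, and every h value sits below the 0.2
    isochore cutoff.
    """
    with resources.files("lhgr").joinpath(
        "data/sus_scrofa_chr16_isochores.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
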