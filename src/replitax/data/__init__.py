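"""Bundled reference tables.

``reference_replicons`` returns the published replicon inventory of the
three finished Rhizobium genomes this package ships as a worked example
(GenBank CP117255-CP117270): per replicon, its published name, role call,
size in bp, GC percent, and accession.
"""

from importlib import resources

import pandas as pd

__all__ = ["reference_replicons"]


def reference_replicons() -> pd.DataFrame:
    with resources.files(__package__).joinpath(
        "reference_replicons.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
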